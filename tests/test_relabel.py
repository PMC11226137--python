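"""Majority-vote labels, threshold multi-labels and inconsistency audit,
checked against brute-force pixel counting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gleasonpatch.io_formats import GRADES, GradeCode, LabelPolicy, Manifest, write_mask
from gleasonpatch.relabel import (
    binary_targets,
    class_counts,
    inconsistency_report,
    majority_label,
    misclassified_fractions,
    multilabel_from_mask,
)
from gleasonpatch.synthetic import planted_fraction_mask

BG, NC, G3, G4, G5 = (int(c) for c in GradeCode)


def brute_majority(mask):
    """Independent oracle: count pixels by looping, pick the largest
    grade count, highest grade on ties, NC when no grade pixels."""
    counts = {c: 0 for c in range(5)}
    for v in np.asarray(mask).ravel():
        counts[int(v)] += 1
    grade_counts = [(counts[G3], G3), (counts[G4], G4), (counts[G5], G5)]
    best = max(c for c, _ in grade_counts)
    if best == 0:
        return GradeCode.NC
    return GradeCode(max(g for c, g in grade_counts if c == best))


def brute_multilabel(mask, tau, min_count=1):
    counts = {c: 0 for c in range(5)}
    flat = np.asarray(mask).ravel()
    for v in flat:
        counts[int(v)] += 1
    n = flat.size
    thresh = max(min_count, int(np.floor(tau * n)))
    grades = {GradeCode(g) for g in (G3, G4, G5) if counts[g] >= thresh}
    nc = all(counts[g] == 0 for g in (G3, G4, G5))
    return grades, nc


def fraction_mask(shape, counts):
    """Mask with the given {code: pixel count} laid out in raster order."""
    flat = np.concatenate([np.full(n, c, dtype=np.uint8) for c, n in counts.items()])
    assert flat.size == shape[0] * shape[1]
    return flat.reshape(shape)


class TestMajorityLabel:
    def test_strict_majority(self):
        mask = fraction_mask((10, 10), {G4: 60, G3: 40})
        assert majority_label(mask) == GradeCode.G4

    def test_pure_nc_tissue(self):
        assert majority_label(np.full((4, 4), NC, dtype=np.uint8)) == GradeCode.NC

    def test_tie_breaks_to_higher_grade(self):
        mask = fraction_mask((2, 2), {G3: 2, G5: 2})
        assert majority_label(mask) == GradeCode.G5

    def test_bg_ignored(self):
        mask = fraction_mask((10, 10), {BG: 90, G3: 6, G4: 4})
        assert majority_label(mask) == GradeCode.G3

    def test_all_background_rejected(self):
        with pytest.raises(ValueError, match="tissue"):
            majority_label(np.zeros((3, 3), dtype=np.uint8))

    def test_exhaustive_2x2_vs_oracle(self):
        for values in itertools.product((NC, G3, G4, G5), repeat=4):
            mask = np.array(values, dtype=np.uint8).reshape(2, 2)
            assert majority_label(mask) == brute_majority(mask)


class TestMultilabelFromMask:
    def test_one_percent_of_512_is_2621_pixels(self):
        # 2622 G3 pixels in a 512x512 patch clears the 1% threshold
        mask = fraction_mask((512, 512), {G3: 2622, NC: 512 * 512 - 2622})
        ml = multilabel_from_mask(mask, LabelPolicy(tau=0.01))
        assert ml.grades == {GradeCode.G3}
        assert not ml.nc
        # 2620 does not (threshold is exactly 2621)
        mask = fraction_mask((512, 512), {G3: 2620, NC: 512 * 512 - 2620})
        ml = multilabel_from_mask(mask, LabelPolicy(tau=0.01))
        assert ml.grades == frozenset()
        assert not ml.nc and ml.excluded

    def test_minority_class_captured(self):
        mask = fraction_mask((100, 100), {G4: 9800, G5: 200})
        ml = multilabel_from_mask(mask, LabelPolicy(tau=0.01))
        assert ml.grades == {GradeCode.G4, GradeCode.G5}

    def test_sub_threshold_cancer_is_ambiguous(self):
        mask = fraction_mask((200, 200), {G3: 200, NC: 39800})  # 0.5% G3
        ml = multilabel_from_mask(mask, LabelPolicy(tau=0.01))
        assert ml.grades == frozenset() and not ml.nc and ml.excluded

    def test_nc_iff_zero_grade_pixels(self):
        pure = np.full((8, 8), NC, dtype=np.uint8)
        assert multilabel_from_mask(pure, LabelPolicy()).nc
        one_pixel = pure.copy()
        one_pixel[0, 0] = G5
        assert not multilabel_from_mask(one_pixel, LabelPolicy()).nc

    def test_exhaustive_2x2_vs_oracle(self):
        policy = LabelPolicy(tau=0.25)
        for values in itertools.product((NC, G3, G4, G5), repeat=4):
            mask = np.array(values, dtype=np.uint8).reshape(2, 2)
            ml = multilabel_from_mask(mask, policy)
            grades, nc = brute_multilabel(mask, 0.25)
            assert ml.grades == grades and ml.nc == nc

    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.5))
    @settings(max_examples=60, deadline=None)
    def test_random_64x64_vs_oracle(self, seed, tau):
        rng = np.random.default_rng(seed)
        mask = rng.integers(0, 5, size=(64, 64)).astype(np.uint8)
        if (mask == BG).all():
            return
        ml = multilabel_from_mask(mask, LabelPolicy(tau=tau))
        grades, nc = brute_multilabel(mask, tau)
        assert ml.grades == grades and ml.nc == nc

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_tau_and_superset_of_majority(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.integers(1, 5, size=(16, 16)).astype(np.uint8)
        tau1, tau2 = sorted(rng.uniform(0, 1, size=2))
        g1 = multilabel_from_mask(mask, LabelPolicy(tau=tau1)).grades
        g2 = multilabel_from_mask(mask, LabelPolicy(tau=tau2)).grades
        assert g1 >= g2  # lower threshold admits at least as many grades
        m = majority_label(mask)
        counts = class_counts(mask)
        if m in GRADES and counts[m] / mask.size >= tau1 and counts[m] >= 1:
            assert m in g1

    def test_counts_sum_to_mask_size(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 5, size=(31, 17)).astype(np.uint8)
        assert sum(class_counts(mask).values()) == mask.size


class TestMisclassifiedFractions:
    def test_thirty_percent_minority(self):
        mask = fraction_mask((10, 10), {G4: 70, G3: 30})
        fracs = misclassified_fractions(mask)
        assert fracs[GradeCode.G3] == pytest.approx(0.30)
        assert fracs[GradeCode.G5] == 0.0
        assert fracs[GradeCode.G4] == 0.0  # the majority class itself

    def test_pure_nc_all_zero(self):
        fracs = misclassified_fractions(np.full((6, 6), NC, dtype=np.uint8))
        assert all(v == 0.0 for v in fracs.values())

    def test_exhaustive_4x4_vs_pixel_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            mask = rng.integers(1, 5, size=(4, 4)).astype(np.uint8)
            m = brute_majority(mask)
            fracs = misclassified_fractions(mask)
            for g in GRADES:
                expected = 0.0 if g == m else np.sum(mask == int(g)) / mask.size
                assert fracs[g] == pytest.approx(expected)


class TestInconsistencyReport:
    def _manifest(self, tmp_path, masks, folds):
        rows = []
        for i, (mask, fold) in enumerate(zip(masks, folds)):
            rel = f"mask_{i}.png"
            write_mask(mask, tmp_path / rel)
            rows.append({"patch_path": f"img_{i}.png", "mask_path": rel,
                         "patient_id": f"P{i}", "slide_id": f"S{i}", "fold": fold})
        return Manifest(pd.DataFrame(rows), root=tmp_path)

    def test_mean_and_max_arithmetic(self, tmp_path):
        masks = [
            fraction_mask((20, 20), {G4: 360, G3: 40}),   # G3 off-majority 0.10
            fraction_mask((20, 20), {G4: 320, G3: 80}),   # G3 off-majority 0.20
        ]
        man = self._manifest(tmp_path, masks, ["Val1", "Val1"])
        table = inconsistency_report(man, LabelPolicy()).table
        g3 = table[(table["split"] == "Val1") & (table["class"] == "G3")].iloc[0]
        assert g3["mean_frac"] == pytest.approx(0.15)
        assert g3["max_frac"] == pytest.approx(0.20)
        assert g3["n_patches"] == 2

    def test_absent_class_reports_zero_with_n_zero(self, tmp_path):
        masks = [fraction_mask((10, 10), {G4: 90, G3: 10})]
        man = self._manifest(tmp_path, masks, ["Test"])
        table = inconsistency_report(man, LabelPolicy()).table
        g5 = table[(table["split"] == "Test") & (table["class"] == "G5")].iloc[0]
        assert g5["mean_frac"] == 0.0 and g5["max_frac"] == 0.0 and g5["n_patches"] == 0

    def test_planted_fractions_recovered_exactly(self, tmp_path):
        # planted off-majority G3 fractions with known mean 0.15, max 0.30
        planted = [0.05, 0.10, 0.30]
        masks = [planted_fraction_mask((40, 40), GradeCode.G4, {GradeCode.G3: f})
                 for f in planted]
        man = self._manifest(tmp_path, masks, ["Val2"] * 3)
        table = inconsistency_report(man, LabelPolicy()).table
        g3 = table[(table["split"] == "Val2") & (table["class"] == "G3")].iloc[0]
        assert g3["mean_frac"] == pytest.approx(np.mean(planted))
        assert g3["max_frac"] == pytest.approx(0.30)

    def test_histograms_use_one_point_bins(self, tmp_path):
        masks = [fraction_mask((20, 20), {G4: 360, G3: 40})]
        man = self._manifest(tmp_path, masks, ["Val1"])
        report = inconsistency_report(man, LabelPolicy())
        hist = report.histograms[("Val1", "G3")]
        assert hist.shape == (100,)
        assert hist[10] == 1  # 0.10 falls in the [0.10, 0.11) bin


class TestBinaryTargets:
    def test_statuses(self, tmp_path):
        masks = [
            fraction_mask((100, 100), {G4: 5000, G5: 5000}),   # positive for G4
            np.full((100, 100), NC, dtype=np.uint8),           # negative (NC)
            fraction_mask((200, 200), {G3: 200, NC: 39800}),   # sub-threshold -> excluded
            fraction_mask((100, 100), {G3: 10000}),            # negative for G4
        ]
        rows = []
        for i, mask in enumerate(masks):
            rel = f"m{i}.png"
            write_mask(mask, tmp_path / rel)
            rows.append({"patch_path": f"i{i}.png", "mask_path": rel,
                         "patient_id": f"P{i}", "slide_id": f"S{i}", "fold": "Val1"})
        man = Manifest(pd.DataFrame(rows), root=tmp_path)
        statuses = dict(binary_targets(man, LabelPolicy(), GradeCode.G4))
        assert statuses == {0: "positive", 1: "negative", 2: "excluded", 3: "negative"}

    def test_invalid_grade_rejected(self, tmp_path):
        man = Manifest(pd.DataFrame(columns=["patch_path", "mask_path", "patient_id",
                                             "slide_id", "fold"]), root=tmp_path)
        with pytest.raises(ValueError):
            binary_targets(man, LabelPolicy(), GradeCode.NC)
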