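"""Patch relabelling and majority-vote label-noise auditing.

Patch-level Gleason datasets conventionally label each patch with the
grade occupying the most annotated pixels (majority vote).  When a patch
mixes grades, every pixel of a non-majority grade is effectively
mislabelled; on real data the off-majority area reaches tens of percent
of a patch.  This module quantifies that inconsistency and replaces the
single majority label with a multi-label: every grade whose pixel
fraction clears a threshold tau is asserted, and the benign NC label is
issued only when no grade pixel at all is present.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import GRADES, GradeCode, LabelPolicy, Manifest, read_mask

_GRADE_NAMES = {GradeCode.G3: "G3", GradeCode.G4: "G4", GradeCode.G5: "G5"}


@dataclasses.dataclass(frozen=True)
class MultiLabel:
    """Subset of {G3, G4, G5} present in a patch, plus the NC flag.

    ``nc`` is true iff the patch contains zero G3/G4/G5 pixels; a patch
    whose grade pixels all fall below threshold has ``grades == frozenset()``
    and ``nc == False`` ("sub-threshold cancer", excluded from training).
    """

    grades: frozenset
    nc: bool

    def __post_init__(self) -> None:
        if self.nc and self.grades:
            raise ValueError("nc=True requires an empty grade set")

    @property
    def excluded(self) -> bool:
        return not self.nc and not self.grades


def class_counts(mask: np.ndarray) -> dict[GradeCode, int]:
    """Pixel count per GradeCode; counts sum to the mask size."""
    mask = np.asarray(mask)
    counts = np.bincount(mask.ravel(), minlength=5)
    return {code: int(counts[int(code)]) for code in GradeCode}


def _denominator(counts: dict[GradeCode, int], policy: LabelPolicy, size: int) -> int:
    if policy.denominator == "tissue_pixels":
        return size - counts[GradeCode.BG]
    return size


def majority_label(mask: np.ndarray) -> GradeCode:
    """Majority-vote label: the grade with the most pixels.

    BG pixels are ignored; NC is returned only when no grade pixel exists.
    Ties between grades break toward the higher (more aggressive) grade.
    An all-BG mask carries no tissue and raises ValueError.
    """
    counts = class_counts(mask)
    n_tissue = sum(counts[c] for c in GradeCode if c != GradeCode.BG)
    if n_tissue == 0:
        raise ValueError("mask contains no tissue (all background)")
    grade_counts = {g: counts[g] for g in GRADES}
    best = max(grade_counts.values())
    if best == 0:
        return GradeCode.NC
    # high-grade tie-break: iterate grades high to low, take first at max
    for g in reversed(GRADES):
        if grade_counts[g] == best:
            return g
    raise AssertionError("unreachable")


def multilabel_from_mask(mask: np.ndarray, policy: LabelPolicy | None = None) -> MultiLabel:
    """Threshold-based multi-label for a mask.

    Grade c is asserted iff ``count_c >= max(min_count, floor(tau * N))``
    where N is the policy denominator (all pixels by default).  NC is true
    iff the mask has zero grade pixels.
    """
    policy = policy or LabelPolicy()
    counts = class_counts(mask)
    size = int(np.asarray(mask).size)
    if size == counts[GradeCode.BG]:
        raise ValueError("mask contains no tissue (all background)")
    n = _denominator(counts, policy, size)
    thresh = policy.count_threshold(n)
    grades = frozenset(g for g in GRADES if counts[g] >= thresh)
    nc = all(counts[g] == 0 for g in GRADES)
    return MultiLabel(grades=grades, nc=nc)


def misclassified_fractions(
    mask: np.ndarray, policy: LabelPolicy | None = None
) -> dict[GradeCode, float]:
    """Off-majority pixel fraction per grade.

    For majority label m, returns for each grade c != m the fraction
    count_c / N (N per the policy denominator); the majority grade itself
    maps to 0.0, as does any absent grade.  These are the pixels a
    majority-vote label silently mislabels.
    """
    policy = policy or LabelPolicy()
    m = majority_label(mask)  # raises on all-BG
    counts = class_counts(mask)
    n = _denominator(counts, policy, int(np.asarray(mask).size))
    out: dict[GradeCode, float] = {}
    for g in GRADES:
        out[g] = 0.0 if g == m else counts[g] / n
    return out


@dataclasses.dataclass
class InconsistencyReport:
    """Per-split, per-grade summary of off-majority pixel fractions.

    ``table`` rows: split x class with mean_frac, max_frac and n_patches
    (patches where the class appears off-majority, i.e. fraction > 0);
    ``histograms`` maps (split, class) to counts over 1-percentage-point
    bins [0,0.01), ..., [0.99,1.0].
    """

    table: pd.DataFrame
    histograms: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        bad = self.table[self.table["mean_frac"] > self.table["max_frac"]]
        if len(bad):
            raise ValueError("mean_frac exceeds max_frac")


_HIST_BINS = np.linspace(0.0, 1.0, 101)


def inconsistency_report(
    manifest: Manifest,
    policy: LabelPolicy | None = None,
    include_zero: bool = False,
) -> InconsistencyReport:
    """Aggregate misclassified_fractions over a manifest, split by fold.

    By default statistics are over patches where the class occurs
    off-majority (fraction > 0); ``include_zero=True`` instead averages
    over every patch in the split.
    """
    policy = policy or LabelPolicy()
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    fracs: dict[str, dict[GradeCode, list[float]]] = {}
    for _, row in manifest.frame.iterrows():
        mask = read_mask(manifest.resolve(row["mask_path"]))
        per_class = misclassified_fractions(mask, policy)
        split = fracs.setdefault(row["fold"], {g: [] for g in GRADES})
        for g in GRADES:
            split[g].append(per_class[g])
    rows = []
    hists: dict[tuple[str, str], np.ndarray] = {}
    for fold, per_grade in sorted(fracs.items()):
        for g in GRADES:
            values = np.asarray(per_grade[g], dtype=float)
            contributing = values if include_zero else values[values > 0]
            if contributing.size:
                mean_frac = float(contributing.mean())
                max_frac = float(contributing.max())
            else:
                mean_frac = max_frac = 0.0
            rows.append(
                {
                    "split": fold,
                    "class": _GRADE_NAMES[g],
                    "mean_frac": mean_frac,
                    "max_frac": max_frac,
                    "n_patches": int(contributing.size),
                }
            )
            hists[(fold, _GRADE_NAMES[g])] = np.histogram(values[values > 0], bins=_HIST_BINS)[0]
    return InconsistencyReport(table=pd.DataFrame(rows), histograms=hists)


def binary_targets(
    manifest: Manifest,
    policy: LabelPolicy,
    grade: GradeCode,
    labels: Iterable[MultiLabel] | None = None,
) -> list[tuple[int, str]]:
    """One-vs-all targets for a grade's sub-classifier.

    Returns ``(row_index, status)`` per manifest row with status
    ``positive`` (grade in the multi-label), ``negative`` (NC or only
    other grades asserted) or ``excluded`` (sub-threshold cancer:
    no grade clears the threshold yet the patch is not benign).
    Pass ``labels`` to reuse precomputed multi-labels.
    """
    if grade not in GRADES:
        raise ValueError(f"grade must be one of {GRADES}, got {grade}")
    if labels is None:
        labels = [
            multilabel_from_mask(read_mask(manifest.resolve(row["mask_path"])), policy)
            for _, row in manifest.frame.iterrows()
        ]
    out: list[tuple[int, str]] = []
    for idx, ml in enumerate(labels):
        if ml.excluded:
            out.append((idx, "excluded"))
        elif grade in ml.grades:
            out.append((idx, "positive"))
        else:
            out.append((idx, "negative"))
    return out


def multilabel_columns(manifest: Manifest, policy: LabelPolicy) -> pd.DataFrame:
    """Manifest frame augmented with 0/1 columns g3,g4,g5,nc,excluded."""
    labels = [
        multilabel_from_mask(read_mask(manifest.resolve(row["mask_path"])), policy)
        for _, row in manifest.frame.iterrows()
    ]
    frame = manifest.frame.copy()
    for g, name in _GRADE_NAMES.items():
        frame[name.lower()] = [int(g in ml.grades) for ml in labels]
    frame["nc"] = [int(ml.nc) for ml in labels]
    frame["excluded"] = [int(ml.excluded) for ml in labels]
    return frame
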