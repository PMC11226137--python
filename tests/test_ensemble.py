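"""Multi-label decision rule, PR curves vs a brute-force oracle, and the
evaluation metrics on hand-worked tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gleasonpatch.ensemble import (
    EnsembleModel,
    EvalReport,
    _report_for,
    pr_curve,
    predict_multilabel,
    predict_scores,
)
from gleasonpatch.io_formats import GRADES, GradeCode
from gleasonpatch.relabel import MultiLabel

G3, G4, G5 = GradeCode.G3, GradeCode.G4, GradeCode.G5


def brute_pr_points(scores, labels):
    """Oracle: enumerate confusion tables at every candidate threshold."""
    points = {}
    candidates = sorted(set(scores)) + [min(scores) - 1.0]
    for t in candidates:
        tp = sum(1 for s, l in zip(scores, labels) if s > t and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s > t and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s <= t and l == 1)
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        points[t] = (prec, rec, f1)
    return points


class TestPredictMultilabel:
    def test_single_grade_above_threshold(self):
        scores = {G3: 0.9, G4: 0.2, G5: 0.1}
        ml = predict_multilabel(scores, {g: 0.5 for g in GRADES})
        assert ml.grades == {G3} and not ml.nc

    def test_all_below_threshold_is_nc(self):
        scores = {G3: 0.4, G4: 0.3, G5: 0.49}
        ml = predict_multilabel(scores, {g: 0.5 for g in GRADES})
        assert ml.grades == frozenset() and ml.nc

    def test_all_grades_possible(self):
        scores = {G3: 0.6, G4: 0.7, G5: 0.55}
        ml = predict_multilabel(scores, {g: 0.5 for g in GRADES})
        assert ml.grades == {G3, G4, G5}

    def test_tie_at_threshold_is_negative(self):
        scores = {G3: 0.5, G4: 0.2, G5: 0.2}
        assert predict_multilabel(scores, {g: 0.5 for g in GRADES}).nc

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValueError, match="G5"):
            predict_multilabel({G3: 0.1, G4: 0.1, G5: 0.1}, {G3: 0.5, G4: 0.5})

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_raising_thresholds_never_adds_grades(self, seed):
        rng = np.random.default_rng(seed)
        scores = {g: float(rng.uniform()) for g in GRADES}
        t1 = {g: float(rng.uniform()) for g in GRADES}
        t2 = {g: min(1.0, t1[g] + float(rng.uniform(0, 0.5))) for g in GRADES}
        assert predict_multilabel(scores, t2).grades <= predict_multilabel(scores, t1).grades


class TestPRCurve:
    def test_perfectly_separable(self):
        curve = pr_curve(np.array([0.9, 0.8, 0.3, 0.1]), np.array([1, 1, 0, 0]))
        assert curve.best_f1 == pytest.approx(1.0)

    def test_all_equal_scores_single_operating_point(self):
        curve = pr_curve(np.array([0.5, 0.5, 0.5, 0.5]), np.array([1, 0, 0, 1]))
        # the only informative point predicts everything positive:
        # precision = prevalence
        informative = curve.precision[curve.recall == 1.0]
        assert informative[0] == pytest.approx(0.5)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            pr_curve(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_best_threshold_lowest_on_ties(self):
        # both sentinel and the 0.2 threshold give identical confusion tables
        curve = pr_curve(np.array([0.9, 0.9, 0.2]), np.array([1, 1, 0]))
        assert curve.best_threshold == pytest.approx(0.2)

    def test_exhaustive_short_vectors_vs_oracle(self):
        """All label assignments and score patterns over a two-value grid
        up to length 6, against threshold-by-threshold enumeration."""
        grid = (0.3, 0.7)
        for n in range(2, 7):
            for scores in itertools.product(grid, repeat=n):
                for labels in itertools.product((0, 1), repeat=n):
                    if sum(labels) in (0, n):
                        continue
                    curve = pr_curve(np.array(scores), np.array(labels))
                    oracle = brute_pr_points(scores, labels)
                    for i, t in enumerate(curve.thresholds):
                        prec, rec, f1 = oracle[t]
                        assert curve.precision[i] == pytest.approx(prec)
                        assert curve.recall[i] == pytest.approx(rec)
                        assert curve.f1[i] == pytest.approx(f1)
                    assert curve.best_f1 == pytest.approx(max(p[2] for p in oracle.values()))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_random_vectors_against_sklearn(self, seed):
        """Cross-check the full curve against an independent implementation
        (sklearn sweeps the same operating points, minus the degenerate
        tail it pins to precision=1/recall=0)."""
        from sklearn.metrics import precision_recall_curve

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        scores = rng.uniform(size=n).round(2)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            return
        curve = pr_curve(scores, labels)
        prec_sk, rec_sk, thr_sk = precision_recall_curve(labels, scores)
        for t, p, r in zip(thr_sk, prec_sk, rec_sk):
            # sklearn's threshold t means "score >= t"; ours is strict, so
            # compare at the next-lower grid point
            ours = np.flatnonzero(curve.thresholds < t)
            i = ours[-1]
            assert curve.precision[i] == pytest.approx(p)
            assert curve.recall[i] == pytest.approx(r)

    def test_recall_spans_one_to_zero(self):
        curve = pr_curve(np.array([0.1, 0.4, 0.9]), np.array([0, 1, 1]))
        assert curve.recall[0] == 1.0 and curve.recall[-1] == 0.0


class _ConstantModel:
    """Stub sub-classifier producing fixed logits."""

    def __init__(self, logit_pos):
        self.logit_pos = logit_pos

    def forward(self, x, train=False):
        return np.tile([0.0, self.logit_pos], (len(x), 1))


class TestPredictScores:
    def _ensemble(self):
        return EnsembleModel(sub_models={G3: _ConstantModel(2.0),
                                         G4: _ConstantModel(0.0),
                                         G5: _ConstantModel(-2.0)})

    def test_scores_in_unit_interval(self):
        scores = predict_scores(self._ensemble(), np.zeros((3, 8, 8)))
        assert all(0.0 <= s <= 1.0 for s in scores.values())

    def test_symmetric_logits_give_half(self):
        scores = predict_scores(self._ensemble(), np.zeros((3, 8, 8)))
        assert scores[G4] == pytest.approx(0.5)

    def test_deterministic(self):
        x = np.random.default_rng(0).standard_normal((3, 8, 8))
        ens = self._ensemble()
        assert predict_scores(ens, x) == predict_scores(ens, x)


class TestEvaluateMetrics:
    def _labels(self, spec):
        out = []
        for grades in spec:
            gs = frozenset(grades)
            out.append(MultiLabel(grades=gs, nc=not gs))
        return out

    def test_perfect_predictions(self):
        refs = self._labels([{G3}, {G4, G5}, set(), {G5}])
        per_f1, acc, subset, _ = _report_for(refs, refs, [])
        assert all(v == 1.0 for v in per_f1.values())
        assert acc == 1.0 and subset == 1.0

    def test_complement_predictions_zero_f1(self):
        refs = self._labels([{G3}, {G4}, {G5}, set()])
        preds = self._labels([{G4, G5}, {G3, G5}, {G3, G4}, {G3, G4, G5}])
        per_f1, _, subset, _ = _report_for(refs, preds, [])
        assert all(v == 0.0 for v in per_f1.values())
        assert subset == 0.0

    def test_hand_worked_eight_patch_table(self):
        refs = self._labels([{G3}, {G3, G4}, {G4}, {G5}, set(), set(), {G4, G5}, {G3}])
        preds = self._labels([{G3}, {G4}, {G4}, set(), set(), {G3}, {G4, G5}, {G3}])
        per_f1, acc, subset, counts = _report_for(refs, preds, [])
        # G3: refs positives {0,1,7}, preds {0,5,7} -> tp=2 fp=1 fn=1
        assert per_f1["G3"] == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))
        # G4: refs {1,2,6}, preds {1?,no...} preds positives {1,2,6} -> tp=3
        assert per_f1["G4"] == pytest.approx(1.0)
        # G5: refs {3,6}, preds {6} -> tp=1 fp=0 fn=1
        assert per_f1["G5"] == pytest.approx(2 * 1 / (2 * 1 + 0 + 1))
        # NC: refs {4,5}, preds {3,4} -> tp=1 fp=1 fn=1
        assert per_f1["NC"] == pytest.approx(0.5)
        # accuracy: per-problem accuracies (NC 6/8, G3 6/8, G4 8/8, G5 7/8)
        assert acc == pytest.approx((6 + 6 + 8 + 7) / 32)
        assert subset == pytest.approx(5 / 8)  # patches 0,2,4,6,7 match exactly
        row = counts.set_index("class").loc["G3"]
        assert (row["tp"], row["fp"], row["fn"], row["tn"]) == (2, 1, 1, 4)

    def test_macro_f1_is_mean_of_per_class(self):
        refs = self._labels([{G3}, {G4}, set(), {G5}, {G3, G5}])
        preds = self._labels([{G3}, set(), set(), {G5}, {G3}])
        per_f1, acc, subset, counts = _report_for(refs, preds, [])
        report = EvalReport(per_class_f1=per_f1, macro_f1=float(np.mean(list(per_f1.values()))),
                            accuracy=acc, subset_accuracy=subset, counts=counts,
                            per_fold=pd.DataFrame(), n_eligible=5, n_excluded=0)
        assert report.macro_f1 == pytest.approx(np.mean(list(per_f1.values())))

    def test_inconsistent_macro_f1_rejected(self):
        with pytest.raises(ValueError):
            EvalReport(per_class_f1={"NC": 1.0, "G3": 0.0, "G4": 0.0, "G5": 0.0},
                       macro_f1=0.9, accuracy=0.5, subset_accuracy=0.5,
                       counts=pd.DataFrame(), per_fold=pd.DataFrame(),
                       n_eligible=1, n_excluded=0)
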