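"""Multi-label ensemble prediction, threshold selection and metrics.

Three one-vs-all binary CNNs (one per Gleason grade) score each patch
independently; a grade enters the predicted multi-label when its score
exceeds that grade's decision threshold, and the benign NC label is
issued when no grade does.  Thresholds are selected per grade as the
F1-optimal operating point of the validation precision-recall curve.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_formats import GRADES, GradeCode, LabelPolicy, Manifest, read_mask
from .relabel import MultiLabel, multilabel_from_mask
from .train import _softmax_pos, load_patch_batch, predict_logits

_GRADE_NAMES = {GradeCode.G3: "G3", GradeCode.G4: "G4", GradeCode.G5: "G5"}


@dataclasses.dataclass
class EnsembleModel:
    """Three one-vs-all sub-classifiers plus per-grade score thresholds."""

    sub_models: dict[GradeCode, object]
    thresholds: dict[GradeCode, float] = dataclasses.field(
        default_factory=lambda: {g: 0.5 for g in GRADES}
    )

    def __post_init__(self) -> None:
        if set(self.sub_models) != set(GRADES):
            raise ValueError(f"sub_models must cover exactly {[g.name for g in GRADES]}")
        for g, t in self.thresholds.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold for {g} outside [0,1]: {t}")


def predict_scores(ensemble: EnsembleModel, x: np.ndarray) -> dict[GradeCode, float]:
    """Positive-class softmax score of each sub-classifier for one patch.

    ``x`` is a preprocessed (3, S, S) or (1, 3, S, S) input.  Scores are
    independent probabilities and need not sum to one.
    """
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError(f"expected (N, 3, H, W) input, got shape {x.shape}")
    out = {}
    for g in GRADES:
        logits = ensemble.sub_models[g].forward(x, train=False)
        out[g] = float(_softmax_pos(logits)[0])
    return out


def predict_multilabel(
    scores: dict[GradeCode, float], thresholds: dict[GradeCode, float]
) -> MultiLabel:
    """Threshold the three scores into a multi-label.

    Grade g is asserted iff score_g > threshold_g (strict; ties are
    negative); NC iff no grade is asserted.
    """
    missing = [g.name for g in GRADES if g not in thresholds]
    if missing:
        raise ValueError(f"missing threshold(s) for {missing}")
    grades = frozenset(g for g in GRADES if scores[g] > thresholds[g])
    return MultiLabel(grades=grades, nc=not grades)


@dataclasses.dataclass
class PRCurve:
    """Precision/recall/F1 swept over score thresholds.

    The threshold grid is the sorted unique scores plus a sentinel below
    the minimum, so the curve spans recall 1 (everything predicted
    positive) down to recall 0 (nothing predicted; the top threshold
    equals the maximum score and prediction is strict ``score > t``).
    best_threshold maximizes F1, lowest threshold on ties.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    best_threshold: float
    best_f1: float

    def __post_init__(self) -> None:
        for arr in (self.precision, self.recall, self.f1):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError("PR values outside [0, 1]")
        if np.any(np.diff(self.recall) > 1e-12):
            raise ValueError("recall must be non-increasing in threshold")


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> PRCurve:
    """Precision-recall curve of one binary detector.

    At each threshold t, predictions are ``score > t``; precision is
    TP/(TP+FP) (1.0 when nothing is predicted), recall TP/(TP+FN), and
    F1 = 2PR/(P+R) (0 when P+R = 0).  Requires both label values.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("pr_curve requires both positive and negative labels")
    uniq = np.unique(scores)
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    precision = np.empty_like(thresholds)
    recall = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = scores > t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        precision[i] = tp / (tp + fp) if (tp + fp) else 1.0
        recall[i] = tp / n_pos
    with np.errstate(invalid="ignore"):
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    best = int(np.argmax(f1))  # first (lowest threshold) on ties
    return PRCurve(thresholds, precision, recall, f1,
                   best_threshold=float(thresholds[best]), best_f1=float(f1[best]))


# ---------------------------------------------------------------------------
# dataset-level scoring
# ---------------------------------------------------------------------------

def _reference_labels(manifest: Manifest, policy: LabelPolicy) -> list[MultiLabel]:
    return [
        multilabel_from_mask(read_mask(manifest.resolve(row["mask_path"])), policy)
        for _, row in manifest.frame.iterrows()
    ]


def ensemble_scores(ensemble: EnsembleModel, manifest: Manifest,
                    rows: list[int]) -> dict[GradeCode, np.ndarray]:
    """Positive-class scores of every sub-model over the given rows."""
    out: dict[GradeCode, np.ndarray] = {}
    for g in GRADES:
        model = ensemble.sub_models[g]
        x = load_patch_batch(manifest, rows, model.spec.input_size)
        out[g] = _softmax_pos(predict_logits(model, x))
    return out


def select_thresholds(
    ensemble: EnsembleModel, manifest: Manifest, policy: LabelPolicy,
    folds: list[str] | None = None,
) -> dict[GradeCode, float]:
    """Pick per-grade thresholds at the validation F1 optimum.

    For each grade, sweeps the PR curve of that sub-classifier's scores
    against the threshold-based reference labels on the validation
    patches and stores the F1-maximizing threshold in the ensemble.
    """
    sub = manifest.subset(folds) if folds is not None else manifest
    refs = _reference_labels(sub, policy)
    rows = [i for i, ml in enumerate(refs) if not ml.excluded]
    if not rows:
        raise ValueError("no eligible validation patches")
    scores = ensemble_scores(ensemble, sub, rows)
    chosen: dict[GradeCode, float] = {}
    for g in GRADES:
        y = np.array([int(g in refs[i].grades) for i in rows])
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(f"validation set degenerate for grade {g.name}")
        # softmax scores live strictly inside (0,1), so clamping the
        # below-minimum sentinel to 0 leaves the induced decision intact
        chosen[g] = float(np.clip(pr_curve(scores[g], y).best_threshold, 0.0, 1.0))
    ensemble.thresholds = chosen
    return chosen


@dataclasses.dataclass
class EvalReport:
    """Multi-label evaluation over {NC, G3, G4, G5}.

    ``macro_f1`` is the arithmetic mean of the four per-class F1 scores;
    ``accuracy`` is the macro average of the four per-problem binary
    accuracies; ``subset_accuracy`` the exact-match rate of the whole
    multi-label.  Sub-threshold-cancer patches are omitted from all
    metrics and counted in ``n_excluded``.
    """

    per_class_f1: dict[str, float]
    macro_f1: float
    accuracy: float
    subset_accuracy: float
    counts: pd.DataFrame  # per class: tp, fp, fn, tn
    per_fold: pd.DataFrame
    n_eligible: int
    n_excluded: int

    def __post_init__(self) -> None:
        mean = float(np.mean(list(self.per_class_f1.values())))
        if abs(mean - self.macro_f1) > 1e-12:
            raise ValueError("macro_f1 is not the mean of per-class F1")


_EVAL_CLASSES = ["NC", "G3", "G4", "G5"]


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, dict]:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    acc = (tp + tn) / max(1, tp + tn + fp + fn)
    return f1, acc, {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def _report_for(refs: list[MultiLabel], preds: list[MultiLabel],
                folds: list[str]) -> tuple[dict, float, float, pd.DataFrame]:
    def presence(ml: MultiLabel, cls: str) -> int:
        if cls == "NC":
            return int(ml.nc)
        return int(getattr(GradeCode, cls) in ml.grades)

    per_f1, per_acc, count_rows = {}, {}, []
    for cls in _EVAL_CLASSES:
        y_true = np.array([presence(r, cls) for r in refs])
        y_pred = np.array([presence(p, cls) for p in preds])
        f1, acc, counts = _binary_metrics(y_true, y_pred)
        per_f1[cls] = f1
        per_acc[cls] = acc
        count_rows.append({"class": cls, **counts})
    subset = float(np.mean([r == p for r, p in zip(refs, preds)])) if refs else 0.0
    return per_f1, float(np.mean(list(per_acc.values()))), subset, pd.DataFrame(count_rows)


def evaluate(
    ensemble: EnsembleModel, manifest: Manifest, policy: LabelPolicy,
    folds: list[str] | None = None,
) -> EvalReport:
    """Score every eligible patch and compare with reference multi-labels."""
    sub = manifest.subset(folds) if folds is not None else manifest
    refs_all = _reference_labels(sub, policy)
    rows = [i for i, ml in enumerate(refs_all) if not ml.excluded]
    n_excluded = len(refs_all) - len(rows)
    if not rows:
        raise ValueError("no eligible patches to evaluate")
    scores = ensemble_scores(ensemble, sub, rows)
    preds = [
        predict_multilabel({g: float(scores[g][j]) for g in GRADES}, ensemble.thresholds)
        for j in range(len(rows))
    ]
    refs = [refs_all[i] for i in rows]
    row_folds = [sub.frame.iloc[i]["fold"] for i in rows]

    per_f1, accuracy, subset, counts = _report_for(refs, preds, row_folds)
    fold_rows = []
    for fold in sorted(set(row_folds)):
        sel = [j for j, f in enumerate(row_folds) if f == fold]
        f_f1, f_acc, f_subset, _ = _report_for([refs[j] for j in sel],
                                               [preds[j] for j in sel], [])
        fold_rows.append({"fold": fold, "n": len(sel), "accuracy": f_acc,
                          "subset_accuracy": f_subset, "macro_f1": float(np.mean(list(f_f1.values()))),
                          **{f"f1_{k.lower()}": v for k, v in f_f1.items()}})
    return EvalReport(
        per_class_f1=per_f1,
        macro_f1=float(np.mean(list(per_f1.values()))),
        accuracy=accuracy,
        subset_accuracy=subset,
        counts=counts,
        per_fold=pd.DataFrame(fold_rows),
        n_eligible=len(rows),
        n_excluded=n_excluded,
    )
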