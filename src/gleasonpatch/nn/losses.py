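"""Classification losses and class-imbalance weighting."""

from __future__ import annotations

import numpy as np


def weighted_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy over a batch.

    L = sum_i w_{y_i} * (-log softmax(logits_i)_{y_i}) / sum_i w_{y_i},
    i.e. the weighted mean of per-sample negative log-likelihoods, so
    uniform weights reduce to plain cross-entropy.  Returns the scalar
    loss and its gradient w.r.t. the logits.
    """
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    if np.any(weights <= 0):
        raise ValueError("class weights must be positive")
    n, k = logits.shape
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    log_p = shifted - log_z
    w = weights[targets]
    w_sum = w.sum()
    nll = -log_p[np.arange(n), targets]
    loss = float((w * nll).sum() / w_sum)
    p = np.exp(log_p)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), targets] = 1.0
    dlogits = (p - onehot) * (w / w_sum)[:, None]
    return loss, dlogits


def default_class_weights(targets: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Inverse-frequency class weights: w_c = n_total / (n_classes * n_c).

    Balanced targets give uniform weights of 1; a 90/10 split gives the
    minority class weight 5 and the majority 5/9.  Raises if any class is
    absent (a one-vs-all problem needs examples of both classes).
    """
    targets = np.asarray(targets, dtype=np.int64)
    counts = np.bincount(targets, minlength=n_classes)
    if np.any(counts == 0):
        raise ValueError(f"every class needs at least one example, got counts {counts.tolist()}")
    return targets.size / (n_classes * counts.astype(np.float64))
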