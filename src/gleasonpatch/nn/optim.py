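"""Adam optimizer with head/backbone learning-rate groups and L2 penalty."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam with per-parameter learning-rate multipliers.

    Parameters flagged ``head`` use ``lr * head_multiplier`` (the
    fine-tuning convention of training a fresh classification head faster
    than pre-initialized feature layers).  L2 regularization adds
    ``l2 * w`` to the gradient of parameters flagged ``decay`` (conv/FC
    weights only — not biases or batch-norm parameters).
    """

    def __init__(self, params: list[Param], l2: float = 0.0, head_multiplier: float = 1.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.l2 = l2
        self.head_multiplier = head_multiplier
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.l2 * p.data if (self.l2 and p.decay) else p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            rate = lr * self.head_multiplier if p.head else lr
            p.data -= rate * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
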