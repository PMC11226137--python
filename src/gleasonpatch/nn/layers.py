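"""Neural-network layer primitives in NumPy with explicit backward passes.

All layers operate on NCHW float64 batches.  Each layer caches what its
backward pass needs during forward; ``backward`` consumes the gradient of
the loss w.r.t. the layer output and returns the gradient w.r.t. its
input, accumulating parameter gradients in :class:`Param` objects.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient and optimizer-facing flags.

    ``decay=True`` marks weights subject to L2 regularization (conv/FC
    weights; not biases or batch-norm parameters); ``head=True`` marks
    parameters of the classification head, which train at a higher
    learning rate during fine-tuning.
    """

    def __init__(self, data: np.ndarray, name: str, decay: bool = False, head: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name
        self.decay = decay
        self.head = head

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    """2-D convolution (cross-correlation), no bias, square kernel."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator, name: str, head: bool = False):
        self.k, self.stride, self.pad = k, stride, pad
        self.w = Param(_he_normal(rng, (c_out, c_in, k, k), c_in * k * k),
                       f"{name}.w", decay=True, head=head)
        self.params = [self.w]
        self._cols = None
        self._x_shape = None

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = x.shape
        ho, wo = self.out_hw(h, w)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        sn, sc, sh, sw = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, (n, c, k, k, ho, wo), (sn, sc, sh, sw, sh * s, sw * s)
        )
        self._cols = cols
        self._x_shape = x.shape
        out = np.tensordot(cols, self.w.data, axes=([1, 2, 3], [1, 2, 3]))
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.stride, self.pad
        n, c, h, w = self._x_shape
        ho, wo = dy.shape[2], dy.shape[3]
        # dW[o,c,a,b] = sum_{n,i,j} dy[n,o,i,j] * cols[n,c,a,b,i,j]
        self.w.grad += np.tensordot(dy, self._cols, axes=([0, 2, 3], [0, 4, 5]))
        dcols = np.einsum("ocab,noij->ncabij", self.w.data, dy)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for a in range(k):
            for b in range(k):
                dxp[:, :, a : a + s * ho : s, b : b + s * wo : s] += dcols[:, :, a, b]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return dy * g * inv_std[None, :, None, None]
        dxhat = dy * g
        mean_dxhat = dxhat.sum(axis=(0, 2, 3)) / m
        mean_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3)) / m
        dx = (dxhat
              - mean_dxhat[None, :, None, None]
              - xhat * mean_dxhat_xhat[None, :, None, None]) * inv_std[None, :, None, None]
        return dx


class ReLU:
    def __init__(self):
        self.params = []
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2 (even spatial dims required)."""

    def __init__(self):
        self.params = []
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class GlobalAvgPool:
    def __init__(self):
        self.params = []
        self._hw = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None], dy.shape + (h, w)) / (h * w)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 name: str, head: bool = False):
        self.w = Param(_he_normal(rng, (d_out, d_in), d_in), f"{name}.w",
                       decay=True, head=head)
        self.b = Param(np.zeros(d_out), f"{name}.b", head=head)
        self.params = [self.w, self.b]
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.data
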