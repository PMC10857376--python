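"""Minimal NumPy layers with explicit forward/backward passes.

The histogram tensors are small (9 channels, at most 32x32), so an im2col
convolution in double precision is fast enough for desk-scale training while
keeping every gradient auditable.  Layers cache what their backward pass
needs; parameters live in plain arrays so they can be copied, compared
bit-for-bit (layer freezing guarantees *exact* equality) and serialized.
"""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(
            f"spatial input {h}x{w} too small for kernel {k} with stride {stride}"
        )
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s[0], s[1], s[2], s[3], stride * s[2], stride * s[3]),
    )
    cols = np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo)
    return cols, (ho, wo)


def col2im(
    gcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
    out_hw: tuple[int, int],
) -> np.ndarray:
    n, c, h, w = x_shape
    ho, wo = out_hw
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    g6 = gcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            gx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += g6[
                :, :, i, j
            ]
    return gx[:, :, pad : pad + h, pad : pad + w]


class Conv2d:
    """k x k convolution; stride > 1 replaces pooling for downsampling."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int,
        rng: np.random.Generator,
        pad: int | None = None,
    ):
        self.k, self.stride = k, stride
        self.pad = k // 2 if pad is None else pad
        self.W = he_init(rng, (c_out, c_in, k, k), fan_in=c_in * k * k)
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (ho, wo) = im2col(x, self.k, self.stride, self.pad)
        wm = self.W.reshape(self.W.shape[0], -1)
        out = np.matmul(wm, cols) + self.b[None, :, None]
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        n, co = gout.shape[:2]
        g2 = gout.reshape(n, co, ho * wo)
        self.gW = np.tensordot(g2, cols, axes=([0, 2], [0, 2])).reshape(self.W.shape)
        self.gb = gout.sum(axis=(0, 2, 3))
        wm = self.W.reshape(co, -1)
        gcols = np.matmul(wm.T, g2)
        return col2im(gcols, x_shape, self.k, self.stride, self.pad, (ho, wo))


class BatchNorm2d:
    """Per-channel batch normalization with running statistics.

    In a frozen layer both the affine parameters and the running statistics
    are held fixed, and normalization always uses the running statistics.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum, self.eps = momentum, eps
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool, update_stats: bool = True) -> np.ndarray:
        if training and update_stats:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training and update_stats)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, batch_stats = self._cache
        self.ggamma = (gout * xhat).sum(axis=(0, 2, 3))
        self.gbeta = gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma[None, :, None, None]
        if not batch_stats:
            return gxhat * inv[None, :, None, None]
        m = gout.shape[0] * gout.shape[2] * gout.shape[3]
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return gx


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = he_init(rng, (d_in, d_out), fan_in=d_in)
        self.b = np.zeros(d_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ gout
        self.gb = gout.sum(axis=0)
        return gout @ self.W.T


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Dropout:
    """Inverted dropout; identity when not training or rate == 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask


class SGD:
    """Plain gradient descent; preserves the scale of penalty gradients
    (Adam's preconditioning does not), which matters when reasoning about
    strong anchoring penalties."""

    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for name, p in params.items():
            g = grads.get(name)
            if g is not None:
                p -= self.lr * g


class Adam:
    """Adam over a name->array parameter dict; frozen names are skipped."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, p in params.items():
            g = grads.get(name)
            if g is None:
                continue
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
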