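"""Minimal dense/convolutional layers with explicit forward/backward passes.

All arrays are float64, NCHW layout.  Every layer caches what its backward
pass needs during forward; ``backward(dy)`` accumulates parameter gradients
into ``Param.grad`` and returns the gradient w.r.t. its input.  The layers
are deliberately few: exactly what the autoencoder, diffusion U-Net and
segmentation U-Net in this package require.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "GroupNorm",
    "SiLU",
    "Upsample2x",
    "Linear",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: parameter iteration and train/eval-free simplicity."""

    def params(self):
        for v in vars(self).values():
            if isinstance(v, Param):
                yield v
            elif isinstance(v, Module):
                yield from v.params()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


class Conv2d(Module):
    """Same-padded 2-D convolution (odd kernel), stride 1 or 2, He init."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, rng=None, init_gain: float = 1.0):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        scale = init_gain * np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride = k, stride
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # (N,C,Ho,Wo,k,k)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        y = cols @ wmat.T + self.b.value[None, None, :]
        self._cache = (cols, (n, c, h, w), (ho, wo))
        return y.transpose(0, 2, 1).reshape(n, -1, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.k // 2
        cout = dy.shape[1]
        dym = np.ascontiguousarray(dy.reshape(n, cout, ho * wo).transpose(0, 2, 1))  # (N,HoWo,cout)
        wmat = self.w.value.reshape(cout, -1)
        self.w.grad += (
            dym.reshape(-1, cout).T @ cols.reshape(-1, cols.shape[-1])
        ).reshape(self.w.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dcols = (dym @ wmat).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class GroupNorm(Module):
    """Group normalization with learned per-channel scale and shift."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        if channels % groups != 0:
            groups = 1
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.groups, self.eps = groups, eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = xg.var(axis=(2, 3, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mu) * inv
        y = xhat.reshape(n, c, h, w) * self.gamma.value[None, :, None, None] + self.beta.value[
            None, :, None, None
        ]
        self._cache = (xhat, inv, (n, c, h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, (n, c, h, w) = self._cache
        g = self.groups
        xhat_f = xhat.reshape(n, c, h, w)
        self.gamma.grad += (dy * xhat_f).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.value[None, :, None, None]).reshape(n, g, c // g, h, w)
        m = (c // g) * h * w
        s1 = dxhat.sum(axis=(2, 3, 4), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(2, 3, 4), keepdims=True)
        dx = inv / m * (m * dxhat - s1 - xhat * s2)
        return dx.reshape(n, c, h, w)


class SiLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        s = sigmoid(x)
        self._cache = (x, s)
        return x * s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s = self._cache
        return dy * (s * (1.0 + x * (1.0 - s)))


class Upsample2x(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Linear(Module):
    def __init__(self, din: int, dout: int, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(1.0 / din), size=(dout, din)))
        self.b = Param(np.zeros(dout))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.w.grad += dy.T @ x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value
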