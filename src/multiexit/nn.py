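"""Minimal NumPy neural-network engine: layers, softmax, and Adam.

Implements exactly the primitives the multi-exit classifier needs — 3x3
same-padding convolutions (im2col), ReLU, 2x2 max-pooling, dense layers —
with explicit forward/backward passes.  Arrays are NCHW float64; gradients
are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Fan-in-scaled Gaussian init (appropriate for ReLU networks)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Backprop dL/dp through p = softmax(z); returns dL/dz.

    Uses dz = p * (dp - <dp, p>) rowwise; p and dp are (N, C).
    """
    inner = np.sum(dp * p, axis=-1, keepdims=True)
    return p * (dp - inner)


class Conv3x3:
    """3x3 convolution with padding 1 and stride 1 (spatial size preserved)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * 9
        self.W = Param(he_init(rng, (out_ch, fan_in), fan_in))
        self.b = Param(np.zeros(out_ch))
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (N, C, H, W, 3, 3) -> columns (N, H*W, C*9)
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9)
        out = cols @ self.W.value.T + self.b.value
        if train:
            self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        dflat = dout.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)  # (N, HW, F)
        self.W.grad += np.einsum("npf,npk->fk", dflat, cols)
        self.b.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ self.W.value  # (N, HW, C*9)
        dcols = dcols.reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2))
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2:
    """2x2 max pooling with stride 2; input spatial dims must be even."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial dims, got {h}x{w}")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = np.argmax(r, axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class Dense:
    """Fully connected layer on flattened inputs."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Param(he_init(rng, (out_dim, in_dim), in_dim))
        self.b = Param(np.zeros(out_dim))
        self.in_dim = in_dim
        self.out_dim = out_dim
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.W.grad += dout.T @ x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value


class Adam:
    """Adam optimizer over a list of Param objects."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
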