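"""Minimal CPU neural-network primitives used by the virtual-staining models.

Implements the small set of layers needed for the U-Net generator and the
patch discriminator — 2D convolution (stride 1 or 2, 'same' padding),
nearest-neighbour upsampling, instance normalisation and the usual pointwise
activations — each with a hand-written backward pass.  Convolutions are
evaluated as im2col + GEMM, which is what makes desk-scale training on a
single CPU practical.

All layers follow the same protocol: ``forward(x)`` caches what the backward
pass needs, ``backward(dy)`` returns the gradient with respect to the input
and accumulates parameter gradients into ``Param.grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N*Ho*Wo, C*k*k) patch matrix."""
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = cols.shape[:4]
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    """'Same'-padded convolution with stride 1 or 2 (even sizes halve exactly)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, dtype=DTYPE):
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.w = Param(w.astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.pad
        # symmetric padding preserves constant fields exactly, which keeps
        # whole-field and tiled inference consistent on flat regions
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="symmetric")
        cols = _im2col(xp, self.k, self.stride)
        ho = (h + 2 * p - self.k) // self.stride + 1
        wo = (w + 2 * p - self.k) // self.stride + 1
        y = cols @ self.w.value + self.b.value
        y = y.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, _, h, w = xshape
        _, _, ho, wo = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.w.grad += cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.w.value.T  # (N*Ho*Wo, C*k*k)
        dcols = dcols.reshape(n, ho, wo, self.c_in, self.k, self.k)
        p, s, k = self.pad, self.stride, self.k
        dxp = np.zeros((n, self.c_in, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2))
        # fold the symmetric-padding gradient back onto its source pixels
        for q in range(p):
            dxp[:, :, 2 * p - 1 - q] += dxp[:, :, q]
            dxp[:, :, -(2 * p - q)] += dxp[:, :, -(q + 1)]
        for q in range(p):
            dxp[:, :, :, 2 * p - 1 - q] += dxp[:, :, :, q]
            dxp[:, :, :, -(2 * p - q)] += dxp[:, :, :, -(q + 1)]
        return dxp[:, :, p:p + h, p:p + w]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation over the spatial axes (affine)."""

    def __init__(self, c: int, eps: float = 1e-5, dtype=DTYPE):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = xhat.shape[2] * xhat.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        # standard normalisation backward, reduced over the spatial axes
        t1 = dxhat - dxhat.mean(axis=(2, 3), keepdims=True)
        t2 = xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (t1 - t2)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y ** 2)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


def zero_grads(params: list[Param]) -> None:
    for p in params:
        p.grad[...] = 0.0


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, v in zip(params, state, strict=True):
        p.value[...] = v
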