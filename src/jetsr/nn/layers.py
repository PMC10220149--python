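"""Minimal layer framework with explicit forward/backward passes.

All activations are channels-first ``(batch, channels, D, H, W)`` float32.
Every layer caches what its backward pass needs during a training-mode
forward; ``backward`` returns the gradient w.r.t. the layer input and
accumulates parameter gradients on the ``Param`` objects.
"""

from __future__ import annotations

import numpy as np

from .ops import conv3d_backward_input, conv3d_backward_weights, conv3d_forward

__all__ = [
    "Param", "Module", "Conv3d", "Conv1x1", "LeakyReLU", "Upsample3d",
    "Sequential",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    """Symmetric fan-in scaled initialisation (He-style for leaky ReLU)."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv3d(Module):
    """Same-padded stride-1 3x3x3 convolution.

    ``init="he"`` draws symmetric fan-in-scaled weights; ``init="dirac"``
    adds a centre-tap identity over the leading ``min(c_in, c_out)``
    channels on top of down-scaled noise, so a stack of such layers passes
    its input through at initialisation (useful for short training
    schedules at small widths); ``init="zero"`` nulls the layer.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "conv", dtype=np.float32, init: str = "he"):
        self.c_in, self.c_out = c_in, c_out
        W = _he_init(rng, (3, 3, 3, c_in, c_out), 27 * c_in, dtype)
        if init == "dirac":
            W *= 0.1
            for j in range(min(c_in, c_out)):
                W[1, 1, 1, j, j] += 1.0
        elif init == "zero":
            W[...] = 0.0
        elif init != "he":
            raise ValueError(f"unknown init {init!r}")
        self.W = Param(f"{name}.W", W)
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=dtype))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return conv3d_forward(x, self.W.value, self.b.value)

    def backward(self, dy):
        dW, db = conv3d_backward_weights(self._x, dy)
        self.W.grad += dW
        self.b.grad += db
        return conv3d_backward_input(dy, self.W.value)


class Conv1x1(Module):
    """Pointwise (1x1x1) convolution: a per-voxel linear map over channels."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "conv1", dtype=np.float32, init: str = "he"):
        self.c_in, self.c_out = c_in, c_out
        W = _he_init(rng, (c_in, c_out), c_in, dtype)
        if init == "dirac":
            W *= 0.1
            for j in range(min(c_in, c_out)):
                W[j, j] += 1.0
        elif init == "zero":
            W[...] = 0.0
        elif init != "he":
            raise ValueError(f"unknown init {init!r}")
        self.W = Param(f"{name}.W", W)
        self.b = Param(f"{name}.b", np.zeros(c_out, dtype=dtype))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if train:
            self._x = x
        y = np.einsum("bcdhw,ce->bedhw", x, self.W.value, optimize=True)
        return y + self.b.value[None, :, None, None, None]

    def backward(self, dy):
        self.W.grad += np.einsum(
            "bcdhw,bedhw->ce", self._x, dy, optimize=True
        ).astype(self.W.grad.dtype)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        return np.einsum("bedhw,ce->bcdhw", dy, self.W.value, optimize=True)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._mask = None

    def forward(self, x, train=False):
        neg = x < 0
        if train:
            self._mask = neg
        return np.where(neg, self.alpha * x, x)

    def backward(self, dy):
        return np.where(self._mask, self.alpha * dy, dy)


def upsample_matrix(n_in: int, factor: int, dtype=np.float32) -> np.ndarray:
    """Linear-interpolation matrix ``(n_in * factor, n_in)`` per axis.

    Output sample ``i`` sits at ``i / factor`` in input index space
    (edge-clamped): DFT/k-space downsampling places LR sample ``j`` exactly
    on HR sample ``factor * j``, so upsampling is anchored at the shared
    corner, output ``factor * j`` reproduces input ``j``, and constants are
    preserved exactly.
    """
    n_out = n_in * factor
    U = np.zeros((n_out, n_in), dtype=dtype)
    for i in range(n_out):
        pos = i / factor
        lo = int(np.floor(pos))
        frac = pos - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        U[i, lo_c] += 1.0 - frac
        U[i, hi_c] += frac
    return U


class Upsample3d(Module):
    """Non-learned trilinear resize by an integer factor (separable)."""

    def __init__(self, factor: int = 4):
        self.factor = factor
        self._U: dict[int, np.ndarray] = {}

    def _mat(self, n_in: int, dtype) -> np.ndarray:
        if n_in not in self._U:
            self._U[n_in] = upsample_matrix(n_in, self.factor, dtype)
        return self._U[n_in]

    def _apply(self, x, mats):
        y = x
        for axis, U in zip((2, 3, 4), mats):
            y = np.moveaxis(
                np.tensordot(U, y, axes=([1], [axis])), 0, axis
            )
        return np.ascontiguousarray(y)

    def forward(self, x, train=False):
        self._in_dims = x.shape[2:]
        mats = [self._mat(n, x.dtype) for n in x.shape[2:]]
        return self._apply(x, mats)

    def backward(self, dy):
        mats = [self._mat(n, dy.dtype).T for n in self._in_dims]
        return self._apply(dy, mats)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def params(self):
        return [p for m in self.modules for p in m.params()]

    def forward(self, x, train=False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, dy):
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy
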