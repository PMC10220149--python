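"""Low-level 3D convolution kernels (channels-first layout).

Two interchangeable implementations of the same-padded, stride-1, 3x3x3
convolution: a numba row-vectorised direct kernel (default; fastest at the
small channel counts used here) and a pure-numpy shift-and-GEMM version that
doubles as an independent oracle in the tests.  Arrays are
``(batch, channels, D, H, W)``; weights are ``(3, 3, 3, C_in, C_out)``.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (a and callable(a[0])) else a[0]

__all__ = [
    "conv3d_forward",
    "conv3d_backward_input",
    "conv3d_backward_weights",
    "conv3d_forward_numpy",
    "HAVE_NUMBA",
]


@njit(cache=True, fastmath=True)
def _conv3d_fwd_kernel(xp, W, b, y):  # pragma: no cover - compiled
    B, Co, D, H, Wd = y.shape
    Ci = xp.shape[1]
    for bb in range(B):
        for co in range(Co):
            for d in range(D):
                for h in range(H):
                    row = y[bb, co, d, h]
                    for w in range(Wd):
                        row[w] = b[co]
                    for kd in range(3):
                        for kh in range(3):
                            for ci in range(Ci):
                                xrow = xp[bb, ci, d + kd, h + kh]
                                for kw in range(3):
                                    wv = W[kd, kh, kw, ci, co]
                                    for w in range(Wd):
                                        row[w] += wv * xrow[w + kw]


@njit(cache=True, fastmath=True)
def _conv3d_dw_kernel(xp, dy, dW, db):  # pragma: no cover - compiled
    B, Co, D, H, Wd = dy.shape
    Ci = xp.shape[1]
    for bb in range(B):
        for co in range(Co):
            for d in range(D):
                for h in range(H):
                    dyrow = dy[bb, co, d, h]
                    s = 0.0
                    for w in range(Wd):
                        s += dyrow[w]
                    db[co] += s
                    for kd in range(3):
                        for kh in range(3):
                            for ci in range(Ci):
                                xrow = xp[bb, ci, d + kd, h + kh]
                                for kw in range(3):
                                    acc = 0.0
                                    for w in range(Wd):
                                        acc += dyrow[w] * xrow[w + kw]
                                    dW[kd, kh, kw, ci, co] += acc


def _pad_spatial(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))


def conv3d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 3x3x3 convolution, channels-first."""
    if not HAVE_NUMBA:  # pragma: no cover
        return conv3d_forward_numpy(x, W, b)
    B, Ci, D, H, Wd = x.shape
    Co = W.shape[-1]
    y = np.empty((B, Co, D, H, Wd), dtype=x.dtype)
    _conv3d_fwd_kernel(_pad_spatial(x), W, b, y)
    return y


def conv3d_backward_input(dy: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. the input: convolution with the flipped, transposed
    kernel (the exact adjoint of the zero-padded forward map)."""
    W_adj = np.ascontiguousarray(
        W[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
    )
    zero_b = np.zeros(W_adj.shape[-1], dtype=dy.dtype)
    return conv3d_forward(dy, W_adj, zero_b)


def conv3d_backward_weights(
    x: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients w.r.t. weights and bias."""
    Ci, Co = x.shape[1], dy.shape[1]
    if HAVE_NUMBA:
        # accumulate in float64 regardless of the input dtype
        dW = np.zeros((3, 3, 3, Ci, Co), dtype=np.float64)
        db = np.zeros(Co, dtype=np.float64)
        _conv3d_dw_kernel(_pad_spatial(x), dy, dW, db)
        return dW.astype(x.dtype), db.astype(x.dtype)
    return _conv3d_dw_numpy(x, dy)  # pragma: no cover


def conv3d_forward_numpy(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shift-and-GEMM reference implementation (independent of numba)."""
    B, Ci, D, H, Wd = x.shape
    Co = W.shape[-1]
    xp = _pad_spatial(x)
    # flatten to channels-last for the GEMM
    y = np.zeros((B, D, H, Wd, Co), dtype=np.result_type(x, W))
    yf = y.reshape(-1, Co)
    yf += b
    for kd in range(3):
        for kh in range(3):
            for kw in range(3):
                xs = np.ascontiguousarray(
                    xp[:, :, kd:kd + D, kh:kh + H, kw:kw + Wd]
                    .transpose(0, 2, 3, 4, 1)
                ).reshape(-1, Ci)
                yf += xs @ W[kd, kh, kw]
    return np.ascontiguousarray(y.transpose(0, 4, 1, 2, 3))


def _conv3d_dw_numpy(x, dy):  # pragma: no cover
    B, Ci, D, H, Wd = x.shape
    Co = dy.shape[1]
    xp = _pad_spatial(x)
    dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 4, 1)).reshape(-1, Co)
    dW = np.zeros((3, 3, 3, Ci, Co), dtype=x.dtype)
    for kd in range(3):
        for kh in range(3):
            for kw in range(3):
                xs = np.ascontiguousarray(
                    xp[:, :, kd:kd + D, kh:kh + H, kw:kw + Wd]
                    .transpose(0, 2, 3, 4, 1)
                ).reshape(-1, Ci)
                dW[kd, kh, kw] = xs.T @ dyf
    return dW, dyf.sum(axis=0)
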