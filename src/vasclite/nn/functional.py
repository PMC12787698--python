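"""Low-level array ops for the NumPy network core.

All tensors are float32 NCHW. Convolutions are expressed through
im2col/col2im so forward and backward both reduce to BLAS matmuls.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "silu",
    "silu_grad",
    "relu",
    "relu_grad",
    "sigmoid",
    "im2col",
    "col2im",
    "conv_out_size",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable split on sign
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def silu(x: np.ndarray) -> np.ndarray:
    """x * sigmoid(x), elementwise."""
    return x * sigmoid(x)


def silu_grad(x: np.ndarray) -> np.ndarray:
    s = sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


def relu(x: np.ndarray) -> np.ndarray:
    """max(0, x), elementwise."""
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0).astype(x.dtype)


def conv_out_size(size: int, kernel: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def im2col(x: np.ndarray, kernel: int, stride: int, pad: int):
    """(N, C, H, W) -> patches (N, C, k*k, L) with L = Ho*Wo.

    Returns (cols, (Ho, Wo)). cols is a fresh contiguous array.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = conv_out_size(h, kernel, stride, pad)
    wo = conv_out_size(w, kernel, stride, pad)
    v = sliding_window_view(x, (kernel, kernel), axis=(2, 3))  # N,C,Hp,Wp,k,k
    v = v[:, :, ::stride, ::stride]  # N,C,Ho,Wo,k,k
    cols = v.transpose(0, 1, 4, 5, 2, 3).reshape(n, c, kernel * kernel, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


def col2im(
    cols: np.ndarray,
    x_shape: tuple,
    kernel: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Adjoint of im2col: scatter-add (N, C, k*k, L) patches back to (N, C, H, W)."""
    n, c, h, w = x_shape
    ho = conv_out_size(h, kernel, stride, pad)
    wo = conv_out_size(w, kernel, stride, pad)
    hp, wp = h + 2 * pad, w + 2 * pad
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kernel, kernel, ho, wo)
    for ki in range(kernel):
        he = ki + stride * ho
        for kj in range(kernel):
            we = kj + stride * wo
            out[:, :, ki:he:stride, kj:we:stride] += cols[:, :, ki, kj]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out
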