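"""Minimal layer library with explicit forward/backward passes.

Each layer caches what its backward pass needs on ``self`` during
``forward(..., training=True)``; ``backward`` consumes the incoming
gradient, accumulates parameter gradients, and returns the gradient
with respect to its input. Parameters and submodules self-register via
attribute assignment, so traversal (for counting, serialization, and
the optimizer) is generic.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F


class Parameter:
    """Trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "decay")

    def __init__(self, data: np.ndarray, decay: bool = True):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        # whether weight decay applies (conv/fc weights yes, bn/bias no)
        self.decay = decay

    @property
    def size(self) -> int:
        return int(self.data.size)


class Module:
    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, ModuleList):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self.__dict__.setdefault("_buffers", {})[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        self.__dict__["_buffers"][name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for n, p in self.__dict__.get("_params", {}).items():
            yield prefix + n, p
        for n, child in self.__dict__.get("_children", {}).items():
            yield from child.named_parameters(prefix + n + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple]:
        for n, b in self.__dict__.get("_buffers", {}).items():
            yield prefix + n, b
        for n, child in self.__dict__.get("_children", {}).items():
            yield from child.named_buffers(prefix + n + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self.__dict__.get("_children", {}).values():
            yield from child.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x, training: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList:
    """Ordered container participating in module traversal."""

    def __init__(self, mods=()):
        self._list = list(mods)

    def append(self, mod: Module):
        self._list.append(mod)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def named_parameters(self, prefix: str = ""):
        for i, mod in enumerate(self._list):
            yield from mod.named_parameters(f"{prefix}{i}.")

    def named_buffers(self, prefix: str = ""):
        for i, mod in enumerate(self._list):
            yield from mod.named_buffers(f"{prefix}{i}.")

    def modules(self):
        for mod in self._list:
            yield from mod.modules()


def kaiming_normal(rng: np.random.Generator, shape, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_out)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    """Bias-free 2-D convolution, 'same'-style padding (k-1)//2."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = kernel
        self.stride = stride
        self.pad = (kernel - 1) // 2
        rng = rng or np.random.default_rng()
        fan_out = out_ch * kernel * kernel
        self.weight = Parameter(
            kaiming_normal(rng, (out_ch, in_ch, kernel, kernel), fan_out))

    def forward(self, x, training: bool = False):
        n, c, h, w = x.shape
        if self.kernel == 1 and self.stride == 1:
            xr = x.reshape(n, c, h * w)
            wr = self.weight.data.reshape(self.out_ch, c)
            out = (wr @ xr).reshape(n, self.out_ch, h, w)
            if training:
                self._cache = ("1x1", xr, (n, c, h, w))
            return out
        cols, (ho, wo) = F.im2col(x, self.kernel, self.stride, self.pad)
        cols = cols.reshape(n, c * self.kernel * self.kernel, ho * wo)
        wr = self.weight.data.reshape(self.out_ch, -1)
        out = (wr @ cols).reshape(n, self.out_ch, ho, wo)
        if training:
            self._cache = ("kxk", cols, (n, c, h, w))
        return out

    def backward(self, dout):
        kind, cols, x_shape = self._cache
        n = x_shape[0]
        dr = dout.reshape(n, self.out_ch, -1)
        dw = np.tensordot(dr, cols, axes=([0, 2], [0, 2]))
        self.weight.grad += dw.reshape(self.weight.data.shape)
        wr = self.weight.data.reshape(self.out_ch, -1)
        dcols = np.matmul(wr.T, dr)  # N, C*k*k, L
        if kind == "1x1":
            return dcols.reshape(x_shape)
        c = x_shape[1]
        dcols = dcols.reshape(n, c, self.kernel * self.kernel, -1)
        return F.col2im(dcols, x_shape, self.kernel, self.stride, self.pad)


class DepthwiseConv2d(Module):
    """Per-channel convolution (groups == channels), bias-free."""

    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.channels = channels
        self.kernel = kernel
        self.stride = stride
        self.pad = (kernel - 1) // 2
        rng = rng or np.random.default_rng()
        fan_out = kernel * kernel  # per-channel fan-out
        self.weight = Parameter(
            kaiming_normal(rng, (channels, 1, kernel, kernel), fan_out))

    def forward(self, x, training: bool = False):
        # shift-and-add: k*k vectorized fused passes, no im2col buffer
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = F.conv_out_size(h, k, s, p)
        wo = F.conv_out_size(w, k, s, p)
        wk = self.weight.data[:, 0]  # (C, k, k)
        out = np.zeros((n, c, ho, wo), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                out += (wk[:, ki, kj][None, :, None, None]
                        * xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s])
        if training:
            self._cache = (xp, x.shape, (ho, wo))
        return out

    def backward(self, dout):
        xp, x_shape, (ho, wo) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        wk = self.weight.data[:, 0]
        dxp = np.zeros_like(xp)
        dw = np.empty_like(wk)
        for ki in range(k):
            for kj in range(k):
                sl = (slice(None), slice(None),
                      slice(ki, ki + s * ho, s), slice(kj, kj + s * wo, s))
                dw[:, ki, kj] = np.einsum("nchw,nchw->c", xp[sl], dout)
                dxp[sl] += wk[:, ki, kj][None, :, None, None] * dout
        self.weight.grad += dw[:, None]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    # EfficientNet convention: eps 1e-3, momentum 0.01
    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.01):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32), decay=False)
        self.bias = Parameter(np.zeros(channels, dtype=np.float32), decay=False)
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x, training: bool = False):
        if training:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            nelem = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * nelem / max(nelem - 1, 1)
            self._set_buffer("running_mean",
                             ((1 - m) * self.running_mean + m * mean).astype(np.float32))
            self._set_buffer("running_var",
                             ((1 - m) * self.running_var + m * unbiased).astype(np.float32))
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
            self._cache = (xhat, invstd, nelem)
        else:
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * invstd[None, :, None, None]
        return (self.weight.data[None, :, None, None] * xhat
                + self.bias.data[None, :, None, None])

    def backward(self, dout):
        xhat, invstd, nelem = self._cache
        axes = (0, 2, 3)
        sum_dy = np.einsum("nchw->c", dout)
        sum_dy_xhat = np.einsum("nchw,nchw->c", dout, xhat)
        self.weight.grad += sum_dy_xhat
        self.bias.grad += sum_dy
        # dx = w*invstd*(dy - mean(dy) - xhat*mean(dy*xhat)), fused in-place
        scale = (self.weight.data * invstd)[None, :, None, None]
        dx = xhat  # reuse the cache buffer
        dx *= (-sum_dy_xhat / nelem)[None, :, None, None]
        dx += dout
        dx -= (sum_dy / nelem)[None, :, None, None]
        dx *= scale
        self._cache = None
        return dx


class Activation(Module):
    """Main nonlinearity site; ``kind`` in {'silu', 'relu'}."""

    def __init__(self, kind: str):
        if kind not in ("silu", "relu"):
            raise ValueError(f"unknown activation kind: {kind!r}")
        self.kind = kind

    def forward(self, x, training: bool = False):
        if training:
            self._cache = x
        return F.silu(x) if self.kind == "silu" else F.relu(x)

    def backward(self, dout):
        x = self._cache
        g = F.silu_grad(x) if self.kind == "silu" else F.relu_grad(x)
        return dout * g


class SqueezeExcite(Module):
    """Channel gating: GAP -> FC reduce -> activation -> FC restore -> sigmoid -> scale."""

    def __init__(self, channels: int, squeezed: int, act_kind: str,
                 rng: np.random.Generator | None = None):
        self.channels = channels
        self.squeezed = squeezed
        self.act_kind = act_kind
        rng = rng or np.random.default_rng()
        self.w1 = Parameter(kaiming_normal(rng, (squeezed, channels), squeezed))
        self.b1 = Parameter(np.zeros(squeezed, dtype=np.float32), decay=False)
        self.w2 = Parameter(kaiming_normal(rng, (channels, squeezed), channels))
        self.b2 = Parameter(np.zeros(channels, dtype=np.float32), decay=False)

    @property
    def present(self) -> bool:
        return True

    def forward(self, x, training: bool = False):
        if x.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: input has {x.shape[1]}, SE expects {self.channels}")
        s = x.mean(axis=(2, 3))  # squeeze: N, C
        z1 = s @ self.w1.data.T + self.b1.data
        a1 = F.silu(z1) if self.act_kind == "silu" else F.relu(z1)
        z2 = a1 @ self.w2.data.T + self.b2.data
        g = F.sigmoid(z2)  # excitation weights in (0, 1)
        out = x * g[:, :, None, None]
        if training:
            self._cache = (x, s, z1, a1, g)
        return out

    def backward(self, dout):
        x, s, z1, a1, g = self._cache
        hw = x.shape[2] * x.shape[3]
        dx = dout * g[:, :, None, None]
        dg = np.sum(dout * x, axis=(2, 3))
        dz2 = dg * g * (1.0 - g)
        self.w2.grad += dz2.T @ a1
        self.b2.grad += dz2.sum(axis=0)
        da1 = dz2 @ self.w2.data
        gk = F.silu_grad(z1) if self.act_kind == "silu" else F.relu_grad(z1)
        dz1 = da1 * gk
        self.w1.grad += dz1.T @ s
        self.b1.grad += dz1.sum(axis=0)
        ds = dz1 @ self.w1.data
        dx += ds[:, :, None, None] / hw
        return dx


class DummySE(Module):
    """Identity occupying the SE position so graph structure is unchanged."""

    present = False

    def forward(self, x, training: bool = False):
        return x

    def backward(self, dout):
        return dout


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        r = 1.0 / np.sqrt(out_features)
        self.weight = Parameter(
            rng.uniform(-r, r, size=(out_features, in_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32), decay=False)

    def forward(self, x, training: bool = False):
        if training:
            self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout):
        x = self._cache
        self.weight.grad += dout.T @ x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class Dropout(Module):
    """Inverted dropout on (N, C) feature vectors."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training: bool = False):
        if not training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._cache = mask
        return x * mask

    def backward(self, dout):
        if self.p == 0.0:
            return dout
        return dout * self._cache


class GlobalAvgPool(Module):
    def forward(self, x, training: bool = False):
        if training:
            self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._cache
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)
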