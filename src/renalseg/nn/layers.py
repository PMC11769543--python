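"""A compact numpy engine for 3-D segmentation networks.

Tensors are single samples laid out channels-first, ``(C, X, Y, Z)``; a
mini-batch is processed as repeated forward/backward passes with gradient
accumulation.  Convolutions are evaluated as k^3 shifted BLAS matmuls —
one (out_ch x in_ch) product per kernel offset against a shifted view of
the input — which keeps temporaries at input size instead of an im2col
buffer k^3 times larger.  Every module implements an explicit ``backward``
that is validated against finite differences in the test suite.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from scipy.special import erf, expit

from ._kernels import HAVE_NUMBA, conv3d_bwd_w, conv3d_bwd_x, conv3d_fwd

# below this in_ch*out_ch product the jitted direct kernels beat BLAS
_NUMBA_CHANNEL_LIMIT = 2048


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: recursive parameter collection and grad reset."""

    def parameters(self) -> List[Param]:
        out: List[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Module):
    """3-D convolution, kernel k, stride s, symmetric zero padding k//2."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, bias=True, pad=None,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel ** 3
        self.weight = Param(_he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in, dtype), "conv.w")
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "conv.b") if bias else None
        self._cache = None

    def _shift(self, xp, i, j, l, out_shape):
        # contiguous copy of the (i, j, l)-shifted, stride-subsampled input
        s = self.stride
        Xo, Yo, Zo = out_shape
        xs = xp[:, i:i + (Xo - 1) * s + 1:s,
                j:j + (Yo - 1) * s + 1:s,
                l:l + (Zo - 1) * s + 1:s]
        return np.ascontiguousarray(xs).reshape(xp.shape[0], -1)

    @property
    def _jit_ok(self):
        return HAVE_NUMBA and self.in_ch * self.out_ch <= _NUMBA_CHANNEL_LIMIT

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        if train:
            self._cache = (xp, x.shape)
        out_shape = tuple((n + 2 * p - k) // s + 1 for n in x.shape[1:])
        W = self.weight.data.astype(x.dtype, copy=False)
        if self._jit_ok:
            out = conv3d_fwd(np.ascontiguousarray(xp), np.ascontiguousarray(W),
                             s, *out_shape)
        else:
            # k^3 shifted BLAS matmuls (temporaries stay at input size)
            N = int(np.prod(out_shape))
            of = np.zeros((self.out_ch, N), dtype=x.dtype)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        of += W[:, :, i, j, l] @ self._shift(xp, i, j, l, out_shape)
            out = of.reshape((self.out_ch,) + out_shape)
        if self.bias is not None:
            out += self.bias.data.astype(x.dtype)[:, None, None, None]
        return out

    def backward(self, gy):
        assert getattr(self, "_cache", None) is not None, \
            "backward before forward(train=True)"
        xp, xshape = self._cache
        self._cache = None
        k, s, p = self.kernel, self.stride, self.pad
        O, Xo, Yo, Zo = gy.shape
        g2 = gy.reshape(O, -1)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=1)
        W = self.weight.data
        if self._jit_ok:
            xpc = np.ascontiguousarray(xp)
            gyc = np.ascontiguousarray(gy)
            self.weight.grad += conv3d_bwd_w(xpc, gyc, s, k)
            gxp = conv3d_bwd_x(gyc, np.ascontiguousarray(W.astype(gy.dtype, copy=False)),
                               s, *xp.shape[1:])
        else:
            gxp = np.zeros(xp.shape, dtype=gy.dtype)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        xs = self._shift(xp, i, j, l, (Xo, Yo, Zo))
                        self.weight.grad[:, :, i, j, l] += g2 @ xs.T
                        m = (W[:, :, i, j, l].T @ g2).reshape(self.in_ch, Xo, Yo, Zo)
                        gxp[:, i:i + (Xo - 1) * s + 1:s,
                            j:j + (Yo - 1) * s + 1:s,
                            l:l + (Zo - 1) * s + 1:s] += m
        X, Y, Z = xshape[1:]
        return gxp[:, p:p + X, p:p + Y, p:p + Z] if p else gxp


class ConvTranspose3d(Module):
    """Deconvolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, in_ch, out_ch, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(_he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch * 8, dtype), "deconv.w")
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "deconv.b")
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        C, X, Y, Z = x.shape
        W2 = self.weight.data.reshape(C, self.out_ch * 8).astype(x.dtype, copy=False)
        t = W2.T @ x.reshape(C, X * Y * Z)  # (O*8, N)
        t = t.reshape(self.out_ch, 2, 2, 2, X, Y, Z)
        out = np.ascontiguousarray(np.transpose(t, (0, 4, 1, 5, 2, 6, 3))).reshape(
            self.out_ch, 2 * X, 2 * Y, 2 * Z)
        out += self.bias.data.astype(x.dtype)[:, None, None, None]
        return out

    def backward(self, gy):
        x = self._x
        self._x = None
        O = self.out_ch
        C = self.in_ch
        X, Y, Z = x.shape[1:]
        gyr = gy.reshape(O, X, 2, Y, 2, Z, 2)
        # back to (O*8, N) layout matching forward's t
        g8 = np.ascontiguousarray(np.transpose(gyr, (0, 2, 4, 6, 1, 3, 5))).reshape(
            O * 8, X * Y * Z)
        xf = x.reshape(C, X * Y * Z)
        self.weight.grad += (xf @ g8.T).reshape(self.weight.data.shape)
        self.bias.grad += gy.sum(axis=(1, 2, 3))
        W2 = self.weight.data.reshape(C, O * 8)
        return (W2 @ g8).reshape(C, X, Y, Z)


class NearestUpsample(Module):
    """Parameter-free 2x nearest-neighbour upsampling."""

    def forward(self, x, train=False):
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, gy):
        C, X, Y, Z = gy.shape
        return gy.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(2, 4, 6))


class InstanceNorm3d(Module):
    """Per-channel normalisation over the spatial axes, with affine scale."""

    def __init__(self, ch, eps=1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(ch, dtype=dtype), "in.gamma")
        self.beta = Param(np.zeros(ch, dtype=dtype), "in.beta")
        self._cache = None

    def forward(self, x, train=False):
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        if train:
            self._cache = (xhat, std)
        g = self.gamma.data.astype(x.dtype)[:, None, None, None]
        b = self.beta.data.astype(x.dtype)[:, None, None, None]
        return g * xhat + b

    def backward(self, gy):
        xhat, std = self._cache
        g = self.gamma.data[:, None, None, None]
        self.gamma.grad += (gy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += gy.sum(axis=(1, 2, 3))
        m1 = gy.mean(axis=(1, 2, 3), keepdims=True)
        m2 = (gy * xhat).mean(axis=(1, 2, 3), keepdims=True)
        gx = (g / std) * (gy - m1 - xhat * m2)
        self._cache = None
        return gx


class LeakyReLU(Module):
    def __init__(self, slope=0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gy):
        gx = np.where(self._mask, gy, self.slope * gy)
        self._mask = None
        return gx


class Sigmoid(Module):
    def __init__(self):
        self._y = None

    def forward(self, x, train=False):
        y = expit(x)
        if train:
            self._y = y
        return y

    def backward(self, gy):
        y = self._y
        self._y = None
        return gy * y * (1.0 - y)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, train=False):
        for m in self.modules:
            x = m(x, train=train)
        return x

    def backward(self, gy):
        for m in reversed(self.modules):
            gy = m.backward(gy)
        return gy


# -------------------------------------------------- token-level pieces (ViT)

class Linear(Module):
    """Dense layer on the trailing feature axis of (..., F) token arrays."""

    def __init__(self, in_f, out_f, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (out_f, in_f), in_f, dtype), "lin.w")
        self.bias = Param(np.zeros(out_f, dtype=dtype), "lin.b")
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.weight.data.T.astype(x.dtype) + self.bias.data.astype(x.dtype)

    def backward(self, gy):
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        gf = gy.reshape(-1, gy.shape[-1])
        self.weight.grad += gf.T @ xf
        self.bias.grad += gf.sum(axis=0)
        self._x = None
        return (gy @ self.weight.data).reshape(x.shape)


class LayerNorm(Module):
    """Normalisation over the trailing feature axis of token arrays."""

    def __init__(self, dim, eps=1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(dim, dtype=dtype), "ln.gamma")
        self.beta = Param(np.zeros(dim, dtype=dtype), "ln.beta")
        self._cache = None

    def forward(self, x, train=False):
        mu = x.mean(axis=-1, keepdims=True)
        std = np.sqrt(x.var(axis=-1, keepdims=True) + self.eps)
        xhat = (x - mu) / std
        if train:
            self._cache = (xhat, std)
        return self.gamma.data.astype(x.dtype) * xhat + self.beta.data.astype(x.dtype)

    def backward(self, gy):
        xhat, std = self._cache
        self.gamma.grad += (gy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.beta.grad += gy.reshape(-1, gy.shape[-1]).sum(axis=0)
        g = self.gamma.data
        m1 = (gy * g).mean(axis=-1, keepdims=True)
        m2 = (gy * g * xhat).mean(axis=-1, keepdims=True)
        gx = (gy * g - m1 - xhat * m2) / std
        self._cache = None
        return gx


class GELU(Module):
    def __init__(self):
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))

    def backward(self, gy):
        x = self._x
        phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        self._x = None
        return gy * (cdf + x * phi)


def softmax_last(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(y, gy):
    return y * (gy - (gy * y).sum(axis=-1, keepdims=True))
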