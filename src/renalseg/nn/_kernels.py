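"""Numba-compiled direct 3-D convolution kernels.

These avoid the per-offset array copies of the matmul formulation, which
dominate run time at the small channel counts used in CPU-scale training.
Stride-1 kernels accumulate each contiguous z-row into a local buffer so
the inner loops vectorise; strided (downsampling) convolutions fall back
to scalar kernels, which is cheap because their outputs are 8x smaller.
``fastmath`` reassociates the summation, so results differ from the BLAS
path at float rounding level but remain bit-identical run to run.

``HAVE_NUMBA`` gates the dispatch; the matmul path in ``layers`` remains
as a pure-numpy fallback and as the reference these kernels are tested
against.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*a, **kw):  # type: ignore[misc]
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, fastmath=True)
def _fwd_s1(xp, w, Xo, Yo, Zo):
    O, C, k = w.shape[0], w.shape[1], w.shape[2]
    y = np.empty((O, Xo, Yo, Zo), dtype=xp.dtype)
    acc = np.empty(Zo, dtype=xp.dtype)
    for o in range(O):
        for a in range(Xo):
            for b in range(Yo):
                for d in range(Zo):
                    acc[d] = 0.0
                for c in range(C):
                    for i in range(k):
                        for j in range(k):
                            row = xp[c, a + i, b + j]
                            for l in range(k):
                                wv = w[o, c, i, j, l]
                                for d in range(Zo):
                                    acc[d] += wv * row[d + l]
                for d in range(Zo):
                    y[o, a, b, d] = acc[d]
    return y


@njit(cache=True, fastmath=True)
def _bwd_w_s1(xp, gy, k):
    O = gy.shape[0]
    C = xp.shape[0]
    Xo, Yo, Zo = gy.shape[1], gy.shape[2], gy.shape[3]
    gw = np.zeros((O, C, k, k, k), dtype=xp.dtype)
    for o in range(O):
        for c in range(C):
            for i in range(k):
                for j in range(k):
                    for a in range(Xo):
                        for b in range(Yo):
                            rowg = gy[o, a, b]
                            rowx = xp[c, a + i, b + j]
                            for l in range(k):
                                acc = 0.0
                                for d in range(Zo):
                                    acc += rowg[d] * rowx[d + l]
                                gw[o, c, i, j, l] += acc
    return gw


@njit(cache=True, fastmath=True)
def _fwd_sn(xp, w, s, Xo, Yo, Zo):
    O, C, k = w.shape[0], w.shape[1], w.shape[2]
    y = np.empty((O, Xo, Yo, Zo), dtype=xp.dtype)
    acc = np.empty(Zo, dtype=xp.dtype)
    for o in range(O):
        for a in range(Xo):
            for b in range(Yo):
                for d in range(Zo):
                    acc[d] = 0.0
                for c in range(C):
                    for i in range(k):
                        for j in range(k):
                            row = xp[c, a * s + i, b * s + j]
                            for l in range(k):
                                wv = w[o, c, i, j, l]
                                strided = row[l::s]
                                for d in range(Zo):
                                    acc[d] += wv * strided[d]
                for d in range(Zo):
                    y[o, a, b, d] = acc[d]
    return y


@njit(cache=True, fastmath=True)
def _bwd_w_sn(xp, gy, s, k):
    O = gy.shape[0]
    C = xp.shape[0]
    Xo, Yo, Zo = gy.shape[1], gy.shape[2], gy.shape[3]
    gw = np.zeros((O, C, k, k, k), dtype=xp.dtype)
    for o in range(O):
        for c in range(C):
            for i in range(k):
                for j in range(k):
                    for a in range(Xo):
                        for b in range(Yo):
                            rowg = gy[o, a, b]
                            rowx = xp[c, a * s + i, b * s + j]
                            for l in range(k):
                                strided = rowx[l::s]
                                acc = 0.0
                                for d in range(Zo):
                                    acc += rowg[d] * strided[d]
                                gw[o, c, i, j, l] += acc
    return gw


@njit(cache=True, fastmath=True)
def _bwd_x_sn(gy, w, s, Xp, Yp, Zp):
    O = gy.shape[0]
    C = w.shape[1]
    k = w.shape[2]
    Xo, Yo, Zo = gy.shape[1], gy.shape[2], gy.shape[3]
    gxp = np.zeros((C, Xp, Yp, Zp), dtype=gy.dtype)
    for c in range(C):
        for o in range(O):
            for i in range(k):
                for j in range(k):
                    for a in range(Xo):
                        for b in range(Yo):
                            rowg = gy[o, a, b]
                            xv = gxp[c, a * s + i, b * s + j]
                            for l in range(k):
                                wv = w[o, c, i, j, l]
                                strided = xv[l::s]
                                for d in range(Zo):
                                    strided[d] += wv * rowg[d]
    return gxp


def conv3d_fwd(xp, w, s, Xo, Yo, Zo):
    if s == 1:
        return _fwd_s1(xp, w, Xo, Yo, Zo)
    return _fwd_sn(xp, w, s, Xo, Yo, Zo)


def conv3d_bwd_w(xp, gy, s, k):
    if s == 1:
        return _bwd_w_s1(xp, gy, k)
    return _bwd_w_sn(xp, gy, s, k)


def conv3d_bwd_x(gy, w, s, Xp, Yp, Zp):
    if s == 1:
        # input gradient of a stride-1 correlation is a full correlation of
        # the zero-padded output gradient with the transposed, flipped kernel
        k = w.shape[2]
        q = k - 1
        gp = np.pad(gy, ((0, 0), (q, q), (q, q), (q, q)))
        wt = np.ascontiguousarray(w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
        return _fwd_s1(gp, wt, Xp, Yp, Zp)
    return _bwd_x_sn(gy, w, s, Xp, Yp, Zp)
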