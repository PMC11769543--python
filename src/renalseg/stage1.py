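"""Stage one of the dual-stage pipeline: kidney organ segmentation and VOIs.

The default organ backend is a shifted-window (Swin-style) transformer
encoder — four steps of two window-attention blocks each, alternating
unshifted and shifted windows — feeding a CNN decoder of residual blocks
with instance normalisation, deconvolution upsampling and a pointwise
convolution + sigmoid head.  A small pure-CNN backend (a residual UNet) is
provided as a drop-in alternative for CPU-scale runs; stage one is a
pluggable interface and any network with the same forward contract works.

From the binary kidney mask the module extracts at most the two largest
26-connected components (left/right kidney), takes each tight bounding box
and expands it by 25 % per axis (12.5 % per side), clipped to the grid:
the expanded volumes of interest handed to stage two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .grids import CtVolume, LabelMask, Voi
from .metrics import CONNECTIVITY_26
from .nn import (
    Conv3d,
    GELU,
    LayerNorm,
    Linear,
    Module,
    Sigmoid,
    softmax_backward,
    softmax_last,
)
from .tumor_net import ResidualBlock, TumorNetConfig, TumorNet


@dataclass
class OrganNetConfig:
    encoder_steps: int = 4
    transformer_blocks_per_step: int = 2
    window_input_size: int = 128  # per-axis input window extent
    base_channels: int = 24
    window_size: int = 7  # shifted-window partition extent per axis
    num_heads: int = 3
    backend: str = "swin"  # "swin" | "cnn"
    leaky_slope: float = 0.01
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.encoder_steps < 1:
            raise ValueError("encoder_steps must be >= 1")
        if self.window_input_size % (2 ** self.encoder_steps):
            raise ValueError(
                f"window_input_size {self.window_input_size} must be divisible "
                f"by 2^{self.encoder_steps}"
            )


class SwinBlock3d(Module):
    """One shifted-window attention block: W-MSA/SW-MSA + MLP, pre-norm.

    Windows are cyclic-shifted by half a window on alternating blocks; the
    attention mask for wrapped tokens is omitted (a documented
    simplification appropriate at phantom scale).
    """

    def __init__(self, ch, window, heads, shift, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if ch % heads:
            raise ValueError(f"channels {ch} not divisible by heads {heads}")
        self.ch, self.window, self.heads, self.shift = ch, window, heads, shift
        self.norm1 = LayerNorm(ch, dtype=dtype)
        self.qkv = Linear(ch, 3 * ch, rng=rng, dtype=dtype)
        self.proj = Linear(ch, ch, rng=rng, dtype=dtype)
        self.norm2 = LayerNorm(ch, dtype=dtype)
        self.mlp1 = Linear(ch, 4 * ch, rng=rng, dtype=dtype)
        self.gelu = GELU()
        self.mlp2 = Linear(4 * ch, ch, rng=rng, dtype=dtype)
        self._cache = None

    def _partition(self, x):
        # (C, X, Y, Z) -> (nW, w^3, C) with cyclic shift and zero padding
        w, s = self.window, self.shift
        t = np.moveaxis(x, 0, -1)  # (X, Y, Z, C)
        if s:
            t = np.roll(t, (-s, -s, -s), axis=(0, 1, 2))
        shape = t.shape[:3]
        pads = [(0, (-n) % w) for n in shape]
        if any(p[1] for p in pads):
            t = np.pad(t, pads + [(0, 0)])
        nx, ny, nz = [n // w for n in t.shape[:3]]
        t = t.reshape(nx, w, ny, w, nz, w, self.ch)
        t = np.transpose(t, (0, 2, 4, 1, 3, 5, 6)).reshape(nx * ny * nz, w ** 3, self.ch)
        return t, shape, (nx, ny, nz)

    def _unpartition(self, t, shape, grid):
        w, s = self.window, self.shift
        nx, ny, nz = grid
        t = t.reshape(nx, ny, nz, w, w, w, self.ch)
        t = np.transpose(t, (0, 3, 1, 4, 2, 5, 6)).reshape(nx * w, ny * w, nz * w, self.ch)
        t = t[: shape[0], : shape[1], : shape[2]]
        if s:
            t = np.roll(t, (s, s, s), axis=(0, 1, 2))
        return np.moveaxis(t, -1, 0)

    def forward(self, x, train=False):
        C, h = self.ch, self.heads
        d = C // h
        scale = 1.0 / math.sqrt(d)
        t, shape, grid = self._partition(x)
        nW, n, _ = t.shape
        hn = self.norm1(t, train)
        qkv = self.qkv(hn, train).reshape(nW, n, 3, h, d)
        q = np.transpose(qkv[:, :, 0], (0, 2, 1, 3))  # (nW, h, n, d)
        k = np.transpose(qkv[:, :, 1], (0, 2, 1, 3))
        v = np.transpose(qkv[:, :, 2], (0, 2, 1, 3))
        att = softmax_last(np.einsum("whnd,whmd->whnm", q, k) * scale)
        o = np.einsum("whnm,whmd->whnd", att, v)
        o = np.transpose(o, (0, 2, 1, 3)).reshape(nW, n, C)
        t1 = t + self.proj(o, train)
        hm = self.norm2(t1, train)
        t2 = t1 + self.mlp2(self.gelu(self.mlp1(hm, train), train), train)
        if train:
            self._cache = (shape, grid, q, k, v, att, scale)
        return self._unpartition(t2, shape, grid)

    def backward(self, gy):
        shape, grid, q, k, v, att, scale = self._cache
        self._cache = None
        nW, h, n, d = q.shape
        C = self.ch
        # re-partition the incoming spatial gradient into windows
        gt2, _, _ = self._partition(gy)
        gmlp = self.mlp2.backward(gt2)
        gmlp = self.gelu.backward(gmlp)
        gmlp = self.mlp1.backward(gmlp)
        gt1 = gt2 + self.norm2.backward(gmlp)
        go = self.proj.backward(gt1)
        go = np.transpose(go.reshape(nW, n, h, d), (0, 2, 1, 3))
        gatt = np.einsum("whnd,whmd->whnm", go, v)
        gv = np.einsum("whnm,whnd->whmd", att, go)
        gscore = softmax_backward(att, gatt) * scale
        gq = np.einsum("whnm,whmd->whnd", gscore, k)
        gk = np.einsum("whnm,whnd->whmd", gscore, q)
        gqkv = np.zeros((nW, n, 3, h, d), dtype=gy.dtype)
        gqkv[:, :, 0] = np.transpose(gq, (0, 2, 1, 3))
        gqkv[:, :, 1] = np.transpose(gk, (0, 2, 1, 3))
        gqkv[:, :, 2] = np.transpose(gv, (0, 2, 1, 3))
        ghn = self.qkv.backward(gqkv.reshape(nW, n, 3 * C))
        gt = gt1 + self.norm1.backward(ghn)
        return self._unpartition(gt, shape, grid)


class SwinOrganNet(Module):
    """Swin-style encoder (4 steps x 2 blocks) with a residual CNN decoder."""

    def __init__(self, cfg: OrganNetConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        C = cfg.base_channels
        w, hd, slope = cfg.window_size, cfg.num_heads, cfg.leaky_slope
        self.embed = Conv3d(1, C, kernel=2, stride=2, pad=0, rng=rng, dtype=dtype)
        self.stages: List[List[SwinBlock3d]] = []
        self.merges: List[Conv3d] = []
        ch = C
        for step in range(cfg.encoder_steps):
            blocks = [
                SwinBlock3d(ch, w, hd, shift=0 if b % 2 == 0 else w // 2,
                            rng=rng, dtype=dtype)
                for b in range(cfg.transformer_blocks_per_step)
            ]
            self.stages.append(blocks)
            if step < cfg.encoder_steps - 1:
                self.merges.append(Conv3d(ch, 2 * ch, kernel=2, stride=2, pad=0,
                                          rng=rng, dtype=dtype))
                ch *= 2
        # decoder: residual blocks + deconv upsampling back to full resolution
        from .nn import ConvTranspose3d  # local import to avoid cycle noise
        self.dec_blocks: List[ResidualBlock] = []
        self.dec_ups: List[ConvTranspose3d] = []
        widths = [C * 2 ** i for i in range(cfg.encoder_steps)]
        self.bottleneck = ResidualBlock(widths[-1], widths[-1], 1, slope, rng, dtype)
        for i in range(cfg.encoder_steps - 2, -1, -1):
            self.dec_ups.append(ConvTranspose3d(widths[i + 1], widths[i], rng=rng, dtype=dtype))
            self.dec_blocks.append(ResidualBlock(2 * widths[i], widths[i], 1, slope, rng, dtype))
        self.final_up = ConvTranspose3d(widths[0], widths[0], rng=rng, dtype=dtype)
        self.final_block = ResidualBlock(widths[0], widths[0], 1, slope, rng, dtype)
        self.head = Conv3d(widths[0], 1, 1, rng=rng, dtype=dtype)
        self.out_act = Sigmoid()

    def parameters(self):
        out = self.embed.parameters()
        for blocks in self.stages:
            for b in blocks:
                out.extend(b.parameters())
        for m in self.merges:
            out.extend(m.parameters())
        out.extend(self.bottleneck.parameters())
        for u, b in zip(self.dec_ups, self.dec_blocks):
            out.extend(u.parameters())
            out.extend(b.parameters())
        out.extend(self.final_up.parameters())
        out.extend(self.final_block.parameters())
        out.extend(self.head.parameters())
        return out

    def forward(self, x, train=False):
        div = 2 ** self.cfg.encoder_steps
        if any(s % div for s in x.shape[1:]):
            raise ValueError(f"input extent {x.shape[1:]} must be divisible by {div}")
        h = self.embed(x, train)
        skips = []
        for i, blocks in enumerate(self.stages):
            for b in blocks:
                h = b(h, train)
            skips.append(h)
            if i < len(self.merges):
                h = self.merges[i](h, train)
        d = self.bottleneck(skips[-1], train)
        for up, blk, skip in zip(self.dec_ups, self.dec_blocks, reversed(skips[:-1])):
            d = up(d, train)
            d = blk(np.concatenate([d, skip], axis=0), train)
        d = self.final_up(d, train)
        d = self.final_block(d, train)
        return self.out_act(self.head(d, train), train)

    def backward(self, gy):
        g = self.out_act.backward(gy)
        g = self.head.backward(g)
        g = self.final_block.backward(g)
        g = self.final_up.backward(g)
        widths = [self.cfg.base_channels * 2 ** i for i in range(self.cfg.encoder_steps)]
        gskips = [None] * self.cfg.encoder_steps
        # decoder was applied deep -> shallow (skip indices steps-2 .. 0);
        # walk it in reverse application order (skip 0 upward)
        skip_order = list(range(0, self.cfg.encoder_steps - 1))
        for up, blk, sidx in zip(reversed(self.dec_ups), reversed(self.dec_blocks), skip_order):
            g = blk.backward(g)
            gup, gskip = g[: widths[sidx]], g[widths[sidx]:]
            gskips[sidx] = gskip
            g = up.backward(gup)
        gtop = self.bottleneck.backward(g)
        gskips[-1] = gtop if gskips[-1] is None else gskips[-1] + gtop
        g_from_above = None
        for i in range(self.cfg.encoder_steps - 1, -1, -1):
            g = gskips[i] if g_from_above is None else gskips[i] + g_from_above
            for b in reversed(self.stages[i]):
                g = b.backward(g)
            g_from_above = self.merges[i - 1].backward(g) if i > 0 else g
        return self.embed.backward(g_from_above)

    def describe(self):
        return [
            {"step": i + 1,
             "transformer_blocks": len(blocks),
             "channels": self.cfg.base_channels * 2 ** i}
            for i, blocks in enumerate(self.stages)
        ]


class CnnOrganNet(TumorNet):
    """Small residual-UNet organ backend for CPU-scale training."""

    def __init__(self, cfg: OrganNetConfig, n_stages=3, channels=(8, 16, 32),
                 blocks=(1, 1, 2), patch=(64, 64, 64)):
        self.organ_cfg = cfg
        super().__init__(TumorNetConfig(
            n_stages=n_stages, channels=channels, residual_blocks=blocks,
            patch_size=patch, batch_size=2, attention_gates=False,
            leaky_slope=cfg.leaky_slope, seed=cfg.seed, dtype=cfg.dtype,
        ))


def build_organ_net(cfg: Optional[OrganNetConfig] = None) -> Module:
    """Instantiate the stage-one organ network chosen by ``cfg.backend``."""
    cfg = cfg or OrganNetConfig()
    if cfg.backend == "swin":
        return SwinOrganNet(cfg)
    if cfg.backend == "cnn":
        return CnnOrganNet(cfg)
    raise ValueError(f"unknown stage-one backend {cfg.backend!r}")


# ------------------------------------------------------- inference and VOIs

def _gaussian_window(shape, sigma_frac=0.125, dtype=np.float32):
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij", sparse=True)
    w = np.ones(shape, dtype=np.float64)
    for g, n in zip(grids, shape):
        sigma = max(n * sigma_frac, 1.0)
        w = w * np.exp(-0.5 * ((g - (n - 1) / 2) / sigma) ** 2)
    return np.maximum(w, 1e-3).astype(dtype)


def sliding_window_predict(data: np.ndarray, net: Module, window: Tuple[int, int, int],
                           overlap: float = 0.5) -> np.ndarray:
    """Gaussian-blended sliding-window probabilities over a whole volume.

    Volumes smaller than the window on any axis are symmetrically padded
    and the prediction cropped back.
    """
    orig_shape = data.shape
    pads = [(max(0, (w - n)) // 2, max(0, w - n) - max(0, (w - n)) // 2)
            for n, w in zip(data.shape, window)]
    if any(p[0] or p[1] for p in pads):
        data = np.pad(data, pads, mode="symmetric")
    shape = data.shape
    step = [max(1, int(round(w * (1 - overlap)))) for w in window]
    starts = []
    for n, w, s in zip(shape, window, step):
        ax = list(range(0, max(n - w, 0) + 1, s))
        if ax[-1] != n - w:
            ax.append(n - w)
        starts.append(sorted(set(ax)))
    acc = np.zeros(shape, dtype=np.float32)
    norm = np.zeros(shape, dtype=np.float32)
    gw = _gaussian_window(window)
    for x0 in starts[0]:
        for y0 in starts[1]:
            for z0 in starts[2]:
                sl = (slice(x0, x0 + window[0]), slice(y0, y0 + window[1]),
                      slice(z0, z0 + window[2]))
                patch = data[sl][None].astype(np.float32)
                prob = net(patch)[0]
                acc[sl] += prob * gw
                norm[sl] += gw
    out = acc / norm
    crop_sl = tuple(slice(p[0], p[0] + n) for p, n in zip(pads, orig_shape))
    return out[crop_sl]


def segment_kidney(vol: CtVolume, net: Module, window: Tuple[int, int, int],
                   threshold: float = 0.5, overlap: float = 0.5,
                   fill_holes: bool = True) -> LabelMask:
    """Binary kidney mask from sliding-window organ-net inference.

    Interior holes are filled by default: the kidney organ is simply
    connected, and hypodense intrarenal tumors otherwise punch holes into
    the organ mask.
    """
    prob = sliding_window_predict(vol.data, net, window, overlap)
    mask = prob >= threshold
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return LabelMask(data=mask.astype(np.int16), spacing=vol.spacing,
                     origin=vol.origin)


def calibrate_organ_threshold(net: Module, cases, window: Tuple[int, int, int],
                              thresholds=(0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
                              fill_holes: bool = True, overlap: float = 0.5) -> float:
    """Pick the organ probability threshold maximising median training Dice.

    Short training runs leave the sigmoid head poorly calibrated; sweeping
    the threshold on (a subset of) the *training* volumes and freezing the
    best value into the pipeline costs one inference pass per volume and
    transfers to unseen cases because it corrects a property of the model,
    not of any particular image.
    """
    from .metrics import dice as _dice, voxel_confusion  # local: avoid cycle

    probs = [(sliding_window_predict(v.data, net, window, overlap), m)
             for v, m in cases]
    best_thr, best_score = thresholds[0], -1.0
    for thr in thresholds:
        scores = []
        for p, m in probs:
            mask = p >= thr
            if fill_holes:
                mask = ndimage.binary_fill_holes(mask)
            scores.append(_dice(voxel_confusion(mask, m.data >= 1)))
        score = float(np.median(scores))
        if score > best_score:
            best_thr, best_score = float(thr), score
    return best_thr


def expand_box(start, stop, shape, expansion: float = 0.25) -> Voi:
    """Expand a tight box by ``expansion`` of each axis extent, then clip.

    The expanded extent is ``round(extent * (1 + expansion))`` (half the
    margin on each side, left side receiving the floor), clipped to grid
    bounds.
    """
    new_start, new_stop = [], []
    src_extent = tuple(b - a for a, b in zip(start, stop))
    for a, b, n in zip(start, stop, shape):
        ext = b - a
        target = int(np.floor(ext * (1.0 + expansion) + 0.5))
        margin = target - ext
        lo = a - margin // 2
        hi = b + (margin - margin // 2)
        new_start.append(max(0, lo))
        new_stop.append(min(n, hi))
    return Voi(start=tuple(new_start), stop=tuple(new_stop),
               source_extent=src_extent, expansion=expansion)


def extract_vois(kidney_mask: LabelMask, expansion: float = 0.25,
                 min_component_voxels: int = 50, max_components: int = 2) -> List[Voi]:
    """Expanded bounding boxes of the (at most two) largest kidney components.

    26-connected components smaller than ``min_component_voxels`` are
    ignored; an empty mask yields an empty list ("no kidney found").
    """
    binary = kidney_mask.data > 0
    labeled, n = ndimage.label(binary, structure=CONNECTIVITY_26)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, n + 1))
    keep = [i + 1 for i in np.argsort(sizes)[::-1][:max_components]
            if sizes[i] >= min_component_voxels]
    objects = ndimage.find_objects(labeled)
    vois = []
    for comp in sorted(keep):
        sl = objects[comp - 1]
        start = tuple(s.start for s in sl)
        stop = tuple(s.stop for s in sl)
        vois.append(expand_box(start, stop, kidney_mask.data.shape, expansion))
    return sorted(vois, key=lambda v: v.start)
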