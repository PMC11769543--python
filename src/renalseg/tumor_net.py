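"""The Kidney Tumor 3D UNet: residual encoder, attention-gated skips.

The encoder has six stages by default, with feature widths
(32, 64, 128, 256, 320, 320) and (1, 3, 4, 6, 6, 6) residual blocks per
stage; resolution halves between consecutive stages via a strided
convolution inside the first residual unit of each stage, so a
192 x 128 x 128 patch bottoms out at 6 x 4 x 4.  The decoder mirrors the
encoder with one convolution per stage and deconvolution upsampling;
each skip connection passes through an additive attention gate (project
skip and gating features to a common width, sum, nonlinearity, pointwise
projection to one channel, sigmoid, elementwise multiply).  LeakyReLU and
instance normalisation are used throughout; the head is a pointwise
convolution with a sigmoid over a single tumor channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .nn import (
    Conv3d,
    ConvTranspose3d,
    InstanceNorm3d,
    LeakyReLU,
    Module,
    NearestUpsample,
    Sigmoid,
)


@dataclass
class TumorNetConfig:
    n_stages: int = 6
    channels: Tuple[int, ...] = (32, 64, 128, 256, 320, 320)
    residual_blocks: Tuple[int, ...] = (1, 3, 4, 6, 6, 6)
    decoder_convs_per_stage: int = 1
    leaky_slope: float = 0.01
    attention_gates: bool = True
    patch_size: Tuple[int, int, int] = (192, 128, 128)
    batch_size: int = 5
    in_channels: int = 1
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if len(self.channels) != self.n_stages or len(self.residual_blocks) != self.n_stages:
            raise ValueError("channels and residual_blocks must have n_stages entries")
        div = 2 ** (self.n_stages - 1)
        if any(p % div for p in self.patch_size):
            raise ValueError(
                f"patch size {self.patch_size} must be divisible by 2^(n_stages-1) = {div}"
            )

    def bottleneck_extent(self) -> Tuple[int, ...]:
        div = 2 ** (self.n_stages - 1)
        return tuple(p // div for p in self.patch_size)


class ResidualBlock(Module):
    """conv-IN-LReLU-conv-IN plus an identity (or projected) skip, LReLU out."""

    def __init__(self, in_ch, out_ch, stride=1, slope=0.01, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride=stride, rng=rng, dtype=dtype)
        self.norm1 = InstanceNorm3d(out_ch, dtype=dtype)
        self.act1 = LeakyReLU(slope)
        self.conv2 = Conv3d(out_ch, out_ch, 3, rng=rng, dtype=dtype)
        self.norm2 = InstanceNorm3d(out_ch, dtype=dtype)
        if in_ch != out_ch or stride != 1:
            self.proj = Conv3d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng, dtype=dtype)
            self.proj_norm = InstanceNorm3d(out_ch, dtype=dtype)
        else:
            self.proj = None
            self.proj_norm = None
        self.act_out = LeakyReLU(slope)

    def forward(self, x, train=False):
        h = self.conv1(x, train)
        h = self.norm1(h, train)
        h = self.act1(h, train)
        h = self.conv2(h, train)
        h = self.norm2(h, train)
        if self.proj is not None:
            s = self.proj_norm(self.proj(x, train), train)
        else:
            s = x
        return self.act_out(h + s, train)

    def backward(self, gy):
        g = self.act_out.backward(gy)
        gh = self.norm2.backward(g)
        gh = self.conv2.backward(gh)
        gh = self.act1.backward(gh)
        gh = self.norm1.backward(gh)
        gx = self.conv1.backward(gh)
        if self.proj is not None:
            gx = gx + self.proj.backward(self.proj_norm.backward(g))
        else:
            gx = gx + g
        return gx


class AttentionGate(Module):
    """Additive attention gate modulating a skip connection.

    The gating signal (the coarser decoder feature map) is upsampled to the
    skip resolution, both fields are projected pointwise to a common width,
    summed, passed through a nonlinearity, projected to one channel and
    squashed with a sigmoid; the resulting per-voxel coefficients in (0, 1)
    multiply the skip features.
    """

    def __init__(self, skip_ch, gate_ch, inter_ch=None, slope=0.01, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        inter_ch = inter_ch or max(skip_ch // 2, 1)
        self.up = NearestUpsample()
        self.w_skip = Conv3d(skip_ch, inter_ch, 1, rng=rng, dtype=dtype)
        self.w_gate = Conv3d(gate_ch, inter_ch, 1, rng=rng, dtype=dtype)
        self.act = LeakyReLU(slope)
        self.psi = Conv3d(inter_ch, 1, 1, rng=rng, dtype=dtype)
        self.sig = Sigmoid()
        self._cache = None

    def forward_pair(self, skip, gate, train=False):
        g_up = self.up(gate, train)
        a = self.w_skip(skip, train) + self.w_gate(g_up, train)
        a = self.act(a, train)
        alpha = self.sig(self.psi(a, train), train)  # (1, X, Y, Z)
        if train:
            self._cache = (skip, alpha)
        return skip * alpha

    # Module protocol: treat (skip, gate) tuple as the input
    def forward(self, x, train=False):
        return self.forward_pair(*x, train=train)

    def backward(self, gy):
        skip, alpha = self._cache
        self._cache = None
        gskip = gy * alpha
        galpha = (gy * skip).sum(axis=0, keepdims=True)
        ga = self.psi.backward(self.sig.backward(galpha))
        ga = self.act.backward(ga)
        gskip = gskip + self.w_skip.backward(ga)
        ggate = self.up.backward(self.w_gate.backward(ga))
        return gskip, ggate

    def coefficients(self, skip, gate):
        """The per-voxel attention map alpha, for inspection."""
        g_up = self.up(gate)
        a = self.act(self.w_skip(skip) + self.w_gate(g_up))
        return self.sig(self.psi(a))


class _DecoderStage(Module):
    def __init__(self, deep_ch, skip_ch, n_convs, use_gate, slope, rng, dtype):
        self.gate = AttentionGate(skip_ch, deep_ch, slope=slope, rng=rng, dtype=dtype) \
            if use_gate else None
        self.up = ConvTranspose3d(deep_ch, skip_ch, rng=rng, dtype=dtype)
        convs = []
        in_ch = 2 * skip_ch
        for _ in range(n_convs):
            convs.append(Conv3d(in_ch, skip_ch, 3, rng=rng, dtype=dtype))
            convs.append(InstanceNorm3d(skip_ch, dtype=dtype))
            convs.append(LeakyReLU(slope))
            in_ch = skip_ch
        self.convs = convs
        self.skip_ch = skip_ch

    def forward_pair(self, deep, skip, train=False):
        up = self.up(deep, train)
        gated = self.gate.forward_pair(skip, deep, train) if self.gate else skip
        h = np.concatenate([up, gated], axis=0)
        for m in self.convs:
            h = m(h, train)
        return h

    def forward(self, x, train=False):
        return self.forward_pair(*x, train=train)

    def backward(self, gy):
        g = gy
        for m in reversed(self.convs):
            g = m.backward(g)
        gup, ggated = g[: self.skip_ch], g[self.skip_ch:]
        gdeep = self.up.backward(gup)
        if self.gate:
            gskip, ggate = self.gate.backward(ggated)
            gdeep = gdeep + ggate
        else:
            gskip = ggated
        return gdeep, gskip


class TumorNet(Module):
    """Residual attention-gated 3D UNet over a single tumor channel."""

    def __init__(self, cfg: TumorNetConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels
        slope = cfg.leaky_slope
        self.encoder: List[List[ResidualBlock]] = []
        in_ch = cfg.in_channels
        for i in range(cfg.n_stages):
            blocks = []
            stride = 1 if i == 0 else 2
            blocks.append(ResidualBlock(in_ch, ch[i], stride, slope, rng, dtype))
            for _ in range(cfg.residual_blocks[i] - 1):
                blocks.append(ResidualBlock(ch[i], ch[i], 1, slope, rng, dtype))
            self.encoder.append(blocks)
            in_ch = ch[i]
        self.decoder: List[_DecoderStage] = []
        for i in range(cfg.n_stages - 2, -1, -1):
            self.decoder.append(
                _DecoderStage(ch[i + 1], ch[i], cfg.decoder_convs_per_stage,
                              cfg.attention_gates, slope, rng, dtype)
            )
        self.head = Conv3d(ch[0], 1, 1, rng=rng, dtype=dtype)
        self.out_act = Sigmoid()
        self._skips: Optional[list] = None

    # -- flatten submodules for parameter collection
    def parameters(self):
        out = []
        for blocks in self.encoder:
            for b in blocks:
                out.extend(b.parameters())
        for d in self.decoder:
            out.extend(d.parameters())
        out.extend(self.head.parameters())
        return out

    def forward(self, x, train=False):
        div = 2 ** (self.cfg.n_stages - 1)
        if any(s % div for s in x.shape[1:]):
            raise ValueError(
                f"input extent {x.shape[1:]} not divisible by {div} "
                f"(n_stages = {self.cfg.n_stages})"
            )
        skips = []
        h = x
        for blocks in self.encoder:
            for b in blocks:
                h = b(h, train)
            skips.append(h)
        if train:
            self._skips = skips
        deep = skips[-1]
        for stage, i in zip(self.decoder, range(self.cfg.n_stages - 2, -1, -1)):
            deep = stage.forward_pair(deep, skips[i], train)
        logits = self.head(deep, train)
        return self.out_act(logits, train)

    def backward(self, gy):
        g = self.out_act.backward(gy)
        g = self.head.backward(g)
        # decoder stages were applied deep -> shallow over skip indices
        # n-2 .. 0, so backward walks them in reverse application order
        gskips = [None] * self.cfg.n_stages
        for stage, i in zip(reversed(self.decoder), range(0, self.cfg.n_stages - 1)):
            gdeep, gskip = stage.backward(g)
            gskips[i] = gskip
            g = gdeep
        gskips[self.cfg.n_stages - 1] = g
        # encoder stage i output feeds both decoder skip i and stage i+1
        g_from_above = None
        for i in range(self.cfg.n_stages - 1, -1, -1):
            g = gskips[i] if g_from_above is None else gskips[i] + g_from_above
            for b in reversed(self.encoder[i]):
                g = b.backward(g)
            g_from_above = g
        self._skips = None
        return g_from_above

    def describe(self) -> List[dict]:
        """Per-stage audit table: width, residual blocks, output extent."""
        rows = []
        extent = self.cfg.patch_size
        for i in range(self.cfg.n_stages):
            if i > 0:
                extent = tuple(e // 2 for e in extent)
            rows.append({
                "stage": i + 1,
                "channels": self.cfg.channels[i],
                "residual_blocks": self.cfg.residual_blocks[i],
                "output_extent": extent,
            })
        return rows


def build_tumor_net(cfg: Optional[TumorNetConfig] = None) -> TumorNet:
    """Instantiate the Kidney Tumor 3D UNet from its configuration."""
    return TumorNet(cfg or TumorNetConfig())


def tiny_tumor_config(patch=(32, 32, 32), seed: int = 0) -> TumorNetConfig:
    """A 3-stage desk-scale configuration for CPU training runs."""
    return TumorNetConfig(
        n_stages=3,
        channels=(8, 16, 32),
        residual_blocks=(1, 2, 2),
        patch_size=patch,
        batch_size=2,
        seed=seed,
    )
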