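"""Patch-based training loops for both stages.

Patches are sampled with a configurable fraction centred on foreground
voxels (foreground oversampling), optionally augmented, and optimised
against the DiceCE loss — SGD with nesterov momentum and polynomial
learning-rate decay for the tumor stage, AdamW for the organ stage.
Runs are bit-reproducible for a fixed seed in single-threaded CPU mode.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .augment import AugmentParams, random_augment
from .grids import CtVolume, LabelMask
from .nn import SGD, AdamW, Module, dice_ce_loss, polynomial_lr
from .preprocess import IntensityStats


@dataclass
class TrainConfig:
    stage: str = "tumor"  # "organ" | "tumor"
    optimizer: str = "sgd"  # "sgd" | "adamw"
    lr: float = 1e-3
    momentum: float = 0.99
    nesterov: bool = True
    weight_decay: float = 0.0
    epochs: int = 20
    patches_per_volume: int = 2
    batch_size: int = 2
    patch_size: Tuple[int, int, int] = (32, 32, 32)
    foreground_oversampling: float = 0.5
    target_label: str = "tumor"  # "kidney" (labels >= 1) | "tumor" (label == 2)
    augment: Optional[AugmentParams] = None
    augment_prob: float = 0.5
    seed: int = 0
    lr_power: float = 0.9

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.foreground_oversampling <= 1.0:
            raise ValueError("foreground_oversampling must lie in [0, 1]")

    @classmethod
    def organ_default(cls, **kw) -> "TrainConfig":
        kw.setdefault("stage", "organ")
        kw.setdefault("optimizer", "adamw")
        kw.setdefault("lr", 3.5e-4)
        kw.setdefault("weight_decay", 1e-2)
        kw.setdefault("target_label", "kidney")
        return cls(**kw)

    @classmethod
    def tumor_default(cls, **kw) -> "TrainConfig":
        kw.setdefault("stage", "tumor")
        kw.setdefault("optimizer", "sgd")
        kw.setdefault("lr", 1e-3)
        kw.setdefault("target_label", "tumor")
        return cls(**kw)


def target_field(mask: LabelMask, target_label: str) -> np.ndarray:
    if target_label == "kidney":
        return (mask.data >= 1).astype(np.float32)
    if target_label == "tumor":
        return (mask.data == 2).astype(np.float32)
    raise ValueError(f"unknown target label {target_label!r}")


def sample_patch(vol_data: np.ndarray, tgt: np.ndarray, patch: Sequence[int],
                 rng: np.random.Generator, foreground: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Extract one training patch, optionally centred on a foreground voxel.

    Volumes smaller than the patch on an axis are symmetrically padded.
    """
    pads = [(max(0, p - n) // 2, max(0, p - n) - max(0, p - n) // 2)
            for n, p in zip(vol_data.shape, patch)]
    if any(p[0] or p[1] for p in pads):
        vol_data = np.pad(vol_data, pads, mode="symmetric")
        tgt = np.pad(tgt, pads)
    shape = vol_data.shape
    if foreground:
        fg = np.argwhere(tgt > 0)
        if len(fg):
            center = fg[rng.integers(0, len(fg))]
        else:
            center = [rng.integers(0, n) for n in shape]
        start = [int(np.clip(c - p // 2, 0, n - p))
                 for c, p, n in zip(center, patch, shape)]
    else:
        start = [int(rng.integers(0, n - p + 1)) for p, n in zip(patch, shape)]
    sl = tuple(slice(s, s + p) for s, p in zip(start, patch))
    return vol_data[sl], tgt[sl]


def train_stage(net: Module, cases: Sequence[Tuple[CtVolume, LabelMask]],
                cfg: TrainConfig, rng: Optional[np.random.Generator] = None,
                verbose: bool = False):
    """Train a network on preprocessed cases; returns (net, log DataFrame)."""
    if not cases:
        raise ValueError("no training cases")
    rng = rng or np.random.default_rng(cfg.seed)
    targets = [target_field(m, cfg.target_label) for _, m in cases]
    if cfg.foreground_oversampling > 0 and not any(t.any() for t in targets):
        raise ValueError(
            f"no {cfg.target_label!r} foreground anywhere in the training set"
        )
    params = net.parameters()
    if cfg.optimizer == "sgd":
        opt = SGD(params, lr=cfg.lr, momentum=cfg.momentum,
                  nesterov=cfg.nesterov, weight_decay=cfg.weight_decay)
    elif cfg.optimizer == "adamw":
        opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    n_iters = max(1, len(cases) * cfg.patches_per_volume // cfg.batch_size)
    total_steps = cfg.epochs * n_iters
    step = 0
    log_rows = []
    for epoch in range(cfg.epochs):
        losses = []
        for _ in range(n_iters):
            opt.zero_grad()
            opt.lr = polynomial_lr(cfg.lr, step, total_steps, cfg.lr_power)
            batch_loss = 0.0
            for _ in range(cfg.batch_size):
                ci = int(rng.integers(0, len(cases)))
                vol, mask = cases[ci]
                tgt = targets[ci]
                if cfg.augment is not None and rng.random() < cfg.augment_prob:
                    tgt_mask = mask.with_data((tgt > 0).astype(np.int16))
                    avol, amask = random_augment(vol, tgt_mask, cfg.augment, rng)
                    vdata, tdata = avol.data, (amask.data > 0).astype(np.float32)
                else:
                    vdata, tdata = vol.data, tgt
                fg = rng.random() < cfg.foreground_oversampling
                px, pt = sample_patch(vdata, tdata, cfg.patch_size, rng, fg)
                pred = net(px[None].astype(np.float32), train=True)
                loss, grad = dice_ce_loss(pred[0], pt, return_grad=True)
                net.backward((grad / cfg.batch_size)[None].astype(np.float32))
                batch_loss += loss / cfg.batch_size
            opt.step()
            step += 1
            losses.append(batch_loss)
        log_rows.append({"epoch": epoch, "mean_loss": float(np.mean(losses)),
                         "lr": opt.lr})
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):.4f}  lr {opt.lr:.2e}")
    return net, pd.DataFrame(log_rows)


# ------------------------------------------------------------- checkpointing

def save_checkpoint(path, net: Module, kind: str, net_config, stats: Optional[IntensityStats] = None,
                    extra: Optional[dict] = None) -> None:
    """Persist weights + config + frozen intensity stats as one npz file."""
    meta = {
        "kind": kind,
        "config": dataclasses.asdict(net_config),
        "stats": stats.to_dict() if stats is not None else None,
        "extra": extra or {},
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(net.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Rebuild the network (and stats) saved by :func:`save_checkpoint`."""
    from .stage1 import CnnOrganNet, OrganNetConfig, build_organ_net
    from .tumor_net import TumorNetConfig, build_tumor_net

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        kind = meta["kind"]
        cfg_dict = dict(meta["config"])
        for key in ("channels", "residual_blocks", "patch_size"):
            if key in cfg_dict and cfg_dict[key] is not None:
                cfg_dict[key] = tuple(cfg_dict[key])
        if kind == "tumor":
            cfg = TumorNetConfig(**cfg_dict)
            net = build_tumor_net(cfg)
        elif kind == "organ":
            cfg = OrganNetConfig(**cfg_dict)
            net = build_organ_net(cfg)
        elif kind == "organ_cnn_tiny":
            cfg = TumorNetConfig(**cfg_dict)
            net = build_tumor_net(cfg)
        else:
            raise ValueError(f"unknown checkpoint kind {kind!r}")
        for i, p in enumerate(net.parameters()):
            arr = data[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint does not match the rebuilt network")
            p.data = arr.astype(p.data.dtype)
        stats = IntensityStats.from_dict(meta["stats"]) if meta["stats"] else None
    return net, cfg, stats, meta.get("extra", {})
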