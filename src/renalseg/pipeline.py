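"""Dual-stage inference: preprocess, localise the kidneys, crop expanded
VOIs, segment tumors inside each VOI, paste back and return to the native
grid.

Tumor probabilities are computed only inside the stage-one VOIs —
overlapping VOI predictions merge by voxelwise maximum probability before
thresholding — so a dual-stage prediction cannot place tumor voxels
outside the kidney neighbourhood by construction.  A single-stage mode
(one network over the whole volume) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .grids import CtVolume, LabelMask, Voi, crop
from .nn import Module
from .preprocess import IntensityStats, clip_and_normalize, resample_isotropic
from .stage1 import extract_vois, segment_kidney, sliding_window_predict


@dataclass
class PipelineConfig:
    target_spacing: float = 1.0
    expansion: float = 0.25
    organ_threshold: float = 0.5
    tumor_threshold: float = 0.5
    organ_window: Tuple[int, int, int] = (64, 64, 64)
    tumor_window: Tuple[int, int, int] = (32, 32, 32)
    overlap: float = 0.5
    min_kidney_voxels: int = 50
    resample: bool = True  # False: spacing already matches, skip resampling


@dataclass
class CasePrediction:
    kidney_mask: LabelMask  # native grid
    tumor_mask: LabelMask  # native grid
    vois: List[Voi]  # voxel boxes on the processing grid
    provenance: dict = field(default_factory=dict)
    kidney_mask_proc: Optional[LabelMask] = None  # processing (isotropic) grid
    tumor_mask_proc: Optional[LabelMask] = None


def _resample_mask_to(mask_data: np.ndarray, shape, spacing, origin) -> LabelMask:
    if mask_data.shape != tuple(shape):
        zoom = [t / s for t, s in zip(shape, mask_data.shape)]
        data = ndimage.zoom(mask_data.astype(np.int16), zoom, order=0,
                            mode="nearest", grid_mode=True)
        fitted = np.zeros(shape, dtype=np.int16)
        sl = tuple(slice(0, min(a, b)) for a, b in zip(data.shape, shape))
        fitted[sl] = data[sl]
        mask_data = fitted
    return LabelMask(data=mask_data.astype(np.int16), spacing=spacing, origin=origin)


def _preprocess(vol: CtVolume, stats: IntensityStats, cfg: PipelineConfig) -> CtVolume:
    if vol.spacing is None or any(s <= 0 for s in vol.spacing):
        raise ValueError("volume lacks valid spacing metadata")
    work = resample_isotropic(vol, cfg.target_spacing) if cfg.resample else vol
    return clip_and_normalize(work, stats)


def run_dual_stage(vol: CtVolume, organ_net: Module, tumor_net: Module,
                   stats: IntensityStats, cfg: Optional[PipelineConfig] = None) -> CasePrediction:
    """Full coarse-to-fine inference on one native-grid volume."""
    cfg = cfg or PipelineConfig()
    norm = _preprocess(vol, stats, cfg)

    kidney = segment_kidney(norm, organ_net, cfg.organ_window,
                            threshold=cfg.organ_threshold, overlap=cfg.overlap)
    vois = extract_vois(kidney, expansion=cfg.expansion,
                        min_component_voxels=cfg.min_kidney_voxels)

    tumor_prob = np.zeros(norm.data.shape, dtype=np.float32)
    for voi in vois:
        sub = crop(norm, voi)
        prob = sliding_window_predict(sub.data, tumor_net, cfg.tumor_window,
                                      overlap=cfg.overlap)
        region = tumor_prob[voi.slices]
        np.maximum(region, prob, out=region)  # max-merge overlapping VOIs
    tumor_bin = (tumor_prob >= cfg.tumor_threshold).astype(np.int16) * 2
    tumor_proc = LabelMask(data=tumor_bin, spacing=norm.spacing, origin=norm.origin)

    kidney_native = _resample_mask_to(kidney.data, vol.data.shape, vol.spacing, vol.origin)
    tumor_native = _resample_mask_to(tumor_bin, vol.data.shape, vol.spacing, vol.origin)
    return CasePrediction(
        kidney_mask=kidney_native,
        tumor_mask=tumor_native,
        vois=vois,
        provenance={
            "mode": "dual_stage",
            "target_spacing": cfg.target_spacing,
            "expansion": cfg.expansion,
            "organ_threshold": cfg.organ_threshold,
            "tumor_threshold": cfg.tumor_threshold,
            "stats": stats.to_dict(),
            "n_vois": len(vois),
        },
        kidney_mask_proc=kidney,
        tumor_mask_proc=tumor_proc,
    )


def run_single_stage(vol: CtVolume, net: Module, stats: IntensityStats,
                     cfg: Optional[PipelineConfig] = None) -> CasePrediction:
    """Single-network tumor segmentation over the whole volume (SS mode)."""
    cfg = cfg or PipelineConfig()
    norm = _preprocess(vol, stats, cfg)
    prob = sliding_window_predict(norm.data, net, cfg.tumor_window, overlap=cfg.overlap)
    tumor_bin = (prob >= cfg.tumor_threshold).astype(np.int16) * 2
    tumor_proc = LabelMask(data=tumor_bin, spacing=norm.spacing, origin=norm.origin)
    empty = LabelMask(data=np.zeros(vol.data.shape, dtype=np.int16),
                      spacing=vol.spacing, origin=vol.origin)
    return CasePrediction(
        kidney_mask=empty,
        tumor_mask=_resample_mask_to(tumor_bin, vol.data.shape, vol.spacing, vol.origin),
        vois=[],
        provenance={
            "mode": "single_stage",
            "target_spacing": cfg.target_spacing,
            "tumor_threshold": cfg.tumor_threshold,
            "stats": stats.to_dict(),
        },
        kidney_mask_proc=None,
        tumor_mask_proc=tumor_proc,
    )


def gt_voi_crops(vol: CtVolume, mask: LabelMask, expansion: float = 0.25,
                 min_kidney_voxels: int = 50):
    """Stage-two training inputs: crops of the expanded ground-truth kidney
    boxes, mirroring what stage one hands to the tumor network at inference."""
    kidney = mask.with_data((mask.data >= 1).astype(np.int16))
    vois = extract_vois(kidney, expansion=expansion,
                        min_component_voxels=min_kidney_voxels)
    return [(crop(vol, voi), crop(mask, voi)) for voi in vois]


def tumor_voxels_outside_vois(pred: CasePrediction) -> int:
    """Count predicted tumor voxels outside every VOI (0 by construction
    for dual-stage predictions; may be positive in single-stage mode)."""
    mask = pred.tumor_mask_proc.data == 2 if pred.tumor_mask_proc is not None \
        else pred.tumor_mask.data == 2
    inside = np.zeros_like(mask)
    for voi in pred.vois:
        inside[voi.slices] = True
    return int(np.count_nonzero(mask & ~inside))
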