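"""Intensity and geometry preprocessing for CECT volumes.

The recipe is the one used throughout this package's training pipeline:

1. keep only the intensity range between the lower and upper 0.5 % of
   HU values, pooled over the training set;
2. resample every volume isotropically to a 1.0 mm voxel spacing;
3. z-score normalise with the pooled post-clipping mean and standard
   deviation, so that inference can reproduce training normalisation
   exactly from two frozen numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Union

import numpy as np
from scipy import ndimage

from .grids import CtVolume, LabelMask

DEFAULT_PERCENTILE = 0.5  # percent trimmed from each tail
DEFAULT_TARGET_SPACING = 1.0  # mm


@dataclass
class IntensityStats:
    """Pooled dataset intensity statistics frozen at training time."""

    lower_clip: float
    upper_clip: float
    mean: float
    std: float

    def __post_init__(self) -> None:
        if self.lower_clip > self.upper_clip:
            raise ValueError("lower_clip must not exceed upper_clip")
        if self.std < 0:
            raise ValueError("std must be non-negative")

    def to_dict(self) -> dict:
        return {
            "lower_clip": float(self.lower_clip),
            "upper_clip": float(self.upper_clip),
            "mean": float(self.mean),
            "std": float(self.std),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntensityStats":
        return cls(**{k: float(d[k]) for k in ("lower_clip", "upper_clip", "mean", "std")})


def compute_intensity_stats(
    volumes: Iterable[CtVolume],
    percentile: float = DEFAULT_PERCENTILE,
    pooled: bool = True,
) -> Union[IntensityStats, List[IntensityStats]]:
    """Percentile clip bounds and post-clip moments of the pooled voxel values.

    Percentiles use linear interpolation between order statistics.  With
    ``pooled=False`` a per-volume list of stats is returned instead (an
    ablation mode; pooled statistics are the supported default).
    """
    vols = list(volumes)
    if not vols:
        raise ValueError("compute_intensity_stats needs at least one volume")
    if not pooled:
        return [compute_intensity_stats([v], percentile=percentile) for v in vols]
    values = np.concatenate([np.asarray(v.data, dtype=np.float64).ravel() for v in vols])
    if values.size < 2:
        raise ValueError("pooled voxel count must be at least 2")
    lower = float(np.percentile(values, percentile))
    upper = float(np.percentile(values, 100.0 - percentile))
    clipped = np.clip(values, lower, upper)
    return IntensityStats(
        lower_clip=lower,
        upper_clip=upper,
        mean=float(clipped.mean()),
        std=float(clipped.std()),
    )


def clip_and_normalize(vol: CtVolume, stats: IntensityStats) -> CtVolume:
    """Clip to the stats window, subtract the mean, divide by the std."""
    if stats.std == 0:
        raise ValueError(
            "cannot normalize with std = 0 (constant training data); "
            "refusing rather than dividing by zero"
        )
    data = np.clip(vol.data.astype(np.float32), stats.lower_clip, stats.upper_clip)
    data = (data - np.float32(stats.mean)) / np.float32(stats.std)
    return vol.with_data(data)


def _target_shape(shape, spacing, target: float):
    # round-half-away-from-zero keeps the output extent deterministic
    out = []
    for n, s in zip(shape, spacing):
        m = int(np.floor(n * s / target + 0.5))
        out.append(max(m, 1))
    return tuple(out)


def resample_isotropic(vol, target_spacing: float = DEFAULT_TARGET_SPACING):
    """Resample a volume (trilinear) or mask (nearest) to an isotropic grid.

    Output extent per axis is ``round(extent * spacing / target)`` with a
    minimum of 1.  Mask labels stay in {0, 1, 2} by construction.
    """
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    new_shape = _target_shape(vol.data.shape, vol.spacing, target_spacing)
    if new_shape == vol.data.shape and np.allclose(vol.spacing, target_spacing):
        return vol.with_data(vol.data.copy())
    zoom = [m / n for m, n in zip(new_shape, vol.data.shape)]
    is_mask = isinstance(vol, LabelMask)
    order = 0 if is_mask else 1
    data = ndimage.zoom(
        vol.data.astype(np.int16 if is_mask else np.float32),
        zoom,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    # grid_mode zoom can be off by one voxel in extent for odd ratios; crop/pad
    data = _fit_to_shape(data, new_shape)
    out = vol.with_data(data)
    out.spacing = (float(target_spacing),) * 3
    return out


def _fit_to_shape(data: np.ndarray, shape) -> np.ndarray:
    if data.shape == tuple(shape):
        return data
    slices = tuple(slice(0, min(a, b)) for a, b in zip(data.shape, shape))
    fitted = np.zeros(shape, dtype=data.dtype)
    fitted[tuple(slice(0, s.stop) for s in slices)] = data[slices]
    return fitted
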