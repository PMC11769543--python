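"""Grid-level domain types shared by every module.

A scan is represented as a :class:`CtVolume` — a 3-D scalar field in
Hounsfield-like units on a regular grid with per-axis voxel spacing in
millimetres — and its annotation as a :class:`LabelMask` on the same grid
(0 background, 1 kidney, 2 tumor).  Arrays are ordered (x, y, z) to match
the header spacing order; all voxel indexing is 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

LABEL_BACKGROUND = 0
LABEL_KIDNEY = 1
LABEL_TUMOR = 2
VALID_LABELS = (LABEL_BACKGROUND, LABEL_KIDNEY, LABEL_TUMOR)


def _check_grid(data: np.ndarray, spacing: Tuple[float, float, float]) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got {data.ndim}-D data of shape {data.shape}")
    if min(data.shape) < 1:
        raise ValueError(f"every axis must have extent >= 1, got shape {data.shape}")
    if len(spacing) != 3:
        raise ValueError(f"spacing must have three components, got {spacing!r}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be strictly positive, got {spacing!r}")


@dataclass
class CtVolume:
    """A 3-D scalar field (HU-like) with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.data, self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "CtVolume":
        return replace(self, data=data)


@dataclass
class LabelMask:
    """Integer field on a CtVolume grid: 0 background, 1 kidney, 2 tumor."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = self.data.astype(np.int16)
            if not np.array_equal(as_int, self.data):
                raise ValueError("label mask holds non-integer values")
            self.data = as_int
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.data, self.spacing)
        bad = np.setdiff1d(np.unique(self.data), np.asarray(VALID_LABELS))
        if bad.size:
            raise ValueError(f"label values outside {{0,1,2}}: {bad.tolist()}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "LabelMask":
        return replace(self, data=data)


def same_grid(a, b) -> bool:
    """True when two fields share extents and spacing (tolerant in spacing)."""
    return a.data.shape == b.data.shape and np.allclose(a.spacing, b.spacing)


def require_same_grid(a, b) -> None:
    if not same_grid(a, b):
        raise ValueError(
            f"grid mismatch: {a.data.shape} @ {a.spacing} vs {b.data.shape} @ {b.spacing}"
        )


@dataclass
class Voi:
    """Axis-aligned half-open voxel box, typically the 25 %-expanded kidney box.

    ``start``/``stop`` index the resampled grid; ``source_extent`` records the
    tight pre-expansion box extents and ``expansion`` the fraction applied.
    """

    start: Tuple[int, int, int]
    stop: Tuple[int, int, int]
    source_extent: Tuple[int, int, int] = field(default=(0, 0, 0))
    expansion: float = 0.25

    def __post_init__(self) -> None:
        self.start = tuple(int(v) for v in self.start)
        self.stop = tuple(int(v) for v in self.stop)
        self.source_extent = tuple(int(v) for v in self.source_extent)
        if any(a >= b for a, b in zip(self.start, self.stop)):
            raise ValueError(f"empty VOI: start {self.start} !< stop {self.stop}")
        if any(a < 0 for a in self.start):
            raise ValueError(f"VOI start must be non-negative, got {self.start}")

    @property
    def extent(self) -> Tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    def contains_point(self, idx) -> bool:
        return all(a <= i < b for a, i, b in zip(self.start, idx, self.stop))


def crop(vol, voi: Voi):
    """Crop a volume or mask to a VOI (half-open box). Spacing is kept."""
    if any(b > n for b, n in zip(voi.stop, vol.data.shape)):
        raise ValueError(f"VOI {voi.start}..{voi.stop} exceeds grid {vol.data.shape}")
    return vol.with_data(vol.data[voi.slices].copy())


def paste(target_data: np.ndarray, patch_data: np.ndarray, voi: Voi) -> np.ndarray:
    """Inverse of :func:`crop`: write patch values back at the VOI indices."""
    if patch_data.shape != voi.extent:
        raise ValueError(f"patch shape {patch_data.shape} != VOI extent {voi.extent}")
    target_data[voi.slices] = patch_data
    return target_data
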