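"""Training-time augmentation: rotation, scaling, mirroring, axis
transposition and gamma correction.

The same sampled geometric transform is applied to the image (linear
interpolation) and its mask (nearest neighbour); gamma correction applies
to the image only, as ``v -> ((v - min)/(max - min))^gamma`` rescaled back
to the original range.  Rotations and scalings resample on the fixed grid
(no canvas growth), padding with the volume's background value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

from .grids import CtVolume, LabelMask, require_same_grid


@dataclass
class AugmentParams:
    rotation_range_deg: float = 30.0
    rotation_prob: float = 0.3
    scale_range: Tuple[float, float] = (0.85, 1.25)
    scale_prob: float = 0.3
    mirror_axes: Tuple[int, ...] = (0, 1, 2)
    mirror_prob: float = 0.5
    transpose_enabled: bool = True
    transpose_prob: float = 0.2
    gamma_range: Tuple[float, float] = (0.7, 1.5)
    gamma_prob: float = 0.3

    def __post_init__(self):
        if self.scale_range[0] <= 0 or self.gamma_range[0] <= 0:
            raise ValueError("scale and gamma bounds must be strictly positive")
        for p in (self.rotation_prob, self.scale_prob, self.mirror_prob,
                  self.transpose_prob, self.gamma_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def disabled(cls) -> "AugmentParams":
        return cls(rotation_prob=0, scale_prob=0, mirror_prob=0,
                   transpose_prob=0, gamma_prob=0)


def _affine_pair(img: np.ndarray, msk: np.ndarray, matrix, background: float):
    center = (np.asarray(img.shape) - 1) / 2.0
    offset = center - matrix @ center
    img_t = ndimage.affine_transform(img, matrix, offset=offset, order=1,
                                     mode="constant", cval=background)
    msk_t = ndimage.affine_transform(msk, matrix, offset=offset, order=0,
                                     mode="constant", cval=0)
    return img_t, msk_t


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


def random_augment(vol: CtVolume, mask: LabelMask, params: AugmentParams,
                   rng: np.random.Generator) -> Tuple[CtVolume, LabelMask]:
    """Apply one sampled augmentation to an image/mask pair.

    With all probabilities zero the pair is returned unchanged (copies).
    The draw order is fixed (rotation, scale, mirror, transpose, gamma) so
    a seeded generator reproduces the stream bit-for-bit.
    """
    require_same_grid(vol, mask)
    img = vol.data.astype(np.float32, copy=True)
    msk = mask.data.copy()
    background = float(img.min())

    matrix = np.eye(3)
    apply_affine = False
    if rng.random() < params.rotation_prob:
        angles = np.deg2rad(rng.uniform(-params.rotation_range_deg,
                                        params.rotation_range_deg, size=3))
        matrix = matrix @ _rotation_matrix(angles)
        apply_affine = True
    if rng.random() < params.scale_prob:
        s = rng.uniform(*params.scale_range)
        # affine_transform maps output to input: divide to zoom by s
        matrix = matrix @ (np.eye(3) / s)
        apply_affine = True
    if apply_affine:
        img, msk = _affine_pair(img, msk, matrix, background)

    for axis in params.mirror_axes:
        if rng.random() < params.mirror_prob:
            img = np.flip(img, axis=axis)
            msk = np.flip(msk, axis=axis)
    if params.transpose_enabled and rng.random() < params.transpose_prob:
        # in-plane transposition only (the two axial axes)
        if img.shape[0] == img.shape[1]:
            img = np.swapaxes(img, 0, 1)
            msk = np.swapaxes(msk, 0, 1)
    if rng.random() < params.gamma_prob:
        gamma = rng.uniform(*params.gamma_range)
        lo, hi = float(img.min()), float(img.max())
        if hi > lo:
            img = ((img - lo) / (hi - lo)) ** gamma * (hi - lo) + lo

    return vol.with_data(np.ascontiguousarray(img)), mask.with_data(np.ascontiguousarray(msk))
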