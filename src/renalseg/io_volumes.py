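"""NIfTI reading and writing for CT volumes and label masks.

Volumes are reoriented to the canonical RAS+ orientation on read so that a
single axis convention (x, y, z) holds everywhere downstream; spacing is
taken from the header zooms and the origin from the affine translation.
"""

from __future__ import annotations

import os
from typing import Union

import nibabel as nib
import numpy as np

from .grids import CtVolume, LabelMask

Field = Union[CtVolume, LabelMask]


def _load_canonical(path) -> nib.Nifti1Image:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = img.slicer[..., 0]
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {img.shape}")
    return img


def read_volume(path) -> CtVolume:
    """Read a 3-D NIfTI image as a :class:`CtVolume` (canonical orientation)."""
    img = _load_canonical(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    data = np.asarray(img.dataobj, dtype=np.float32)
    return CtVolume(data=data, spacing=spacing, origin=origin)


def read_mask(path) -> LabelMask:
    """Read a 3-D NIfTI label image as a :class:`LabelMask`."""
    img = _load_canonical(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    data = np.rint(np.asarray(img.dataobj)).astype(np.int16)
    return LabelMask(data=data, spacing=spacing, origin=origin)


def write_volume(vol: Field, path) -> None:
    """Write a volume or mask as NIfTI; masks are stored as integers."""
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if isinstance(vol, LabelMask):
        data = vol.data.astype(np.int16)
    else:
        data = vol.data.astype(np.float32)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
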