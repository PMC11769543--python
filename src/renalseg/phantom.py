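"""Parametric CT phantoms with exact kidney/tumor ground truth.

The generator paints an abdominal scene analytically on the voxel grid —
a soft-tissue body ellipsoid (~40 HU), two bright kidney ellipsoids
(~120 HU, emulating contrast-enhanced parenchyma), optional hypodense
tumor spheres of controlled unidirectional diameter attached to a kidney,
and a high-density spine cylinder (~700 HU) that serves as a decoy for
false-positive analysis — then adds Gaussian noise.  Labels are exact:
1 on painted kidney voxels, 2 on painted tumor voxels.

Two grid presets are provided: ``"abdomen"`` (96 x 96 x 48 voxels at
1.5 x 1.5 x 3.0 mm, anisotropic to exercise resampling, large enough for
tumors up to ~8.5 cm) and ``"desk"`` (64 cubed at 1.0 mm isotropic, small
tumors only, sized for CPU training runs).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grids import CtVolume, LabelMask
from . import metrics as _metrics
from .io_volumes import write_volume

HU_AIR = -1000.0
HU_BODY = 40.0
HU_KIDNEY = 120.0
HU_SPINE = 700.0

NOISE_SD = {"easy": 10.0, "hard": 25.0}
TUMOR_OFFSET = {"easy": 60.0, "hard": 20.0}  # HU below kidney parenchyma

UD_RANGE_CM = (0.5, 10.0)

_PRESETS = {
    "abdomen": dict(
        shape=(96, 96, 48),
        spacing=(1.5, 1.5, 3.0),
        body_radii=(66.0, 58.0, 78.0),
        kidney_radii=(16.0, 12.0, 26.0),
        kidney_offset_x=36.0,
        spine_center_y=40.0,
        spine_radius=10.0,
        ud_ranges={"small": (1.2, 4.0), "medium": (4.05, 7.0), "large": (7.05, 8.5)},
    ),
    "desk": dict(
        shape=(64, 64, 64),
        spacing=(1.0, 1.0, 1.0),
        body_radii=(30.0, 27.0, 31.0),
        kidney_radii=(9.0, 7.5, 12.0),
        kidney_offset_x=16.0,
        spine_center_y=20.0,
        spine_radius=5.0,
        ud_ranges={"small": (0.9, 1.7), "medium": (0.9, 1.7), "large": (0.9, 1.7)},
    ),
}


@dataclass
class TumorSpec:
    center_mm: Tuple[float, float, float]  # physical coords relative to volume origin
    target_ud_cm: float
    intensity_offset: float  # HU subtracted from kidney intensity
    exophytic: bool = False

    def __post_init__(self):
        if not (UD_RANGE_CM[0] <= self.target_ud_cm <= UD_RANGE_CM[1]):
            raise ValueError(
                f"target UD {self.target_ud_cm} cm outside supported range {UD_RANGE_CM}"
            )


@dataclass
class PhantomSpec:
    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    body_center_mm: Tuple[float, float, float]
    body_radii_mm: Tuple[float, float, float]
    kidney_centers_mm: List[Tuple[float, float, float]]
    kidney_radii_mm: Tuple[float, float, float]
    tumors: List[TumorSpec] = dc_field(default_factory=list)
    body_hu: float = HU_BODY
    kidney_hu: float = HU_KIDNEY
    spine_hu: float = HU_SPINE
    spine_center_xy_mm: Tuple[float, float] = (0.0, 40.0)
    spine_radius_mm: float = 10.0
    noise_sd: float = NOISE_SD["easy"]

    def __post_init__(self):
        if not (HU_AIR < self.body_hu < self.kidney_hu < self.spine_hu):
            raise ValueError("intensities must be ordered background < body < kidney < spine")


def _coord_grids(shape, spacing):
    axes = [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _inside_ellipsoid(grids, center, radii):
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator) -> Tuple[CtVolume, LabelMask]:
    """Paint the phantom geometry and return the noisy image plus exact mask.

    Raises if a tumor neither intersects nor abuts a kidney ellipsoid: the
    generator only produces renal tumors.
    """
    grids = _coord_grids(spec.shape, spec.spacing)
    image = np.full(spec.shape, HU_AIR, dtype=np.float32)
    labels = np.zeros(spec.shape, dtype=np.int16)

    body = _inside_ellipsoid(grids, spec.body_center_mm, spec.body_radii_mm)
    image[body] = spec.body_hu

    # spine: a cylinder along z, posterior to the kidneys
    sx = spec.body_center_mm[0] + spec.spine_center_xy_mm[0]
    sy = spec.body_center_mm[1] + spec.spine_center_xy_mm[1]
    r2 = (grids[0] - sx) ** 2 + (grids[1] - sy) ** 2 + 0.0 * grids[2]
    spine = (r2 <= spec.spine_radius_mm ** 2) & body
    image[spine] = spec.spine_hu

    kidney_any = np.zeros(spec.shape, dtype=bool)
    for kc in spec.kidney_centers_mm:
        k = _inside_ellipsoid(grids, kc, spec.kidney_radii_mm)
        kidney_any |= k
    image[kidney_any] = spec.kidney_hu
    labels[kidney_any] = 1

    # one voxel of slack when testing the "abuts a kidney" contract
    slack = np.asarray(spec.spacing, dtype=np.float64)
    near_radii = tuple(r + float(s) for r, s in zip(spec.kidney_radii_mm, slack))
    for t in spec.tumors:
        radius = t.target_ud_cm * 10.0 / 2.0
        tm = _inside_ellipsoid(grids, t.center_mm, (radius,) * 3)
        touches = any(
            np.any(tm & _inside_ellipsoid(grids, kc, near_radii))
            for kc in spec.kidney_centers_mm
        )
        if not touches:
            raise ValueError(
                f"tumor at {t.center_mm} (UD {t.target_ud_cm} cm) does not touch a kidney"
            )
        image[tm] = spec.kidney_hu - t.intensity_offset
        labels[tm] = 2

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)

    vol = CtVolume(data=image, spacing=spec.spacing)
    mask = LabelMask(data=labels, spacing=spec.spacing)
    return vol, mask


def random_spec(
    rng: np.random.Generator,
    preset: str = "abdomen",
    difficulty: str = "easy",
    category: str = "small",
    target_ud_cm: Optional[float] = None,
    exophytic_prob: float = 0.3,
    n_tumors: int = 1,
) -> PhantomSpec:
    """Draw a randomized phantom specification for one case.

    The tumor diameter is sampled within the requested size category (or set
    explicitly), the tumor is attached to a random kidney either intrarenally
    or exophytically, and intensity/noise follow the difficulty regime
    (easy: 60 HU tumor contrast, 10 HU noise; hard: 20 HU contrast, 25 HU
    noise).
    """
    p = _PRESETS[preset]
    shape, spacing = p["shape"], p["spacing"]
    center = tuple((n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    jitter = rng.uniform(-2.0, 2.0, size=3)
    kidney_centers = [
        (center[0] - p["kidney_offset_x"] + jitter[0], center[1] + jitter[1], center[2] + jitter[2]),
        (center[0] + p["kidney_offset_x"] + jitter[0], center[1] + jitter[1], center[2] + jitter[2]),
    ]
    tumors: List[TumorSpec] = []
    for _ in range(n_tumors):
        lo, hi = p["ud_ranges"][category]
        ud = float(target_ud_cm if target_ud_cm is not None else rng.uniform(lo, hi))
        radius_mm = ud * 10.0 / 2.0
        kidney = kidney_centers[int(rng.integers(0, 2))]
        exo = bool(rng.random() < exophytic_prob)
        if radius_mm >= min(p["kidney_radii"]):
            # tumor dwarfs the kidney: centre it on the kidney, pulled inward
            # so the sphere stays inside the body/grid
            pull = np.clip(radius_mm - min(p["kidney_radii"]), 0.0, p["kidney_offset_x"] * 0.8)
            direction = -1.0 if kidney[0] < center[0] else 1.0
            tc = (kidney[0] - direction * pull * 0.5, kidney[1], kidney[2])
        elif exo:
            u = rng.normal(size=3)
            u[1] = -abs(u[1])  # push anteriorly, away from the spine
            u /= np.linalg.norm(u)
            surf = np.asarray(kidney) + u * np.asarray(p["kidney_radii"])
            tc = tuple(float(v) for v in surf)
        else:
            frac = rng.uniform(-0.4, 0.4, size=3)
            tc = tuple(float(k + f * r) for k, f, r in zip(kidney, frac, p["kidney_radii"]))
        tumors.append(
            TumorSpec(
                center_mm=tc,
                target_ud_cm=ud,
                intensity_offset=TUMOR_OFFSET[difficulty],
                exophytic=exo,
            )
        )
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        body_center_mm=center,
        body_radii_mm=p["body_radii"],
        kidney_centers_mm=kidney_centers,
        kidney_radii_mm=p["kidney_radii"],
        tumors=tumors,
        spine_center_xy_mm=(0.0, p["spine_center_y"]),
        spine_radius_mm=p["spine_radius"],
        noise_sd=NOISE_SD[difficulty],
    )


def _apportion(n: int, fractions: Sequence[float]) -> List[int]:
    """Largest-remainder apportionment of n cases over category fractions."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # most negative first
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def generate_cohort(
    n: int,
    size_mix: Sequence[float] = (0.54, 0.24, 0.22),
    difficulty: str = "easy",
    seed: int = 0,
    out_dir: Optional[str] = None,
    preset: str = "abdomen",
    exophytic_prob: float = 0.3,
):
    """Generate ``n`` phantom cases with the requested size-category mix.

    Returns ``(cases, manifest)`` where cases is a list of
    ``(case_id, CtVolume, LabelMask)`` and the manifest records each case's
    category, true diameter, exophytic flag and seed.  With ``out_dir`` the
    image/mask pairs are additionally written as NIfTI plus a manifest CSV.

    The default mix mirrors a public kidney-tumor cohort in which roughly
    54 % of tumors are small, 24 % medium and 22 % large.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    fractions = list(size_mix)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"size mix must sum to 1, got {fractions}")
    counts = _apportion(n, fractions)
    categories = [c for cat, k in zip(_metrics.SIZE_CATEGORIES, counts) for c in [cat] * k]
    root = np.random.default_rng(seed)
    cases = []
    rows = []
    for i, cat in enumerate(categories):
        case_id = f"case_{i:04d}"
        case_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(case_seed)
        spec = random_spec(rng, preset=preset, difficulty=difficulty,
                           category=cat, exophytic_prob=exophytic_prob)
        vol, mask = generate_phantom(spec, rng)
        cases.append((case_id, vol, mask))
        rows.append({
            "case_id": case_id,
            "category": cat,
            "true_ud_cm": spec.tumors[0].target_ud_cm if spec.tumors else float("nan"),
            "exophytic": spec.tumors[0].exophytic if spec.tumors else False,
            "seed": case_seed,
        })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for case_id, vol, mask in cases:
            write_volume(vol, os.path.join(out_dir, f"{case_id}_image.nii.gz"))
            write_volume(mask, os.path.join(out_dir, f"{case_id}_mask.nii.gz"))
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return cases, manifest
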