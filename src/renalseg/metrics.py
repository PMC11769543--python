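"""Segmentation and detection evaluation.

Voxel-level scores
------------------
For voxel confusion counts TP/FP/FN between a binary prediction and the
reference:

* Dice       = 2TP / (2TP + FP + FN)
* precision  = TP / (TP + FP)
* VD         = |FN - FP| / (2TP + FP + FN)   (volumetric distance)
* OSR        = FP / (TP + FN)                (over-segmentation ratio)
* USR        = FN / (TP + FN)                (under-segmentation ratio)

Object-level detection
----------------------
Tumor instances are 26-connected components.  A ground-truth instance
counts as detected when a predicted instance can be matched one-to-one to
it with 3-D object IoU >= 0.25 (greedy matching in descending IoU order).
Unmatched predicted instances are false positives; FPC is the average
false-positive count per patient.

Size stratification
-------------------
Each instance is measured by its unidirectional diameter — the largest
voxel-centre distance within any single axial (x, y) slice plus one
in-plane voxel extent — and binned TNM-style: small <= 4 cm, medium
> 4 to <= 7 cm, large > 7 cm, with small sub-bins <= 2, > 2 to <= 3 and
> 3 to <= 4 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import ConvexHull, QhullError

from .grids import require_same_grid

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

SIZE_SMALL = "small"
SIZE_MEDIUM = "medium"
SIZE_LARGE = "large"
SIZE_CATEGORIES = (SIZE_SMALL, SIZE_MEDIUM, SIZE_LARGE)
SMALL_SUBBINS = ("<=2cm", ">2-<=3cm", ">3-<=4cm")

DEFAULT_IOU_THRESHOLD = 0.25
DEFAULT_MIN_COMPONENT_VOXELS = 8


# ---------------------------------------------------------------- voxel level

@dataclass(frozen=True)
class VoxelConfusion:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def voxel_confusion(pred: np.ndarray, gt: np.ndarray) -> VoxelConfusion:
    """Voxelwise TP/FP/FN counts between two binary fields on one grid."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return VoxelConfusion(tp=tp, fp=fp, fn=fn)


def dice(c: VoxelConfusion) -> float:
    den = 2 * c.tp + c.fp + c.fn
    return 1.0 if den == 0 else 2.0 * c.tp / den


def precision(c: VoxelConfusion) -> float:
    den = c.tp + c.fp
    # empty prediction: perfect when nothing was there to find
    if den == 0:
        return 1.0 if c.fn == 0 else 0.0
    return c.tp / den


def vd(c: VoxelConfusion) -> float:
    den = 2 * c.tp + c.fp + c.fn
    return 0.0 if den == 0 else abs(c.fn - c.fp) / den


def osr(c: VoxelConfusion) -> float:
    den = c.tp + c.fn
    if den == 0:
        return 0.0 if c.fp == 0 else math.inf
    return c.fp / den


def usr(c: VoxelConfusion) -> float:
    den = c.tp + c.fn
    return 0.0 if den == 0 else c.fn / den


# --------------------------------------------------------------- object level

@dataclass
class TumorInstance:
    """A 26-connected tumor component with its measured size."""

    component_id: int
    voxel_indices: np.ndarray  # (n, 3) int array of voxel coordinates
    diameter_cm: float
    category: str
    subcategory: Optional[str] = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_indices.shape[0])

    def voxel_set(self) -> set:
        return set(map(tuple, self.voxel_indices.tolist()))


def size_category(diameter_cm: float) -> str:
    if diameter_cm <= 4.0:
        return SIZE_SMALL
    if diameter_cm <= 7.0:
        return SIZE_MEDIUM
    return SIZE_LARGE


def small_subcategory(diameter_cm: float) -> Optional[str]:
    if diameter_cm > 4.0:
        return None
    if diameter_cm <= 2.0:
        return SMALL_SUBBINS[0]
    if diameter_cm <= 3.0:
        return SMALL_SUBBINS[1]
    return SMALL_SUBBINS[2]


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance among 2-D points (mm)."""
    if len(points) == 1:
        return 0.0
    if len(points) > 16:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # collinear slices: brute force below
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def tumor_diameter(voxel_indices: np.ndarray, spacing: Sequence[float]) -> float:
    """Unidirectional diameter in cm: max in-plane extent over axial slices.

    For each axial slice (fixed z index) the largest voxel-centre distance is
    taken; the result is floored at one in-plane voxel extent so a single
    voxel measures one voxel across rather than zero.
    """
    idx = np.asarray(voxel_indices)
    if idx.size == 0:
        raise ValueError("empty instance has no diameter")
    sx, sy = float(spacing[0]), float(spacing[1])
    inplane = np.array([sx, sy])
    best = 0.0
    for z in np.unique(idx[:, 2]):
        pts = idx[idx[:, 2] == z, :2].astype(np.float64) * inplane
        best = max(best, _max_pairwise_distance(pts))
    return max(best, 0.5 * (sx + sy)) / 10.0  # mm -> cm


def tumor_diameter_feret3d(voxel_indices: np.ndarray, spacing: Sequence[float]) -> float:
    """Alternative measure: the maximal 3-D Feret diameter, in cm."""
    idx = np.asarray(voxel_indices, dtype=np.float64)
    if idx.size == 0:
        raise ValueError("empty instance has no diameter")
    pts = idx * np.asarray(spacing, dtype=np.float64)
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    best = float(np.sqrt((diff ** 2).sum(-1)).max())
    return max(best, float(np.mean(spacing))) / 10.0


def instance_components(
    mask: np.ndarray,
    spacing: Sequence[float],
    min_component_voxels: int = DEFAULT_MIN_COMPONENT_VOXELS,
    diameter_mode: str = "axial",
) -> List[TumorInstance]:
    """26-connected components of a binary field, measured and size-binned.

    Components below ``min_component_voxels`` are discarded as noise.
    ``diameter_mode`` selects the axial in-plane measure (default) or the
    3-D Feret diameter (``"feret3d"``).
    """
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=CONNECTIVITY_26)
    measure = tumor_diameter if diameter_mode == "axial" else tumor_diameter_feret3d
    out: List[TumorInstance] = []
    for comp_id in range(1, n + 1):
        idx = np.argwhere(labeled == comp_id)
        if idx.shape[0] < min_component_voxels:
            continue
        d = measure(idx, spacing)
        out.append(
            TumorInstance(
                component_id=comp_id,
                voxel_indices=idx,
                diameter_cm=d,
                category=size_category(d),
                subcategory=small_subcategory(d),
            )
        )
    return out


@dataclass
class DetectionResult:
    """One-to-one greedy matching of predicted to reference instances."""

    matches: List[Tuple[int, int, float]]  # (gt_id, pred_id, IoU)
    detected_gt_ids: List[int]
    unmatched_pred_ids: List[int]
    iou_threshold: float = DEFAULT_IOU_THRESHOLD


def _pairwise_iou(gt: List[TumorInstance], pred: List[TumorInstance]) -> np.ndarray:
    iou = np.zeros((len(gt), len(pred)))
    gt_sets = [g.voxel_set() for g in gt]
    pred_sets = [p.voxel_set() for p in pred]
    for i, gs in enumerate(gt_sets):
        for j, ps in enumerate(pred_sets):
            inter = len(gs & ps)
            if inter:
                iou[i, j] = inter / len(gs | ps)
    return iou


def match_detections(
    gt: List[TumorInstance],
    pred: List[TumorInstance],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> DetectionResult:
    """Greedy one-to-one matching in descending object-IoU order."""
    iou = _pairwise_iou(gt, pred)
    matches: List[Tuple[int, int, float]] = []
    used_gt: set = set()
    used_pred: set = set()
    order = np.dstack(np.unravel_index(np.argsort(iou, axis=None)[::-1], iou.shape))[0] \
        if iou.size else np.empty((0, 2), dtype=int)
    for i, j in order:
        if iou[i, j] < iou_threshold:
            break
        if i in used_gt or j in used_pred:
            continue
        used_gt.add(int(i))
        used_pred.add(int(j))
        matches.append((gt[i].component_id, pred[j].component_id, float(iou[i, j])))
    detected = [gt[i].component_id for i in sorted(used_gt)]
    fps = [pred[j].component_id for j in range(len(pred)) if j not in used_pred]
    return DetectionResult(
        matches=matches,
        detected_gt_ids=detected,
        unmatched_pred_ids=fps,
        iou_threshold=iou_threshold,
    )


# ------------------------------------------------------------------ reporting

@dataclass
class CaseEvaluation:
    """Detection + per-instance segmentation scores for one case."""

    case_id: str
    gt_instances: List[TumorInstance]
    pred_instances: List[TumorInstance]
    detection: DetectionResult
    instance_confusions: Dict[int, VoxelConfusion] = field(default_factory=dict)


def evaluate_case(
    case_id: str,
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    spacing: Sequence[float],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    min_component_voxels: int = DEFAULT_MIN_COMPONENT_VOXELS,
    diameter_mode: str = "axial",
) -> CaseEvaluation:
    """Instance-match one case and score each detected instance voxelwise."""
    gt_inst = instance_components(gt_mask, spacing, min_component_voxels, diameter_mode)
    pred_inst = instance_components(pred_mask, spacing, min_component_voxels, diameter_mode)
    det = match_detections(gt_inst, pred_inst, iou_threshold)
    pred_by_id = {p.component_id: p for p in pred_inst}
    gt_by_id = {g.component_id: g for g in gt_inst}
    confusions: Dict[int, VoxelConfusion] = {}
    for gt_id, pred_id, _ in det.matches:
        gs = gt_by_id[gt_id].voxel_set()
        ps = pred_by_id[pred_id].voxel_set()
        inter = len(gs & ps)
        confusions[gt_id] = VoxelConfusion(tp=inter, fp=len(ps) - inter, fn=len(gs) - inter)
    return CaseEvaluation(case_id, gt_inst, pred_inst, det, confusions)


def summarize(cases: List[CaseEvaluation], include_undetected_dice: bool = False) -> pd.DataFrame:
    """Aggregate per size category: sensitivity, FPC and voxel metrics.

    Sensitivity per category = detected reference instances / all reference
    instances of that size; FPC per category = unmatched predicted instances
    of that size / number of patients (FPs are binned by their own measured
    diameter).  Voxel metrics are averaged over detected instances; with
    ``include_undetected_dice`` missed instances enter as Dice 0 / USR 1.
    """
    if not cases:
        raise ValueError("summarize needs at least one case")
    n_patients = len(cases)
    rows = []
    for cat in SIZE_CATEGORIES:
        n_gt = n_det = n_fp = 0
        dices, precisions, vds, osrs, usrs = [], [], [], [], []
        for case in cases:
            detected = set(case.detection.detected_gt_ids)
            for g in case.gt_instances:
                if g.category != cat:
                    continue
                n_gt += 1
                if g.component_id in detected:
                    n_det += 1
                    c = case.instance_confusions[g.component_id]
                    dices.append(dice(c))
                    precisions.append(precision(c))
                    vds.append(vd(c))
                    osrs.append(osr(c))
                    usrs.append(usr(c))
                elif include_undetected_dice:
                    dices.append(0.0)
                    precisions.append(0.0)
                    vds.append(1.0)
                    osrs.append(0.0)
                    usrs.append(1.0)
            pred_fp = set(case.detection.unmatched_pred_ids)
            n_fp += sum(1 for p in case.pred_instances
                        if p.component_id in pred_fp and p.category == cat)
        rows.append({
            "category": cat,
            "n_gt": n_gt,
            "n_detected": n_det,
            "n_fp": n_fp,
            "sensitivity": (n_det / n_gt) if n_gt else float("nan"),
            "fpc": n_fp / n_patients,
            "dice_mean": float(np.mean(dices)) if dices else float("nan"),
            "dice_sd": float(np.std(dices, ddof=1)) if len(dices) > 1 else float("nan"),
            "precision": float(np.mean(precisions)) if precisions else float("nan"),
            "vd": float(np.mean(vds)) if vds else float("nan"),
            "osr": float(np.mean(osrs)) if osrs else float("nan"),
            "usr": float(np.mean(usrs)) if usrs else float("nan"),
        })
    return pd.DataFrame(rows)


def per_case_report(cases: List[CaseEvaluation]) -> pd.DataFrame:
    """One row per case x size category (the CSV export schema)."""
    rows = []
    for case in cases:
        for cat in SIZE_CATEGORIES:
            sub = summarize([case]).set_index("category").loc[cat]
            rows.append({"case_id": case.case_id, "category": cat, **sub.to_dict()})
    return pd.DataFrame(rows)


def compare_dice(model_a: Sequence[float], model_b: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on per-case Dice lists."""
    a = np.asarray(model_a, dtype=float)
    b = np.asarray(model_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired cases")
    if np.allclose(a, b):
        return 1.0  # no signed ranks to test
    return float(stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox").pvalue)
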