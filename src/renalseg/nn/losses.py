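"""Compound Dice + cross-entropy loss on per-voxel probabilities.

``loss = (1 - soft Dice(p, t)) + BCE(p, t)`` with both terms averaged over
the patch; the gradient is returned with respect to the probabilities so it
can be chained into a sigmoid head's backward pass.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

_EPS = 1e-7
_SMOOTH = 1e-5


def dice_ce_loss(pred: np.ndarray, target: np.ndarray,
                 return_grad: bool = False):
    """DiceCE between probabilities in (0,1) and a binary target field.

    Returns the scalar loss, or ``(loss, dloss/dpred)`` with
    ``return_grad=True``.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    t = target.astype(p.dtype)
    n = p.size

    inter = float((p * t).sum())
    psum = float(p.sum())
    tsum = float(t.sum())
    soft_dice = (2.0 * inter + _SMOOTH) / (psum + tsum + _SMOOTH)
    bce = float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())
    loss = (1.0 - soft_dice) + bce
    if not return_grad:
        return loss

    den = psum + tsum + _SMOOTH
    # d(1 - softDice)/dp = -(2 t den^-1) + (2 inter + smooth) den^-2
    gdice = -(2.0 * t) / den + (2.0 * inter + _SMOOTH) / den ** 2
    gbce = (-(t / p) + (1.0 - t) / (1.0 - p)) / n
    grad = gdice + gbce
    grad = np.where((pred > _EPS) & (pred < 1.0 - _EPS), grad, 0.0)  # clamp region
    return loss, grad.astype(pred.dtype)


def soft_dice(pred: np.ndarray, target: np.ndarray) -> float:
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    return float((2 * (p * t).sum() + _SMOOTH) / (p.sum() + t.sum() + _SMOOTH))
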