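"""Segmentation overlap metrics and the combined BCE + soft-Dice loss."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InputError
from .nn import sigmoid

__all__ = ["SegMetrics", "dice_iou", "loss_bce_softdice", "bce_softdice_from_logits"]


@dataclass
class SegMetrics:
    """Per-fold (or pooled) overlap metrics. IoU <= Dice always, and per
    image Dice = 2*IoU / (1 + IoU) exactly."""

    dice_mean: float
    dice_sd: float
    iou_mean: float
    iou_sd: float
    per_image_dice: np.ndarray
    per_image_iou: np.ndarray

    @classmethod
    def from_pairs(cls, dice: np.ndarray, iou: np.ndarray) -> "SegMetrics":
        dice = np.asarray(dice, dtype=float)
        iou = np.asarray(iou, dtype=float)
        return cls(
            dice_mean=float(dice.mean()),
            dice_sd=float(dice.std(ddof=1)) if dice.size > 1 else 0.0,
            iou_mean=float(iou.mean()),
            iou_sd=float(iou.std(ddof=1)) if iou.size > 1 else 0.0,
            per_image_dice=dice,
            per_image_iou=iou,
        )


def dice_iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> tuple[float, float]:
    """Dice = 2|A&B| / (|A|+|B|) and IoU = |A&B| / |A|B| for binary masks.

    Conventions for degenerate masks: both empty -> (1, 1); exactly one
    empty -> (0, 0).
    """
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise InputError("pred_mask and true_mask must have the same shape")
    a = pred_mask.astype(bool)
    b = true_mask.astype(bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0
    inter = int((a & b).sum())
    union = na + nb - inter
    if inter == 0:
        return 0.0, 0.0
    return 2.0 * inter / (na + nb), inter / union


def loss_bce_softdice(
    pred_probs: np.ndarray,
    true_mask: np.ndarray,
    w_bce: float = 1.0,
    w_dice: float = 1.0,
    smooth: float = 1.0,
) -> float:
    """Combined loss: w1 * BCE + w2 * (1 - (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps)).

    ``pred_probs`` must lie strictly inside (0, 1). The soft-Dice term is
    computed per sample (leading axis) and averaged; with a single image the
    whole array is one sample.
    """
    p = np.asarray(pred_probs, dtype=float)
    g = np.asarray(true_mask, dtype=float)
    if p.shape != g.shape:
        raise InputError("pred_probs and true_mask must have the same shape")
    if np.any(p <= 0) or np.any(p >= 1):
        raise InputError("pred_probs must lie strictly in (0, 1)")
    bce = float(-(g * np.log(p) + (1 - g) * np.log(1 - p)).mean())
    if p.ndim < 3:
        p = p[None]
        g = g[None]
    axes = tuple(range(1, p.ndim))
    dice = (2 * (p * g).sum(axes) + smooth) / (p.sum(axes) + g.sum(axes) + smooth)
    return w_bce * bce + w_dice * float((1 - dice).mean())


def bce_softdice_from_logits(
    logits: np.ndarray, true_mask: np.ndarray, w_bce: float, w_dice: float, smooth: float
) -> tuple[float, np.ndarray]:
    """Numerically stable loss and its gradient w.r.t. the logits.

    Used by the training loop: returns (loss, dloss/dlogits) for a batch of
    shape (N, H, W).
    """
    g = true_mask.astype(np.float32)
    p = sigmoid(logits)
    m = float(logits.size)
    # BCE on logits: log(1+exp(-|z|)) + max(z,0) - z*g
    bce = float((np.logaddexp(0.0, -np.abs(logits)) + np.maximum(logits, 0) - logits * g).mean())
    dbce = (p - g) / m

    axes = (1, 2)
    num = 2 * (p * g).sum(axes) + smooth
    den = p.sum(axes) + g.sum(axes) + smooth
    dice = num / den
    n = logits.shape[0]
    # d(1 - num/den)/dp = -(2g*den - num)/den^2, averaged over the batch
    ddice_dp = -(2 * g * den[:, None, None] - num[:, None, None]) / (den[:, None, None] ** 2 * n)
    ddice = ddice_dp * p * (1 - p)

    loss = w_bce * bce + w_dice * float((1 - dice).mean())
    grad = (w_bce * dbce + w_dice * ddice).astype(np.float32)
    return loss, grad
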