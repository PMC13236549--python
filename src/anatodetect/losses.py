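"""Detection losses: focal classification, Dice/CE segmentation, GIoU.

The multitask training objective is the unweighted sum

    L_total = L_Dice_seg + L_CE_seg + L_GIoU_reg + L_CE_cls

with the classification term a focal-modulated cross-entropy.  The focal
weighting used here multiplies the positive term by ``alpha`` and modulates
both terms by the (1 - p_t)^gamma factor; with gamma = 0 and alpha = 1 it
reduces exactly to plain binary cross-entropy.

Each loss exists twice: a plain-numpy form (the public, oracle-testable
contract) and an autograd form (suffix ``_t``) used in the training graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "DetectionLossTerms", "focal_ce", "seg_losses", "soft_dice_loss",
    "giou_loss_arrays",
]

_EPS = 1e-7
_DICE_EPS = 1e-5


@dataclass(frozen=True)
class DetectionLossTerms:
    """The four reported terms of the multitask objective and their sum."""

    l_dice_seg: float
    l_ce_seg: float
    l_giou_reg: float
    l_ce_cls: float

    def __post_init__(self):
        for name, v in (("l_dice_seg", self.l_dice_seg), ("l_ce_seg", self.l_ce_seg),
                        ("l_giou_reg", self.l_giou_reg), ("l_ce_cls", self.l_ce_cls)):
            if v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")

    @property
    def l_total(self) -> float:
        return self.l_dice_seg + self.l_ce_seg + self.l_giou_reg + self.l_ce_cls


# ---------------------------------------------------------------------------
# focal classification loss
# ---------------------------------------------------------------------------


def focal_ce(pred_prob, target, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Focal cross-entropy averaged over the given (non-ignored) anchors.

    ``pred_prob`` are foreground probabilities in (0, 1); ``target`` is a 0/1
    array.  gamma = 0, alpha = 1 recovers plain binary cross-entropy.
    """
    p = np.clip(np.asarray(pred_prob, dtype=np.float64), _EPS, 1 - _EPS)
    t = np.asarray(target, dtype=np.float64)
    pos = alpha * t * (1 - p) ** gamma * (-np.log(p))
    neg = (1 - t) * p**gamma * (-np.log(1 - p))
    return float((pos + neg).mean())


def focal_ce_t(logits: Tensor, target: np.ndarray, gamma: float, alpha: float,
               normalizer: float) -> Tensor:
    """Autograd focal loss on logits (softplus form, saturation-safe);
    sum / ``normalizer``."""
    t = Tensor(target.astype(np.float32))
    p = logits.sigmoid()
    pos = (p * -1.0 + 1.0) ** gamma * (logits * -1.0).softplus() * t * alpha
    neg = p**gamma * logits.softplus() * (t * -1.0 + 1.0)
    return (pos + neg).sum() * (1.0 / normalizer)


# ---------------------------------------------------------------------------
# segmentation losses
# ---------------------------------------------------------------------------


def soft_dice_loss(pred_prob, gt_mask, eps: float = _DICE_EPS) -> float:
    p = np.asarray(pred_prob, dtype=np.float64)
    g = np.asarray(gt_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    inter = (p * g).sum()
    return float(1.0 - (2 * inter + eps) / (p.sum() + g.sum() + eps))


def seg_losses(pred_mask_prob, gt_mask) -> tuple[float, float]:
    """(soft Dice loss, voxel-mean binary cross-entropy)."""
    p = np.asarray(pred_mask_prob, dtype=np.float64)
    g = np.asarray(gt_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    dice = soft_dice_loss(p, g)
    pc = np.clip(p, _EPS, 1 - _EPS)
    ce = float(-(g * np.log(pc) + (1 - g) * np.log(1 - pc)).mean())
    return dice, ce


def seg_losses_t(logits: Tensor, gt_mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """Soft Dice + BCE on segmentation logits (BCE in softplus form)."""
    g = Tensor(gt_mask.astype(np.float32))
    prob = logits.sigmoid()
    inter = (prob * g).sum()
    dice = 1.0 - (inter * 2.0 + _DICE_EPS) / (prob.sum() + g.sum() + _DICE_EPS)
    ce = (g * (logits * -1.0).softplus() + (g * -1.0 + 1.0) * logits.softplus()).mean()
    return dice, ce


# ---------------------------------------------------------------------------
# GIoU regression loss
# ---------------------------------------------------------------------------


def giou_loss_arrays(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Per-row 1 - GIoU for (N, 6) box arrays (numpy form)."""
    pred = np.asarray(pred, dtype=np.float64).reshape(-1, 6)
    target = np.asarray(target, dtype=np.float64).reshape(-1, 6)
    ilo = np.maximum(pred[:, :3], target[:, :3])
    ihi = np.minimum(pred[:, 3:], target[:, 3:])
    inter = np.prod(np.clip(ihi - ilo, 0, None), axis=1)
    vp = np.prod(pred[:, 3:] - pred[:, :3], axis=1)
    vt = np.prod(target[:, 3:] - target[:, :3], axis=1)
    union = vp + vt - inter
    elo = np.minimum(pred[:, :3], target[:, :3])
    ehi = np.maximum(pred[:, 3:], target[:, 3:])
    enc = np.prod(ehi - elo, axis=1)
    giou = inter / union - (enc - union) / enc
    return 1.0 - giou


def _prod3(x: Tensor) -> Tensor:
    return x[:, 0] * x[:, 1] * x[:, 2]


def giou_loss_t(pred_lo: Tensor, pred_hi: Tensor, target: np.ndarray) -> Tensor:
    """Mean 1 - GIoU between predicted (lo, hi) tensors and (N, 6) targets."""
    tlo = Tensor(target[:, :3].astype(np.float32))
    thi = Tensor(target[:, 3:].astype(np.float32))
    ilo = pred_lo.maximum(tlo)
    ihi = pred_hi.minimum(thi)
    inter = _prod3((ihi - ilo).clamp_min(0.0))
    vp = _prod3((pred_hi - pred_lo).clamp_min(1e-4))
    vt = _prod3(thi - tlo)
    union = vp + vt - inter
    elo = pred_lo.minimum(tlo)
    ehi = pred_hi.maximum(thi)
    enc = _prod3(ehi - elo).clamp_min(1e-4)
    giou = inter / union - (enc - union) / enc
    return (1.0 - giou).mean()


def squash_deltas_t(raw: Tensor) -> Tensor:
    """Bound raw head outputs smoothly: centers to (-2, 2) anchor extents,
    log shape ratios to (-3, 3).  tanh keeps gradients alive at the bounds
    (a hard clamp would freeze runaway regressions permanently)."""
    c = (raw[:, :3] * 0.5).tanh() * 2.0
    s = (raw[:, 3:] * (1.0 / 3.0)).tanh() * 3.0
    from .nn import concatenate
    return concatenate([c, s], axis=1)


def squash_deltas(raw: np.ndarray) -> np.ndarray:
    """Numpy twin of :func:`squash_deltas_t` for inference."""
    raw = np.asarray(raw, dtype=np.float64).reshape(-1, 6)
    return np.concatenate([2.0 * np.tanh(raw[:, :3] / 2.0),
                           3.0 * np.tanh(raw[:, 3:] / 3.0)], axis=1)


def decode_delta_t(raw_deltas: Tensor, anchors: np.ndarray) -> tuple[Tensor, Tensor]:
    """Differentiable squash + decode of (N, 6) delta tensors vs anchors."""
    deltas = squash_deltas_t(raw_deltas)
    anchors = np.asarray(anchors, dtype=np.float32).reshape(-1, 6)
    ac = Tensor((anchors[:, :3] + anchors[:, 3:]) / 2)
    asz = Tensor(anchors[:, 3:] - anchors[:, :3])
    c = ac + deltas[:, :3] * asz
    s = asz * deltas[:, 3:].exp()
    return c - s * 0.5, c + s * 0.5
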