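"""Detector training: patch sampling, the multitask loss, the SGD loop.

The optimisation recipe follows the warm polynomial-decay schedule: SGD with
Nesterov momentum 0.9, weight decay 3e-5, a linear warm-up from 1e-6 to the
base rate 0.01, then polynomial decay with gamma 0.9.  Full-scale defaults
(50 epochs x 2500 iterations, 96^3 patches, batch 2) are encoded in
:class:`DetTrainConfig`; desk-scale runs shrink epochs/patches through
:func:`desk_det_config` without touching the recipe's structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .anchors import (AnchorConfig, build_anchors, desk_anchor_config,
                      match_anchors)
from .augment import AugmentConfig, Sample, augment
from .boxes import LesionBox3D, boxes_from_mask, boxes_to_array
from .checkpoint import load_checkpoint, save_checkpoint
from .losses import (DetectionLossTerms, decode_delta_t, focal_ce_t,
                     giou_loss_t, seg_losses_t)
from .networks import (CNNEncoderConfig, DetectionNetwork, SwinEncoderConfig,
                       build_encoder, desk_cnn_config, desk_swin_config)
from .phantom import CaseRecord
from .ssl import normalize_channels

__all__ = [
    "DetTrainConfig", "desk_det_config", "DetectorModel",
    "detection_loss", "train_detector", "case_channels",
    "save_detector", "load_detector",
]


@dataclass(frozen=True)
class DetTrainConfig:
    """Supervised detection training schedule (full-scale defaults)."""

    epochs: int = 50
    iterations_per_epoch: int = 2500
    batch_size: int = 2
    patch_size: int = 96
    learning_rate: float = 0.01
    momentum: float = 0.9
    nesterov: bool = True
    weight_decay: float = 3e-5
    warmup_iterations: int = 4000
    warmup_start_lr: float = 1e-6
    poly_gamma: float = 0.9
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    pos_iou: float = 0.5
    ignore_low: float = 0.4
    lesion_patch_fraction: float = 0.5
    cls_normalizer: str = "positives"   # or "anchors"
    grad_clip: float = 12.0
    fpn_width: int = 32
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.iterations_per_epoch, self.batch_size,
               self.patch_size) <= 0:
            raise ValueError("schedule sizes must be positive")
        if not 0.0 <= self.lesion_patch_fraction <= 1.0:
            raise ValueError("lesion_patch_fraction must be in [0, 1]")
        if self.cls_normalizer not in ("positives", "anchors"):
            raise ValueError("cls_normalizer must be 'positives' or 'anchors'")


def desk_det_config(**overrides) -> DetTrainConfig:
    """CPU-scale schedule used for the miniature phantom experiments."""
    base = dict(epochs=6, iterations_per_epoch=25, batch_size=2, patch_size=48,
                warmup_iterations=20, fpn_width=16,
                augment=AugmentConfig(p_mirror=0.5, p_noise=0.1, p_blur=0.0,
                                      p_brightness=0.15))
    base.update(overrides)
    return DetTrainConfig(**base)


# ---------------------------------------------------------------------------
# sample assembly
# ---------------------------------------------------------------------------


def case_channels(case: CaseRecord, use_organ_channel: bool) -> np.ndarray:
    """Stack normalised network input channels: PET, CT[, organ labels].

    The organ channel is the integer label map scaled by the maximum table
    label, giving a single [0, 1] channel rather than a one-hot stack.
    """
    chans = [normalize_channels(case.pet.data[None])[0],
             normalize_channels(case.ct.data[None])[0]]
    if use_organ_channel:
        max_label = max(case.organs.label_table, default=1)
        chans.append(case.organs.labels.astype(np.float32) / max_label)
    return np.stack(chans)


def _sample_patch(case: CaseRecord, channels: np.ndarray, patch: int,
                  lesion_centered: bool, rng) -> Sample:
    shape = case.lesion_mask.shape
    if all(s <= patch for s in shape):
        return Sample(channels.copy(), case.organs.labels.copy(),
                      case.lesion_mask.copy(), list(case.gt_boxes))
    max_o = [max(s - patch, 0) for s in shape]
    if lesion_centered and case.gt_boxes:
        box = case.gt_boxes[int(rng.integers(len(case.gt_boxes)))]
        center = [(l + h) / 2 for l, h in zip(box.lo, box.hi)]
        origin = [int(np.clip(round(c - patch / 2), 0, m))
                  for c, m in zip(center, max_o)]
    else:
        origin = [int(rng.integers(0, m + 1)) for m in max_o]
    sl = tuple(slice(o, o + patch) for o in origin)
    mask = case.lesion_mask[sl]
    return Sample(channels[(slice(None),) + sl].copy(),
                  case.organs.labels[sl].copy(), mask.copy(),
                  boxes_from_mask(mask))


# ---------------------------------------------------------------------------
# multitask loss
# ---------------------------------------------------------------------------


def _flatten_heads(outputs: dict) -> tuple[Tensor, Tensor]:
    """Head outputs -> (cls (N, A_tot), reg (N, A_tot, 6)) matching the
    anchor ordering of :func:`build_anchors`."""
    cls_flat, reg_flat = [], []
    for cls, reg in zip(outputs["cls"], outputs["reg"]):
        n, a, d, h, w = cls.shape
        cls_flat.append(cls.reshape(n, a * d * h * w))
        reg_flat.append(reg.reshape(n, a, 6, d, h, w)
                        .transpose(0, 1, 3, 4, 5, 2)
                        .reshape(n, a * d * h * w, 6))
    return nn.concatenate(cls_flat, axis=1), nn.concatenate(reg_flat, axis=1)


def detection_loss(outputs: dict, anchors: np.ndarray,
                   assignments: list[np.ndarray],
                   gt_boxes: list[list[LesionBox3D]],
                   gt_masks: np.ndarray, gamma: float = 2.0,
                   alpha: float = 0.25, cls_normalizer: str = "anchors"):
    """Multitask detection loss; returns (total Tensor, DetectionLossTerms).

    Classification is focal cross-entropy over positive and negative anchors
    (ignored anchors excluded); GIoU regression runs on positive anchors
    only; Dice + CE supervise the auxiliary segmentation head.  The total is
    the unweighted sum of the four terms averaged over the batch.
    """
    cls_flat, reg_flat = _flatten_heads(outputs)
    seg_logit = outputs["seg"]
    n = cls_flat.shape[0]
    zero = Tensor(np.float32(0.0))
    dice_t = ce_seg_t = giou_t = cls_t = zero
    for i in range(n):
        assign = assignments[i]
        keep = assign != -2
        target = (assign >= 0).astype(np.float32)
        if cls_normalizer == "positives":
            norm = float(max((assign >= 0).sum(), 1))
        else:
            norm = float(max(keep.sum(), 1))
        cls_t = cls_t + focal_ce_t(cls_flat[i][keep], target[keep], gamma, alpha, norm)
        pos_idx = np.flatnonzero(assign >= 0)
        if pos_idx.size and gt_boxes[i]:
            deltas = reg_flat[i][pos_idx]
            lo, hi = decode_delta_t(deltas, anchors[pos_idx])
            targets = boxes_to_array(gt_boxes[i])[assign[pos_idx]]
            giou_t = giou_t + giou_loss_t(lo, hi, targets)
        d_t, c_t = seg_losses_t(seg_logit[i, 0], gt_masks[i])
        dice_t = dice_t + d_t
        ce_seg_t = ce_seg_t + c_t
    scale = 1.0 / n
    dice_t, ce_seg_t = dice_t * scale, ce_seg_t * scale
    giou_t, cls_t = giou_t * scale, cls_t * scale
    total = dice_t + ce_seg_t + giou_t + cls_t
    terms = DetectionLossTerms(
        l_dice_seg=float(dice_t.item()), l_ce_seg=float(ce_seg_t.item()),
        l_giou_reg=float(max(giou_t.item(), 0.0)), l_ce_cls=float(cls_t.item()))
    return total, terms


# ---------------------------------------------------------------------------
# model wrapper + training loop
# ---------------------------------------------------------------------------


@dataclass
class DetectorModel:
    """A trained detector plus everything needed to run or reload it."""

    network: DetectionNetwork
    encoder_kind: str
    use_organ_channel: bool
    anchor_cfg: AnchorConfig
    patch_size: int
    enc_cfg: object = None

    @property
    def in_channels(self) -> int:
        return 3 if self.use_organ_channel else 2


def _batch_assignments(samples: list[Sample], anchors_flat: np.ndarray,
                       cfg: DetTrainConfig) -> list[np.ndarray]:
    return [match_anchors(anchors_flat, s.boxes, cfg.pos_iou, cfg.ignore_low)
            for s in samples]


def train_detector(train_cases: list[CaseRecord], val_cases: list[CaseRecord],
                   encoder_kind: str = "cnn_unet",
                   use_organ_channel: bool = False,
                   det_cfg: DetTrainConfig | None = None,
                   anchor_cfg: AnchorConfig | None = None,
                   enc_cfg=None, pretrained_encoder_state: dict | None = None):
    """Train a detector; returns (DetectorModel, history DataFrame).

    ``use_organ_channel`` controls nothing but the presence of the third
    input channel, so with/without-anatomy ablations differ only in the
    first-layer width.
    """
    if not train_cases:
        raise ValueError("no training cases")
    det_cfg = det_cfg or desk_det_config()
    anchor_cfg = anchor_cfg or desk_anchor_config()
    in_ch = 3 if use_organ_channel else 2
    if enc_cfg is None:
        enc_cfg = (desk_cnn_config(in_ch) if encoder_kind in ("cnn", "cnn_unet")
                   else desk_swin_config(in_ch))
    if enc_cfg.in_channels != in_ch:
        raise ValueError(f"encoder config expects {enc_cfg.in_channels} input "
                         f"channels but use_organ_channel implies {in_ch}")
    rng = np.random.default_rng(det_cfg.seed)
    encoder = build_encoder(encoder_kind, enc_cfg,
                            rng=np.random.default_rng(det_cfg.seed + 1))
    if pretrained_encoder_state is not None:
        encoder.load_state_dict(pretrained_encoder_state)
    network = DetectionNetwork(encoder, fpn_width=det_cfg.fpn_width,
                               anchors_per_loc=anchor_cfg.anchors_per_location,
                               rng=np.random.default_rng(det_cfg.seed + 2))
    opt = nn.SGD(network.parameters(), lr=det_cfg.learning_rate,
                 momentum=det_cfg.momentum, nesterov=det_cfg.nesterov,
                 weight_decay=det_cfg.weight_decay)

    patch = det_cfg.patch_size
    patch_shape = (patch,) * 3
    anchors_levels = build_anchors(patch_shape, anchor_cfg)
    anchors_flat = np.concatenate(anchors_levels, axis=0)

    train_channels = [case_channels(c, use_organ_channel) for c in train_cases]
    val_channels = [case_channels(c, use_organ_channel) for c in val_cases]

    total_iters = det_cfg.epochs * det_cfg.iterations_per_epoch
    it = 0
    history = []
    lr_log = []
    for epoch in range(1, det_cfg.epochs + 1):
        sums = np.zeros(5)
        for _ in range(det_cfg.iterations_per_epoch):
            lr = nn.warmup_poly_lr(it, total_iters, det_cfg.learning_rate,
                                   det_cfg.warmup_iterations,
                                   det_cfg.warmup_start_lr, det_cfg.poly_gamma)
            opt.lr = lr
            lr_log.append(lr)
            samples = []
            for _ in range(det_cfg.batch_size):
                ci = int(rng.integers(len(train_cases)))
                lesioned = rng.random() < det_cfg.lesion_patch_fraction
                s = _sample_patch(train_cases[ci], train_channels[ci], patch,
                                  lesioned, rng)
                s = augment(s, det_cfg.augment, int(rng.integers(0, 2**31 - 1)))
                samples.append(s)
            x = Tensor(np.stack([s.image for s in samples]))
            masks = np.stack([s.lesion_mask for s in samples])
            assigns = _batch_assignments(samples, anchors_flat, det_cfg)
            outputs = network(x)
            total, terms = detection_loss(
                outputs, anchors_flat, assigns, [s.boxes for s in samples],
                masks, det_cfg.focal_gamma, det_cfg.focal_alpha,
                det_cfg.cls_normalizer)
            network.zero_grad()
            total.backward()
            nn.clip_grad_norm(network.parameters(), det_cfg.grad_clip)
            opt.step()
            sums += [terms.l_dice_seg, terms.l_ce_seg, terms.l_giou_reg,
                     terms.l_ce_cls, terms.l_total]
            it += 1
        means = sums / det_cfg.iterations_per_epoch
        val_total = _validation_loss(network, val_cases, val_channels,
                                     anchors_flat, det_cfg) if val_cases else np.nan
        history.append({"epoch": epoch, "l_dice_seg": means[0],
                        "l_ce_seg": means[1], "l_giou_reg": means[2],
                        "l_ce_cls": means[3], "l_total": means[4],
                        "val_l_total": val_total, "lr": lr_log[-1]})
    model = DetectorModel(network, encoder_kind, use_organ_channel,
                          anchor_cfg, patch, enc_cfg)
    return model, pd.DataFrame(history)


def _validation_loss(network, val_cases, val_channels, anchors_flat,
                     det_cfg) -> float:
    rng = np.random.default_rng(det_cfg.seed + 3)
    totals = []
    with nn.no_grad():
        for case, chans in zip(val_cases, val_channels):
            s = _sample_patch(case, chans, det_cfg.patch_size, True, rng)
            outputs = network(Tensor(s.image[None]))
            assigns = _batch_assignments([s], anchors_flat, det_cfg)
            _, terms = detection_loss(
                outputs, anchors_flat, assigns, [s.boxes],
                s.lesion_mask[None], det_cfg.focal_gamma, det_cfg.focal_alpha,
                det_cfg.cls_normalizer)
            totals.append(terms.l_total)
    return float(np.mean(totals))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_detector(model: DetectorModel, path) -> None:
    meta = {
        "encoder_kind": model.encoder_kind,
        "use_organ_channel": model.use_organ_channel,
        "patch_size": model.patch_size,
        "anchor_cfg": dataclasses.asdict(model.anchor_cfg),
        "enc_cfg": dataclasses.asdict(model.enc_cfg),
        "fpn_width": model.network.fpn.out_width,
    }
    save_checkpoint(path, model.network, meta)


def load_detector(path) -> DetectorModel:
    from .checkpoint import read_checkpoint_meta

    meta = read_checkpoint_meta(path)
    kind = meta["encoder_kind"]
    enc_meta = meta["enc_cfg"]

    def _tup(v):
        return tuple(v) if isinstance(v, list) else v

    enc_meta = {k: _tup(v) for k, v in enc_meta.items()}
    enc_cfg = (CNNEncoderConfig(**enc_meta) if kind in ("cnn", "cnn_unet")
               else SwinEncoderConfig(**enc_meta))
    a = meta["anchor_cfg"]
    anchor_cfg = AnchorConfig(
        base_sizes=tuple(tuple(s) for s in a["base_sizes"]),
        ratios=tuple(tuple(r) for r in a["ratios"]),
        strides=tuple(a["strides"]))
    encoder = build_encoder(kind, enc_cfg)
    network = DetectionNetwork(encoder, fpn_width=meta["fpn_width"],
                               anchors_per_loc=anchor_cfg.anchors_per_location)
    load_checkpoint(path, network)
    model = DetectorModel(network, kind, meta["use_organ_channel"],
                          anchor_cfg, meta["patch_size"], enc_cfg)
    return model
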