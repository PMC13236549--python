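"""Anchor grids, box-delta encoding, and anchor-to-truth matching.

Anchors are dense reference boxes tiled over the stride-4/8/16 feature-map
locations.  The regression targets are center offsets normalised by the
anchor extent and per-axis log shape ratios, so decode(encode(b, a), a) == b
up to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import LesionBox3D, boxes_to_array, pairwise_iou

__all__ = [
    "AnchorConfig", "build_anchors", "match_anchors",
    "encode_delta", "decode_delta", "default_anchor_config",
    "desk_anchor_config", "ASSIGN_NEGATIVE", "ASSIGN_IGNORE",
]

ASSIGN_NEGATIVE = -1
ASSIGN_IGNORE = -2

DETECTION_STRIDES = (4, 8, 16)  # stride-2 level is reserved for segmentation


@dataclass(frozen=True)
class AnchorConfig:
    """Per-level anchor base sizes (voxels) and a shared axis-ratio set.

    Each location carries ``len(base_sizes[level]) * len(ratios)`` anchors; an
    anchor's extent along axis k is ``size * ratios[j][k]``.
    """

    base_sizes: tuple[tuple[float, ...], ...]
    ratios: tuple[tuple[float, float, float], ...] = ((1.0, 1.0, 1.0),)
    strides: tuple[int, ...] = DETECTION_STRIDES

    def __post_init__(self):
        if len(self.base_sizes) != len(self.strides):
            raise ValueError("one size tuple per detection level required")
        counts = {len(s) for s in self.base_sizes}
        if len(counts) != 1:
            raise ValueError("identical size count per level required "
                             "(shared heads need a constant anchor count)")
        if any(s <= 0 for sizes in self.base_sizes for s in sizes):
            raise ValueError("anchor sizes must be positive")
        if any(r <= 0 for ratio in self.ratios for r in ratio):
            raise ValueError("aspect ratios must be positive")

    @property
    def anchors_per_location(self) -> int:
        return len(self.base_sizes[0]) * len(self.ratios)


def default_anchor_config() -> AnchorConfig:
    """Full-scale default: 27 anchors per location (3 sizes x 9 axis-ratio
    combinations) at strides 4/8/16."""
    ratios = tuple((1.0, a, b) for a in (0.5, 1.0, 2.0) for b in (0.5, 1.0, 2.0))
    return AnchorConfig(base_sizes=((6.0, 8.0, 10.0), (12.0, 16.0, 20.0),
                                    (24.0, 32.0, 40.0)),
                        ratios=ratios)


def desk_anchor_config() -> AnchorConfig:
    """Two isotropic anchors per location, sized for desk-scale lesions."""
    return AnchorConfig(base_sizes=((8.0, 12.0), (16.0, 24.0), (32.0, 44.0)))


def build_anchors(patch_shape, cfg: AnchorConfig) -> list[np.ndarray]:
    """Anchor arrays per detection level, each (N_level, 6).

    Within a level, anchor index varies slowest over the (size, ratio)
    combination and then over (z, y, x) locations — matching the layout of a
    head output of shape (A, D, H, W) flattened C-style.
    """
    patch_shape = tuple(int(s) for s in patch_shape)
    if any(s % max(cfg.strides) for s in patch_shape):
        raise ValueError(f"patch shape {patch_shape} not divisible by the "
                         f"maximum stride {max(cfg.strides)}")
    levels = []
    for stride, sizes in zip(cfg.strides, cfg.base_sizes):
        dims = [s // stride for s in patch_shape]
        zz, yy, xx = np.meshgrid(*[(np.arange(d) + 0.5) * stride for d in dims],
                                 indexing="ij")
        centers = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        blocks = []
        for size in sizes:
            for ratio in cfg.ratios:
                ext = np.array([size * r for r in ratio])
                lo = centers - ext / 2
                hi = centers + ext / 2
                blocks.append(np.concatenate([lo, hi], axis=1))
        levels.append(np.concatenate(blocks, axis=0))
    return levels


def encode_delta(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """(N, 6) boxes vs anchors -> (N, 6) deltas [dz, dy, dx, lz, ly, lx]."""
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 6)
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 6)
    bc = (boxes[:, :3] + boxes[:, 3:]) / 2
    bs = boxes[:, 3:] - boxes[:, :3]
    ac = (anchors[:, :3] + anchors[:, 3:]) / 2
    asz = anchors[:, 3:] - anchors[:, :3]
    return np.concatenate([(bc - ac) / asz, np.log(bs / asz)], axis=1)


def decode_delta(deltas: np.ndarray, anchors: np.ndarray,
                 patch_shape=None) -> np.ndarray:
    """Invert :func:`encode_delta`; optionally clip to the patch bounds.

    Clipping never produces a degenerate box: extents are floored at one
    voxel inside the patch.
    """
    deltas = np.asarray(deltas, dtype=float).reshape(-1, 6)
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 6)
    ac = (anchors[:, :3] + anchors[:, 3:]) / 2
    asz = anchors[:, 3:] - anchors[:, :3]
    c = ac + deltas[:, :3] * asz
    s = asz * np.exp(deltas[:, 3:])
    lo = c - s / 2
    hi = c + s / 2
    if patch_shape is not None:
        bound = np.asarray(patch_shape, dtype=float)
        lo = np.clip(lo, 0.0, bound - 1.0)
        hi = np.clip(hi, 1.0, bound)
        hi = np.maximum(hi, lo + 1.0)
        lo = np.minimum(lo, hi - 1.0)
    return np.concatenate([lo, hi], axis=1)


def match_anchors(anchors: np.ndarray, gt_boxes: list[LesionBox3D],
                  pos_iou: float = 0.5, ignore_low: float = 0.4) -> np.ndarray:
    """Assign every anchor to {positive gt index, negative, ignore}.

    An anchor is positive iff its best IoU >= ``pos_iou`` (assigned to the
    argmax gt, ties by lowest gt index), ignored when its best IoU falls in
    [ignore_low, pos_iou), negative otherwise.  Each ground-truth box with at
    least one overlapping anchor additionally force-matches its single best
    anchor (ties by lowest anchor index), so no target is left unsupervised.
    """
    if not 0.0 <= ignore_low < pos_iou <= 1.0:
        raise ValueError("need 0 <= ignore_low < pos_iou <= 1")
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 6)
    n = anchors.shape[0]
    assignment = np.full(n, ASSIGN_NEGATIVE, dtype=np.int64)
    if not gt_boxes:
        return assignment
    iou = pairwise_iou(anchors, boxes_to_array(gt_boxes))  # (N, G)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(n), best_gt]
    assignment[(best_iou >= ignore_low) & (best_iou < pos_iou)] = ASSIGN_IGNORE
    pos = best_iou >= pos_iou
    assignment[pos] = best_gt[pos]
    for g in range(iou.shape[1]):
        col = iou[:, g]
        if col.max() > 0:
            assignment[int(col.argmax())] = g
    return assignment
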