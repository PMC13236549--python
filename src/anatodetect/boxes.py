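"""Axis-aligned 3D boxes and the operations the detector builds on.

Boxes live in voxel coordinates with the fixed (z, y, x) axis order, 0-based,
half-open: a box occupies voxels ``lo <= v < hi``.  Volumes and overlaps are
therefore exact integer-free products of extents, which keeps IoU/GIoU free of
off-by-one ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class LesionBox3D:
    """An axis-aligned box: ``lo`` inclusive, ``hi`` exclusive, (z, y, x)."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    label: int = 1
    score: float | None = None

    def __post_init__(self):
        lo = tuple(float(v) for v in self.lo)
        hi = tuple(float(v) for v in self.hi)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if len(lo) != 3 or len(hi) != 3:
            raise ValueError("boxes are 3D: lo and hi need three components")
        if not all(h > l for l, h in zip(lo, hi)):
            raise ValueError(f"degenerate box: hi must exceed lo, got lo={lo} hi={hi}")

    @property
    def volume(self) -> float:
        return float(np.prod([h - l for l, h in zip(self.lo, self.hi)]))

    def as_array(self) -> np.ndarray:
        return np.array([*self.lo, *self.hi], dtype=float)


def boxes_to_array(boxes: list[LesionBox3D]) -> np.ndarray:
    """Stack boxes into an (N, 6) array [lo_z, lo_y, lo_x, hi_z, hi_y, hi_x]."""
    if not boxes:
        return np.zeros((0, 6), dtype=float)
    return np.stack([b.as_array() for b in boxes])


def array_to_boxes(arr: np.ndarray, scores=None, label: int = 1) -> list[LesionBox3D]:
    out = []
    for i, row in enumerate(np.asarray(arr, dtype=float).reshape(-1, 6)):
        out.append(LesionBox3D(tuple(row[:3]), tuple(row[3:]), label=label,
                               score=None if scores is None else float(scores[i])))
    return out


def pairwise_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N, 6) and (M, 6) box arrays."""
    a = np.asarray(a, dtype=float).reshape(-1, 6)
    b = np.asarray(b, dtype=float).reshape(-1, 6)
    lo = np.maximum(a[:, None, :3], b[None, :, :3])
    hi = np.minimum(a[:, None, 3:], b[None, :, 3:])
    inter = np.prod(np.clip(hi - lo, 0.0, None), axis=-1)
    vol_a = np.prod(a[:, 3:] - a[:, :3], axis=-1)
    vol_b = np.prod(b[:, 3:] - b[:, :3], axis=-1)
    union = vol_a[:, None] + vol_b[None, :] - inter
    return inter / union


def iou_3d(a: LesionBox3D, b: LesionBox3D) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    return float(pairwise_iou(a.as_array(), b.as_array())[0, 0])


def giou_3d(a: LesionBox3D, b: LesionBox3D) -> float:
    """Generalized IoU: IoU minus the enclosing-box penalty; in (-1, 1]."""
    arr_a, arr_b = a.as_array(), b.as_array()
    iou = float(pairwise_iou(arr_a, arr_b)[0, 0])
    enc_lo = np.minimum(arr_a[:3], arr_b[:3])
    enc_hi = np.maximum(arr_a[3:], arr_b[3:])
    enc = float(np.prod(enc_hi - enc_lo))
    inter_lo = np.maximum(arr_a[:3], arr_b[:3])
    inter_hi = np.minimum(arr_a[3:], arr_b[3:])
    inter = float(np.prod(np.clip(inter_hi - inter_lo, 0.0, None)))
    union = a.volume + b.volume - inter
    return iou - (enc - union) / enc


def giou_loss_3d(a: LesionBox3D, b: LesionBox3D) -> float:
    """1 - GIoU, in [0, 2)."""
    return 1.0 - giou_3d(a, b)


def nms(detections: list[LesionBox3D], iou_threshold: float) -> list[LesionBox3D]:
    """Greedy non-maximum suppression.

    Detections are visited in descending score (ties broken by lower original
    index); a detection is suppressed when its IoU with an already-kept box is
    at or above ``iou_threshold``.  Idempotent and deterministic.
    """
    if not detections:
        return []
    if any(d.score is None for d in detections):
        raise ValueError("nms needs scored detections")
    arr = boxes_to_array(detections)
    scores = np.array([d.score for d in detections])
    order = np.lexsort((np.arange(len(detections)), -scores))
    iou_mat = pairwise_iou(arr, arr)
    kept: list[int] = []
    for idx in order:
        if all(iou_mat[idx, k] < iou_threshold for k in kept):
            kept.append(int(idx))
    return [detections[i] for i in kept]


def boxes_from_mask(mask: np.ndarray) -> list[LesionBox3D]:
    """Tight bounding boxes of the 26-connected components of a binary mask.

    Returned sorted by (lo_z, lo_y, lo_x).
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary (0/1)")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(mask, structure=structure)
    boxes = []
    for sl in ndimage.find_objects(labeled):
        lo = tuple(float(s.start) for s in sl)
        hi = tuple(float(s.stop) for s in sl)
        boxes.append(LesionBox3D(lo, hi))
    boxes.sort(key=lambda b: b.lo)
    return boxes
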