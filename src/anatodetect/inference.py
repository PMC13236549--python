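"""Sliding-window inference producing scored lesion boxes per case."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .anchors import build_anchors, decode_delta
from .boxes import LesionBox3D, nms
from .training import DetectorModel, case_channels
from .phantom import CaseRecord

__all__ = ["InferenceConfig", "predict", "write_predictions", "read_predictions"]


@dataclass(frozen=True)
class InferenceConfig:
    """Post-processing thresholds applied to raw network output."""

    nms_iou: float = 0.3
    min_confidence: float = 0.05
    min_object_size: float = 0.0     # voxels; boxes below this volume dropped
    max_detections: int = 100
    overlap: float = 0.5             # sliding-window overlap fraction
    top_k_per_patch: int = 100

    def __post_init__(self):
        for name in ("nms_iou", "min_confidence", "overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _window_origins(extent: int, patch: int, step: int) -> list[int]:
    if extent <= patch:
        return [0]
    origins = list(range(0, extent - patch, step))
    origins.append(extent - patch)  # flush final window
    return sorted(set(origins))


def _gaussian_patch_weight(patch: int) -> np.ndarray:
    ax = np.arange(patch) - (patch - 1) / 2
    g = np.exp(-(ax**2) / (2 * (patch / 4) ** 2))
    w = g[:, None, None] * g[None, :, None] * g[None, None, :]
    return (w / w.max()).astype(np.float32)


def predict(model: DetectorModel, case: CaseRecord,
            inf_cfg: InferenceConfig | None = None,
            return_seg: bool = False):
    """Run the detector over a whole case.

    Sliding windows with the configured overlap are scored independently;
    boxes are decoded per window, mapped to whole-volume voxel coordinates,
    pooled and de-duplicated with global NMS, then filtered by minimum size
    and capped.  Volumes smaller than the patch are zero-padded symmetrically
    and boxes mapped back.  Deterministic given the weights.
    """
    inf_cfg = inf_cfg or InferenceConfig()
    patch = model.patch_size
    channels = case_channels(case, model.use_organ_channel)
    shape = np.array(channels.shape[1:])

    pad = np.maximum(patch - shape, 0)
    lo_pad = pad // 2
    if pad.any():
        channels = np.pad(channels, [(0, 0)] + [(int(l), int(p - l))
                                                for l, p in zip(lo_pad, pad)])
    padded_shape = channels.shape[1:]

    anchors_levels = build_anchors((patch,) * 3, model.anchor_cfg)
    anchors_flat = np.concatenate(anchors_levels, axis=0)
    step = max(int(round(patch * (1.0 - inf_cfg.overlap))), 1)
    origins = [(_z, _y, _x)
               for _z in _window_origins(padded_shape[0], patch, step)
               for _y in _window_origins(padded_shape[1], patch, step)
               for _x in _window_origins(padded_shape[2], patch, step)]

    raw: list[LesionBox3D] = []
    seg_acc = np.zeros(padded_shape, dtype=np.float32) if return_seg else None
    seg_w = np.zeros(padded_shape, dtype=np.float32) if return_seg else None
    gw = _gaussian_patch_weight(patch) if return_seg else None

    for oz, oy, ox in origins:
        window = channels[:, oz:oz + patch, oy:oy + patch, ox:ox + patch]
        with nn.no_grad():
            outputs = model.network(Tensor(window[None]))
        cls_np, reg_np = [], []
        for cls, reg in zip(outputs["cls"], outputs["reg"]):
            _, a, d, h, w = cls.shape
            cls_np.append(cls.data[0].reshape(a * d * h * w))
            reg_np.append(reg.data[0].reshape(a, 6, d, h, w)
                          .transpose(0, 2, 3, 4, 1).reshape(a * d * h * w, 6))
        from .nn.tensor import _stable_sigmoid
        scores = _stable_sigmoid(np.concatenate(cls_np))
        deltas = np.concatenate(reg_np, axis=0)
        keep = np.flatnonzero(scores >= inf_cfg.min_confidence)
        if keep.size > inf_cfg.top_k_per_patch:
            keep = keep[np.argsort(-scores[keep])[:inf_cfg.top_k_per_patch]]
        if keep.size:
            from .losses import squash_deltas
            boxes = decode_delta(squash_deltas(deltas[keep]),
                                 anchors_flat[keep], (patch,) * 3)
            boxes[:, :3] += (oz, oy, ox)
            boxes[:, 3:] += (oz, oy, ox)
            for row, s in zip(boxes, scores[keep]):
                raw.append(LesionBox3D(tuple(row[:3]), tuple(row[3:]),
                                       score=float(s)))
        if return_seg:
            from .nn.tensor import _stable_sigmoid
            prob = _stable_sigmoid(outputs["seg"].data[0, 0])
            sl = (slice(oz, oz + patch), slice(oy, oy + patch),
                  slice(ox, ox + patch))
            seg_acc[sl] += prob * gw
            seg_w[sl] += gw

    kept = nms(raw, inf_cfg.nms_iou)
    final = []
    for b in kept:
        lo = np.array(b.lo) - lo_pad
        hi = np.array(b.hi) - lo_pad
        lo = np.clip(lo, 0, shape)
        hi = np.clip(hi, 0, shape)
        if np.any(hi - lo <= 0):
            continue
        box = LesionBox3D(tuple(lo), tuple(hi), score=b.score)
        if box.volume < inf_cfg.min_object_size:
            continue
        final.append(box)
    final.sort(key=lambda b: -b.score)
    final = final[:inf_cfg.max_detections]
    if return_seg:
        seg = seg_acc / np.maximum(seg_w, 1e-8)
        sl = tuple(slice(int(l), int(l + s)) for l, s in zip(lo_pad, shape))
        return final, seg[sl]
    return final


def write_predictions(case_id: str, detections: list[LesionBox3D], path) -> None:
    """Per-case predictions file: JSON with case_id and (lo, hi, score)."""
    payload = {"case_id": case_id,
               "detections": [{"lo": list(b.lo), "hi": list(b.hi),
                               "score": b.score} for b in detections]}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_predictions(path) -> tuple[str, list[LesionBox3D]]:
    data = json.loads(Path(path).read_text())
    dets = [LesionBox3D(tuple(d["lo"]), tuple(d["hi"]), score=d["score"])
            for d in data["detections"]]
    return data["case_id"], dets
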