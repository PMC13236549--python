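"""Lesion-detection scoring: greedy matching, AP, FROC, stratified reports.

Average precision follows the discrete precision/recall sum

    AP = sum_n (R_n - R_{n-1}) * P_n,   R_0 = 0,

with one threshold per distinct confidence score (descending).  Sensitivity
is TP / (TP + FN) at lesion level.  The FROC curve pools all cases and plots
sensitivity against the average number of false positives per case (FPPI);
the scalar FROC score is the mean sensitivity over fixed FPPI operating
points (1/8, 1/4, 1/2, 1, 2, 4, 8 by default).  mAP averages AP over a set
of IoU matching thresholds (0.1..0.5 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boxes import LesionBox3D, boxes_to_array, pairwise_iou

__all__ = [
    "MatchCounts", "CaseMatch", "FROCCurve", "EvalReport",
    "match_case", "sensitivity", "average_precision", "froc", "evaluate",
    "report_to_frame", "DEFAULT_IOU_SET", "DEFAULT_FPPI_POINTS",
]

DEFAULT_IOU_SET = (0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_FPPI_POINTS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn


@dataclass
class CaseMatch:
    """Per-prediction TP flags (score-descending order) plus counts."""

    flags: np.ndarray       # bool, aligned with `scores`
    scores: np.ndarray      # descending
    counts: MatchCounts


@dataclass
class FROCCurve:
    thresholds: np.ndarray
    fppi: np.ndarray
    sensitivity: np.ndarray
    operating_points: tuple[float, ...]
    froc_score: float


@dataclass
class EvalReport:
    per_iou: dict            # iou -> {"ap": float, "froc": float}
    map_score: float
    iou_set: tuple[float, ...]
    per_group: dict = field(default_factory=dict)  # group -> EvalReport


def match_case(preds: list[LesionBox3D], gts: list[LesionBox3D],
               iou_thr: float) -> CaseMatch:
    """Greedy score-descending one-to-one matching.

    Each prediction (highest score first, ties by original index) claims its
    best-overlapping unmatched ground-truth lesion when that IoU reaches
    ``iou_thr``; claimed lesions are consumed.
    """
    if not 0.0 < iou_thr <= 1.0:
        raise ValueError("iou_thr must be in (0, 1]")
    scores = np.array([p.score if p.score is not None else 1.0 for p in preds])
    order = np.lexsort((np.arange(len(preds)), -scores))
    flags = np.zeros(len(preds), dtype=bool)
    if preds and gts:
        iou = pairwise_iou(boxes_to_array([preds[i] for i in order]),
                           boxes_to_array(gts))
        taken = np.zeros(len(gts), dtype=bool)
        for r in range(len(order)):
            row = np.where(taken, -1.0, iou[r])
            g = int(row.argmax())
            if row[g] >= iou_thr:
                flags[r] = True
                taken[g] = True
    tp = int(flags.sum())
    return CaseMatch(flags=flags, scores=scores[order],
                     counts=MatchCounts(tp=tp, fn=len(gts) - tp,
                                        fp=len(preds) - tp))


def sensitivity(counts: MatchCounts) -> float:
    """Lesion-level recall TP / (TP + FN); undefined without lesions."""
    if counts.n_gt == 0:
        raise ValueError("sensitivity undefined for a case without lesions")
    return counts.tp / counts.n_gt


def average_precision(flags, scores, total_gt: int) -> float:
    """Discrete AP over thresholds at each distinct score (descending)."""
    if total_gt <= 0:
        raise ValueError("average precision undefined without ground truth")
    flags = np.asarray(flags, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if flags.size == 0:
        return 0.0
    order = np.lexsort((np.arange(flags.size), -scores))
    flags, scores = flags[order], scores[order]
    tp_cum = np.cumsum(flags)
    n_cum = np.arange(1, flags.size + 1)
    # one evaluated threshold per distinct score: take the last entry of
    # each tied block
    last = np.flatnonzero(np.diff(scores, append=-np.inf) != 0)
    recall = tp_cum[last] / total_gt
    precision = tp_cum[last] / n_cum[last]
    prev_r = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_r) * precision))


def froc(case_matches: list[CaseMatch], n_cases: int,
         operating_points=DEFAULT_FPPI_POINTS) -> FROCCurve:
    """Pooled FROC curve and its scalar score.

    Sensitivity at an operating point is read at the largest achieved FPPI
    not exceeding it (0 when even the loosest cutoff stays above it).  Cases
    without lesions contribute false positives but not to the sensitivity
    denominator.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    total_gt = sum(m.counts.n_gt for m in case_matches)
    flags = np.concatenate([m.flags for m in case_matches]) \
        if case_matches else np.zeros(0, dtype=bool)
    scores = np.concatenate([m.scores for m in case_matches]) \
        if case_matches else np.zeros(0)
    order = np.argsort(-scores, kind="stable")
    flags, scores = flags[order], scores[order]
    if scores.size:
        last = np.flatnonzero(np.diff(scores, append=-np.inf) != 0)
        tp_cum = np.cumsum(flags)[last]
        fp_cum = np.cumsum(~flags)[last]
        thresholds = scores[last]
        fppi = fp_cum / n_cases
        sens = tp_cum / total_gt if total_gt else np.zeros_like(fppi)
    else:
        thresholds = np.zeros(0)
        fppi = np.zeros(0)
        sens = np.zeros(0)
    ops = tuple(operating_points)
    per_op = []
    for op in ops:
        ok = fppi <= op + 1e-12
        per_op.append(float(sens[ok].max()) if ok.any() else 0.0)
    return FROCCurve(thresholds=thresholds, fppi=fppi, sensitivity=sens,
                     operating_points=ops,
                     froc_score=float(np.mean(per_op)) if ops else 0.0)


def evaluate(predictions: dict, ground_truth: dict,
             iou_set=DEFAULT_IOU_SET, groups: dict | None = None,
             operating_points=DEFAULT_FPPI_POINTS) -> EvalReport:
    """Score a cohort: per-IoU AP and FROC, their mAP, optional stratification.

    ``predictions`` and ``ground_truth`` map case_id -> list[LesionBox3D];
    the id sets must agree.  ``groups`` maps case_id -> group key for
    stratified sub-reports.
    """
    missing_preds = sorted(set(ground_truth) - set(predictions))
    missing_gts = sorted(set(predictions) - set(ground_truth))
    if missing_preds or missing_gts:
        raise ValueError(f"case id mismatch: missing predictions for "
                         f"{missing_preds}, missing ground truth for {missing_gts}")
    case_ids = sorted(ground_truth)
    per_iou = {}
    for iou_thr in iou_set:
        matches = [match_case(predictions[cid], ground_truth[cid], iou_thr)
                   for cid in case_ids]
        total_gt = sum(m.counts.n_gt for m in matches)
        flags = np.concatenate([m.flags for m in matches]) if matches else []
        scores = np.concatenate([m.scores for m in matches]) if matches else []
        ap = average_precision(flags, scores, total_gt) if total_gt else 0.0
        fr = froc(matches, n_cases=len(case_ids),
                  operating_points=operating_points)
        per_iou[float(iou_thr)] = {"ap": float(ap), "froc": fr.froc_score}
    map_score = float(np.mean([v["ap"] for v in per_iou.values()]))
    report = EvalReport(per_iou=per_iou, map_score=map_score,
                        iou_set=tuple(float(i) for i in iou_set))
    if groups:
        for g in sorted({groups.get(cid, "") for cid in case_ids}):
            ids = [cid for cid in case_ids if groups.get(cid, "") == g]
            report.per_group[g] = evaluate(
                {cid: predictions[cid] for cid in ids},
                {cid: ground_truth[cid] for cid in ids},
                iou_set=iou_set, operating_points=operating_points)
    return report


def report_to_frame(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """One row per experiment (and per group), Table-style columns."""
    rows = []

    def _row(name, group, rep):
        get = lambda i, k: rep.per_iou.get(i, {}).get(k, np.nan)
        rows.append({
            "experiment": name, "group": group,
            "FROC@0.1": get(0.1, "froc"), "FROC@0.5": get(0.5, "froc"),
            "AP@0.1": get(0.1, "ap"), "AP@0.5": get(0.5, "ap"),
            "mAP@0.1-0.5": rep.map_score,
        })

    for name, rep in reports.items():
        _row(name, "", rep)
        for g, sub in rep.per_group.items():
            _row(name, g, sub)
    return pd.DataFrame(rows)


def report_to_json(report: EvalReport) -> dict:
    out = {"iou_set": list(report.iou_set), "mAP": report.map_score,
           "per_iou": {str(k): v for k, v in report.per_iou.items()}}
    if report.per_group:
        out["per_group"] = {g: report_to_json(sub)
                            for g, sub in report.per_group.items()}
    return out


def load_ground_truth_sidecars(case_dir) -> tuple[dict, dict]:
    """Read gt boxes and groups from the phantom JSON sidecars in a folder."""
    gts, groups = {}, {}
    for path in sorted(Path(case_dir).glob("*.json")):
        meta = json.loads(path.read_text())
        if "gt_boxes" not in meta:
            continue
        cid = meta["case_id"]
        gts[cid] = [LesionBox3D(tuple(b["lo"]), tuple(b["hi"]),
                                label=b.get("label", 1))
                    for b in meta["gt_boxes"]]
        groups[cid] = meta.get("group", "")
    return gts, groups
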