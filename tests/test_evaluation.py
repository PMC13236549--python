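"""Detection metrics vs independent enumeration oracles."""

import numpy as np
import pytest

from anatodetect.boxes import LesionBox3D, iou_3d
from anatodetect.evaluation import (CaseMatch, MatchCounts, average_precision,
                                    evaluate, froc, match_case, sensitivity)


def _box(lo, size=2.0, score=None):
    return LesionBox3D(tuple(lo), tuple(np.array(lo) + size), score=score)


def _match_oracle(preds, gts, thr):
    """Greedy re-derivation with explicit python loops."""
    order = sorted(range(len(preds)),
                   key=lambda i: (-(preds[i].score or 1.0), i))
    taken = set()
    flags = []
    for i in order:
        best, best_iou = None, -1.0
        for g in range(len(gts)):
            if g in taken:
                continue
            v = iou_3d(preds[i], gts[g])
            if v > best_iou:
                best, best_iou = g, v
        if best is not None and best_iou >= thr:
            taken.add(best)
            flags.append(True)
        else:
            flags.append(False)
    return flags


class TestMatchCase:
    def test_perfect(self):
        gts = [_box((0, 0, 0)), _box((10, 10, 10))]
        preds = [_box((0, 0, 0), score=0.9), _box((10, 10, 10), score=0.8)]
        m = match_case(preds, gts, 1.0)
        assert (m.counts.tp, m.counts.fp, m.counts.fn) == (2, 0, 0)

    def test_no_predictions(self):
        m = match_case([], [_box((0, 0, 0))], 0.5)
        assert (m.counts.tp, m.counts.fn, m.counts.fp) == (0, 1, 0)

    def test_one_to_one_consumption(self):
        gt = [_box((0, 0, 0))]
        preds = [_box((0, 0, 0), score=0.9), _box((0, 0, 0), score=0.8)]
        m = match_case(preds, gt, 0.5)
        assert m.counts.tp == 1 and m.counts.fp == 1

    def test_randomized_oracle(self, rng):
        for _ in range(40):
            gts = [_box(lo, size=float(rng.integers(2, 5)))
                   for lo in rng.uniform(0, 10, (4, 3))]
            preds = [_box(lo, size=float(rng.integers(2, 5)),
                          score=float(np.round(rng.random(), 3)))
                     for lo in rng.uniform(0, 10, (10, 3))]
            m = match_case(preds, gts, 0.3)
            assert list(m.flags) == _match_oracle(preds, gts, 0.3)


class TestSensitivity:
    @pytest.mark.parametrize("tp,fn,expected", [(3, 1, 0.75), (0, 5, 0.0),
                                                (4, 4, 0.5)])
    def test_values(self, tp, fn, expected):
        assert sensitivity(MatchCounts(tp, fn, 0)) == pytest.approx(expected)

    def test_undefined_without_lesions(self):
        with pytest.raises(ValueError):
            sensitivity(MatchCounts(0, 0, 3))


def _ap_oracle(flags, scores, total_gt):
    """Exhaustive threshold enumeration of the discrete AP sum."""
    order = sorted(range(len(flags)), key=lambda i: (-scores[i], i))
    flags = [flags[i] for i in order]
    scores = [scores[i] for i in order]
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_r = 0.0, 0.0
    for thr in thresholds:
        sel = [f for f, s in zip(flags, scores) if s >= thr]
        tp = sum(sel)
        r = tp / total_gt
        p = tp / len(sel)
        ap += (r - prev_r) * p
        prev_r = r
    return ap


class TestAveragePrecision:
    def test_all_tp_covering_all_gts(self):
        assert average_precision([True] * 3, [0.9, 0.8, 0.7], 3) == 1.0

    def test_all_fp(self):
        assert average_precision([False] * 4, [0.9, 0.8, 0.7, 0.6], 2) == 0.0

    def test_hand_enumerated_example(self):
        # flags (desc scores) = [TP, FP, TP], 2 gts:
        # (0.5-0)*1 + (1-0.5)*(2/3) = 5/6
        got = average_precision([True, False, True], [0.9, 0.8, 0.7], 2)
        assert got == pytest.approx(5 / 6, abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 20))
            flags = list(rng.random(n) > 0.5)
            scores = list(np.round(rng.random(n), 2))  # ties likely
            total_gt = max(sum(flags), 1) + int(rng.integers(0, 4))
            assert average_precision(flags, scores, total_gt) == \
                pytest.approx(_ap_oracle(flags, scores, total_gt), abs=1e-9)

    def test_undefined_without_gt(self):
        with pytest.raises(ValueError):
            average_precision([True], [0.5], 0)


def _froc_oracle(matches, n_cases, ops):
    flags = np.concatenate([m.flags for m in matches])
    scores = np.concatenate([m.scores for m in matches])
    total_gt = sum(m.counts.n_gt for m in matches)
    per_op = []
    for op in ops:
        best = 0.0
        for thr in sorted(set(scores), reverse=True):
            sel = scores >= thr
            fppi = (~flags[sel]).sum() / n_cases
            sens = flags[sel].sum() / total_gt
            if fppi <= op + 1e-12:
                best = max(best, sens)
        per_op.append(best)
    return float(np.mean(per_op))


class TestFROC:
    def test_no_predictions(self):
        m = CaseMatch(np.zeros(0, bool), np.zeros(0),
                      MatchCounts(0, 2, 0))
        assert froc([m], 1).froc_score == 0.0

    def test_perfect_detection(self):
        m = CaseMatch(np.array([True, True]), np.array([0.9, 0.9]),
                      MatchCounts(2, 0, 0))
        assert froc([m], 1).froc_score == 1.0

    def test_two_case_fixture_matches_oracle(self):
        m1 = CaseMatch(np.array([True, False, True]),
                       np.array([0.9, 0.8, 0.6]), MatchCounts(2, 1, 1))
        m2 = CaseMatch(np.array([False, True]),
                       np.array([0.7, 0.5]), MatchCounts(1, 0, 1))
        ops = (0.125, 0.5, 1.0, 2.0)
        got = froc([m1, m2], 2, operating_points=ops)
        assert got.froc_score == pytest.approx(_froc_oracle([m1, m2], 2, ops),
                                               abs=1e-12)

    def test_monotone_in_cutoff(self, rng):
        matches = []
        for _ in range(4):
            n = int(rng.integers(1, 10))
            flags = rng.random(n) > 0.4
            matches.append(CaseMatch(flags, np.round(rng.random(n), 2),
                                     MatchCounts(int(flags.sum()), 2,
                                                 int((~flags).sum()))))
        curve = froc(matches, 4)
        assert np.all(np.diff(curve.sensitivity) >= -1e-12)
        assert np.all(np.diff(curve.fppi) >= -1e-12)


class TestEvaluate:
    def _cohort(self, rng, n_cases=4):
        gts, preds = {}, {}
        for i in range(n_cases):
            cid = f"c{i}"
            gts[cid] = [_box(lo, size=3) for lo in rng.uniform(0, 20, (2, 3))]
            preds[cid] = [
                _box(np.array(b.lo) + rng.uniform(-1, 1, 3), size=3,
                     score=float(rng.random())) for b in gts[cid]
            ] + [_box(rng.uniform(0, 20, 3), size=3,
                      score=float(rng.random()))]
        return preds, gts

    def test_perfect_predictions_score_one(self):
        gts = {"a": [_box((0, 0, 0)), _box((8, 8, 8))],
               "b": [_box((2, 2, 2))]}
        preds = {cid: [LesionBox3D(b.lo, b.hi, score=1.0) for b in boxes]
                 for cid, boxes in gts.items()}
        rep = evaluate(preds, gts)
        assert rep.map_score == 1.0
        assert all(v["ap"] == 1.0 and v["froc"] == 1.0
                   for v in rep.per_iou.values())

    def test_map_is_mean_of_ap_column(self, rng):
        preds, gts = self._cohort(rng)
        rep = evaluate(preds, gts)
        assert rep.map_score == pytest.approx(
            np.mean([v["ap"] for v in rep.per_iou.values()]))

    def test_stricter_iou_never_scores_higher(self, rng):
        preds, gts = self._cohort(rng)
        rep = evaluate(preds, gts)
        assert rep.per_iou[0.5]["ap"] <= rep.per_iou[0.1]["ap"] + 1e-12
        assert rep.per_iou[0.5]["froc"] <= rep.per_iou[0.1]["froc"] + 1e-12

    def test_group_stratification_matches_standalone(self, rng):
        preds, gts = self._cohort(rng, n_cases=6)
        groups = {cid: ("g1" if i < 3 else "g2")
                  for i, cid in enumerate(sorted(gts))}
        rep = evaluate(preds, gts, groups=groups)
        for g in ("g1", "g2"):
            ids = [cid for cid in gts if groups[cid] == g]
            solo = evaluate({c: preds[c] for c in ids},
                            {c: gts[c] for c in ids})
            assert rep.per_group[g].map_score == pytest.approx(solo.map_score)
            assert rep.per_group[g].per_iou == solo.per_iou

    def test_case_order_invariance(self, rng):
        preds, gts = self._cohort(rng)
        rep1 = evaluate(preds, gts)
        rev = list(reversed(sorted(gts)))
        rep2 = evaluate({c: preds[c] for c in rev}, {c: gts[c] for c in rev})
        assert rep1.per_iou == rep2.per_iou

    def test_id_mismatch_reported(self):
        with pytest.raises(ValueError, match="c1"):
            evaluate({"c0": []}, {"c0": [], "c1": [_box((0, 0, 0))]})
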