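"""Box geometry: IoU/GIoU against voxel-enumeration oracles, NMS, masks."""

import numpy as np
import pytest

from anatodetect.boxes import (LesionBox3D, boxes_from_mask, giou_3d, iou_3d,
                               nms, pairwise_iou)


def _voxel_iou(a: LesionBox3D, b: LesionBox3D) -> float:
    """Brute-force IoU by enumerating integer voxels."""
    def voxels(box):
        lo = [int(v) for v in box.lo]
        hi = [int(v) for v in box.hi]
        return {(z, y, x) for z in range(lo[0], hi[0])
                for y in range(lo[1], hi[1]) for x in range(lo[2], hi[2])}
    va, vb = voxels(a), voxels(b)
    return len(va & vb) / len(va | vb)


def _random_box(rng, extent=10, max_size=5) -> LesionBox3D:
    lo = rng.integers(0, extent - 1, size=3)
    size = rng.integers(1, max_size + 1, size=3)
    return LesionBox3D(tuple(lo), tuple(lo + size))


class TestIoU:
    def test_identity(self):
        b = LesionBox3D((0, 0, 0), (2, 3, 4))
        assert iou_3d(b, b) == 1.0

    def test_disjoint(self):
        assert iou_3d(LesionBox3D((0, 0, 0), (2, 2, 2)),
                      LesionBox3D((5, 5, 5), (7, 7, 7))) == 0.0

    def test_half_shift(self):
        a = LesionBox3D((0, 0, 0), (2, 2, 2))
        b = LesionBox3D((1, 0, 0), (3, 2, 2))
        assert iou_3d(a, b) == pytest.approx(1 / 3)

    def test_matches_voxel_enumeration(self, rng):
        for _ in range(50):
            a, b = _random_box(rng), _random_box(rng)
            assert iou_3d(a, b) == pytest.approx(_voxel_iou(a, b), abs=1e-12)

    def test_symmetry(self, rng):
        a, b = _random_box(rng), _random_box(rng)
        assert iou_3d(a, b) == iou_3d(b, a)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            LesionBox3D((0, 0, 0), (0, 2, 2))


class TestGIoU:
    def test_identity(self):
        b = LesionBox3D((1, 1, 1), (4, 4, 4))
        assert giou_3d(b, b) == pytest.approx(1.0)

    def test_corner_adjacent_cubes(self):
        # IoU 0, enclosing box 4^3 = 64, union 16 -> giou = -48/64
        a = LesionBox3D((0, 0, 0), (2, 2, 2))
        b = LesionBox3D((2, 2, 2), (4, 4, 4))
        assert giou_3d(a, b) == pytest.approx(-0.75)

    def test_receding_boxes_approach_minus_one(self):
        a = LesionBox3D((0, 0, 0), (1, 1, 1))
        vals = []
        for d in (10, 100, 1000):
            b = LesionBox3D((d, 0, 0), (d + 1, 1, 1))
            vals.append(giou_3d(a, b))
        assert vals[0] > vals[1] > vals[2] > -1.0
        assert vals[2] == pytest.approx(-1.0, abs=2e-3)

    def test_direct_formula_oracle(self, rng):
        for _ in range(50):
            a, b = _random_box(rng), _random_box(rng)
            iou = _voxel_iou(a, b)
            enc_lo = np.minimum(a.as_array()[:3], b.as_array()[:3])
            enc_hi = np.maximum(a.as_array()[3:], b.as_array()[3:])
            enc = np.prod(enc_hi - enc_lo)
            inter = iou * (a.volume + b.volume) / (1 + iou)
            union = a.volume + b.volume - inter
            assert giou_3d(a, b) == pytest.approx(iou - (enc - union) / enc,
                                                  abs=1e-9)


def _nms_reference(dets, thr):
    """O(n^2) reference: greedy by (score desc, index asc)."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    kept = []
    for i in order:
        if all(iou_3d(dets[i], dets[j]) < thr for j in kept):
            kept.append(i)
    return [dets[i] for i in kept]


class TestNMS:
    def test_single_detection(self):
        d = [LesionBox3D((0, 0, 0), (2, 2, 2), score=0.7)]
        assert nms(d, 0.5) == d

    def test_duplicate_suppressed(self):
        a = LesionBox3D((0, 0, 0), (2, 2, 2), score=0.9)
        b = LesionBox3D((0, 0, 0), (2, 2, 2), score=0.8)
        assert nms([a, b], 0.5) == [a]

    def test_matches_reference_and_idempotent(self, rng):
        for trial in range(20):
            dets = [LesionBox3D(tuple(lo), tuple(lo + rng.integers(1, 6, 3)),
                                score=float(np.round(rng.random(), 2)))
                    for lo in rng.integers(0, 12, size=(30, 3))]
            kept = nms(dets, 0.3)
            assert kept == _nms_reference(dets, 0.3)
            assert nms(kept, 0.3) == kept

    def test_unscored_rejected(self):
        with pytest.raises(ValueError):
            nms([LesionBox3D((0, 0, 0), (1, 1, 1))], 0.5)


class TestBoxesFromMask:
    def test_filled_cube(self):
        mask = np.zeros((12, 12, 12), dtype=np.uint8)
        mask[4:8, 4:8, 4:8] = 1
        (box,) = boxes_from_mask(mask)
        assert box.lo == (4.0, 4.0, 4.0) and box.hi == (8.0, 8.0, 8.0)

    def test_empty_mask(self):
        assert boxes_from_mask(np.zeros((5, 5, 5))) == []

    def test_corner_touching_cubes_merge_under_26_connectivity(self):
        mask = np.zeros((8, 8, 8), dtype=np.uint8)
        mask[0:2, 0:2, 0:2] = 1
        mask[2:4, 2:4, 2:4] = 1
        assert len(boxes_from_mask(mask)) == 1
        # independent union-find over 26-neighbourhoods agrees
        vox = [tuple(v) for v in np.argwhere(mask)]
        parent = {v: v for v in vox}

        def find(v):
            while parent[v] != v:
                v = parent[v]
            return v

        for v in vox:
            for w in vox:
                if v != w and all(abs(a - b) <= 1 for a, b in zip(v, w)):
                    parent[find(v)] = find(w)
        assert len({find(v) for v in vox}) == 1

    def test_paint_roundtrip_identity(self, rng):
        # non-overlapping boxes with >= 1 voxel gaps are recovered exactly
        mask = np.zeros((30, 30, 30), dtype=np.uint8)
        boxes = []
        for z in (2, 12, 22):
            lo = (z, int(rng.integers(2, 20)), int(rng.integers(2, 20)))
            hi = tuple(l + int(rng.integers(2, 5)) for l in lo)
            mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
            boxes.append(LesionBox3D(lo, hi))
        out = boxes_from_mask(mask)
        assert [(b.lo, b.hi) for b in out] == \
            sorted([(b.lo, b.hi) for b in boxes])

    def test_sorted_by_lo(self):
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[6:8, 0:2, 0:2] = 1
        mask[0:2, 6:8, 6:8] = 1
        out = boxes_from_mask(mask)
        assert out[0].lo < out[1].lo

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            boxes_from_mask(np.full((3, 3, 3), 2))
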