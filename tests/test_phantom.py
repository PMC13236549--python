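"""Phantom generation invariants, NIfTI round-trips, cohort splitting."""

import dataclasses

import numpy as np
import pytest

from anatodetect.phantom import (ImageVolume, LesionPlacementError,
                                 OrganLabelMap, PhantomSpec, decoy_spec,
                                 default_spec, easy_spec, generate_phantom,
                                 load_case, read_nifti, save_case,
                                 split_cohort, write_nifti)


def _flood_fill_count(mask):
    """Independent 26-connected component count by BFS."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    count = 0
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(p, mask.shape)) \
                        and mask[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
    return count


SMALL = dataclasses.replace(easy_spec((32, 32, 32)),
                            lesion_radius_range=(3.0, 5.0))


class TestGeneratePhantom:
    def test_deterministic_bit_identical(self):
        a = generate_phantom(SMALL, seed=7)
        b = generate_phantom(SMALL, seed=7)
        assert np.array_equal(a.pet.data, b.pet.data)
        assert np.array_equal(a.ct.data, b.ct.data)
        assert np.array_equal(a.organs.labels, b.organs.labels)
        assert np.array_equal(a.lesion_mask, b.lesion_mask)
        assert [(x.lo, x.hi) for x in a.gt_boxes] == \
            [(x.lo, x.hi) for x in b.gt_boxes]

    def test_zero_lesions(self):
        spec = dataclasses.replace(SMALL, lesion_count_law=("fixed", 0))
        case = generate_phantom(spec, seed=3)
        assert not case.lesion_mask.any() and case.gt_boxes == []

    def test_fixed_count_matches_flood_fill(self):
        spec = dataclasses.replace(default_spec((64, 64, 64)),
                                   lesion_count_law=("fixed", 5),
                                   lesion_radius_range=(2.5, 4.0))
        case = generate_phantom(spec, seed=5)
        assert _flood_fill_count(case.lesion_mask) == 5
        assert len(case.gt_boxes) == 5

    def test_boxes_are_tight_component_bounds(self):
        case = generate_phantom(SMALL, seed=11)
        for b in case.gt_boxes:
            sl = tuple(slice(int(l), int(h)) for l, h in zip(b.lo, b.hi))
            sub = case.lesion_mask[sl]
            # every face of the box touches lesion voxels
            assert sub.any(axis=(1, 2))[0] and sub.any(axis=(1, 2))[-1]
            assert sub.any(axis=(0, 2))[0] and sub.any(axis=(0, 2))[-1]
            assert sub.any(axis=(0, 1))[0] and sub.any(axis=(0, 1))[-1]

    def test_shared_geometry(self):
        case = generate_phantom(SMALL, seed=2)
        assert case.ct.same_geometry(case.pet)
        assert case.organs.labels.shape == case.ct.shape

    def test_decoy_uptake_and_box_clearance(self):
        spec = dataclasses.replace(
            decoy_spec((48, 48, 48)), noise_sd_pet=0.0, noise_sd_ct=0.0,
            smoothing_sigma_pet=0.0, smoothing_sigma_ct=0.0)
        case = generate_phantom(spec, seed=13)
        hot = [lbl for lbl, cls in case.organs.uptake_class.items()
               if cls == "high"]
        ranges = {i + 1: r.uptake_range
                  for i, r in enumerate(spec.organ_recipes)}
        for lbl in hot:
            vox = case.pet.data[case.organs.labels == lbl]
            if vox.size:
                lo, hi = ranges[lbl]
                assert vox.min() >= lo - 1e-5 and vox.max() <= hi + 1e-5
        # lesion voxels never fall inside a hot organ (uptake stays pure),
        # and no gt box reaches a hot organ's core (inner 60% of its extent)
        hot_mask = np.isin(case.organs.labels, hot)
        assert not (hot_mask & case.lesion_mask.astype(bool)).any()
        core = np.zeros_like(hot_mask)
        grids = np.ogrid[tuple(slice(0, s) for s in hot_mask.shape)]
        for lbl in hot:
            organ = case.organs.labels == lbl
            if not organ.any():
                continue
            coords = np.argwhere(organ)
            center = coords.mean(axis=0)
            semi = (coords.max(axis=0) - coords.min(axis=0)) / 2 + 0.5
            acc = sum(((g - c) / (0.6 * s)) ** 2
                      for g, c, s in zip(grids, center, semi))
            core |= acc <= 1.0
        for b in case.gt_boxes:
            sl = tuple(slice(int(l), int(h)) for l, h in zip(b.lo, b.hi))
            assert not core[sl].any()

    def test_lesions_hyperintense_validated(self):
        with pytest.raises(ValueError, match="hyperintense"):
            PhantomSpec(lesion_uptake_range=(0.5, 2.0))

    def test_infeasible_placement_raises(self):
        spec = dataclasses.replace(SMALL, lesion_count_law=("fixed", 50),
                                   max_placement_tries=10)
        with pytest.raises(LesionPlacementError, match="placed"):
            generate_phantom(spec, seed=1)


class TestTypes:
    def test_volume_requires_3d(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4)))

    def test_positive_spacing(self):
        with pytest.raises(ValueError):
            ImageVolume(np.zeros((4, 4, 4)), spacing=(1, 0, 1))

    def test_labels_must_be_in_table(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[0, 0, 0] = 3
        with pytest.raises(ValueError, match="label_table"):
            OrganLabelMap(labels, {1: "liver"}, {1: "high"})


class TestNiftiIO:
    def test_float_roundtrip(self, tmp_path, rng):
        vol = ImageVolume(rng.random((16, 16, 16)).astype(np.float32),
                          spacing=(3.0, 1.5, 1.5), origin=(1.0, -2.0, 5.0))
        write_nifti(vol, tmp_path / "v.nii.gz")
        back = read_nifti(tmp_path / "v.nii.gz")
        assert np.allclose(back.data, vol.data, atol=1e-6)
        assert back.spacing == (3.0, 1.5, 1.5)
        assert back.origin == (1.0, -2.0, 5.0)

    def test_integer_roundtrip_exact(self, tmp_path, rng):
        vol = ImageVolume(rng.integers(0, 104, (8, 8, 8)).astype(np.int16))
        write_nifti(vol, tmp_path / "l.nii.gz")
        assert np.array_equal(read_nifti(tmp_path / "l.nii.gz").data, vol.data)

    def test_4d_rejected(self, tmp_path):
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4)),
                 str(tmp_path / "x.nii.gz"))
        with pytest.raises(ValueError, match="3D"):
            read_nifti(tmp_path / "x.nii.gz")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_nifti(tmp_path / "nope.nii.gz")

    def test_case_roundtrip(self, tmp_path):
        case = generate_phantom(SMALL, seed=21, group="annotator1")
        save_case(case, tmp_path)
        back = load_case(tmp_path, case.case_id)
        assert np.allclose(back.pet.data, case.pet.data, atol=1e-6)
        assert np.array_equal(back.organs.labels, case.organs.labels)
        assert np.array_equal(back.lesion_mask, case.lesion_mask)
        assert [(b.lo, b.hi) for b in back.gt_boxes] == \
            [(b.lo, b.hi) for b in case.gt_boxes]
        assert back.group == "annotator1"
        assert back.organs.uptake_class == case.organs.uptake_class


class TestSplitCohort:
    def test_published_cohort_sizes(self):
        train, test = split_cohort([f"p{i}" for i in range(872)], 0.8, seed=0)
        assert len(train) == 698 and len(test) == 174

    def test_partition_properties(self):
        ids = [f"p{i}" for i in range(10)]
        train, test = split_cohort(ids, 0.8, seed=5)
        assert len(train) == 8 and len(test) == 2
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    @pytest.mark.parametrize("n,frac", [(7, 0.5), (13, 0.33), (100, 0.8),
                                        (3, 0.9)])
    def test_sizes_sum_to_n(self, n, frac):
        train, test = split_cohort(list(range(n)), frac, seed=1)
        assert len(train) + len(test) == n

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(20)]
        assert split_cohort(ids, 0.7, 3) == split_cohort(ids, 0.7, 3)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            split_cohort(["a", "b", "a"], 0.5, 0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(["a", "b"], 1.0, 0)
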