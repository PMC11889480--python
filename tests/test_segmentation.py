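"""Seeded region growing against an independent flood-fill oracle, ROI
volumetry and printed rounding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import bfs_flood_fill
from vascmorph.segmentation import (SeedPoint, SeedRejectedError,
                                    ToleranceWindow, region_grow,
                                    region_grow_multiseed,
                                    repair_mask_defects, roi_volume,
                                    round_printed)
from vascmorph.volio import ROIMask, VoxelVolume


def vol(data, vs=(10.0, 10.0, 10.0)):
    return VoxelVolume(np.asarray(data, dtype=np.uint16), vs)


class TestRegionGrow:
    def test_uniform_volume_fully_selected(self):
        v = vol(np.full((4, 4, 4), 30000))
        roi = region_grow(v, SeedPoint((2, 1, 3)), ToleranceWindow(1000))
        assert roi.voxel_count == 64

    def test_l_shaped_path_equals_bfs_oracle(self):
        data = np.full((7, 7, 7), 10000, dtype=np.uint16)
        data[1, 1, 1:6] = 40000   # arm along x
        data[1:6, 1, 5] = 40000   # arm along z
        v = vol(data)
        roi = region_grow(v, SeedPoint((1, 1, 2)), ToleranceWindow(1200))
        oracle = bfs_flood_fill(data, (1, 1, 2), 40000, 1200)
        assert np.array_equal(roi.mask, oracle)
        assert roi.voxel_count == oracle.sum() == 9

    def test_zero_tolerance_selects_exact_gray(self):
        data = np.full((5, 5, 5), 20000, dtype=np.uint16)
        data[2, 2, 2] = 20001
        data[2, 2, 3] = 20001
        v = vol(data)
        roi = region_grow(v, SeedPoint((2, 2, 2)), ToleranceWindow(0))
        assert roi.voxel_count == 2
        assert roi.mask[2, 2, 2] and roi.mask[2, 2, 3]

    def test_out_of_bounds_seed(self):
        v = vol(np.zeros((3, 3, 3)))
        with pytest.raises(IndexError):
            region_grow(v, SeedPoint((5, 0, 0)), ToleranceWindow(100))

    def test_rejected_seed_reports_measured_gray(self):
        data = np.full((3, 3, 3), 100, dtype=np.uint16)
        v = vol(data)
        with pytest.raises(SeedRejectedError) as err:
            region_grow(v, SeedPoint((1, 1, 1), reference_gray=40000),
                        ToleranceWindow(1000))
        assert err.value.measured_gray == 100

    def test_connectivity_6_vs_26(self):
        data = np.full((3, 3, 3), 0, dtype=np.uint16)
        data[0, 0, 0] = 40000
        data[1, 1, 1] = 40000  # diagonal neighbour only
        v = vol(data)
        roi26 = region_grow(v, SeedPoint((0, 0, 0)), ToleranceWindow(100),
                            connectivity=26)
        roi6 = region_grow(v, SeedPoint((0, 0, 0)), ToleranceWindow(100),
                           connectivity=6)
        assert roi26.voxel_count == 2
        assert roi6.voxel_count == 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_equivalence_with_bfs_on_random_volumes(self, seed):
        # random volumes up to 20^3, coarse gray plateaus
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 21, size=3))
        data = (rng.integers(0, 5, size=shape) * 1000).astype(np.uint16)
        seed_idx = tuple(rng.integers(0, s) for s in shape)
        tol = float(rng.choice([0, 500, 1000, 1500]))
        conn = int(rng.choice([6, 26]))
        v = vol(data)
        roi = region_grow(v, SeedPoint(seed_idx), ToleranceWindow(tol),
                          connectivity=conn)
        ref = float(data[seed_idx])
        oracle = bfs_flood_fill(data, seed_idx, ref, tol, conn)
        assert np.array_equal(roi.mask, oracle)
        # contract: contains seed, all in window
        assert roi.mask[seed_idx]
        assert np.all(np.abs(data[roi.mask].astype(float) - ref) <= tol)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_tolerance_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        data = (rng.integers(0, 6, size=(10, 10, 10)) * 700).astype(np.uint16)
        seed_idx = tuple(rng.integers(0, 10, size=3))
        v = vol(data)
        small = region_grow(v, SeedPoint(seed_idx), ToleranceWindow(700))
        large = region_grow(v, SeedPoint(seed_idx), ToleranceWindow(1500))
        assert np.all(large.mask[small.mask])


class TestMultiSeed:
    @pytest.fixture
    def two_plateau_volume(self):
        data = np.full((9, 9, 9), 5000, dtype=np.uint16)
        data[1:4, 1:4, 1:4] = 40000
        data[5:8, 5:8, 5:8] = 20000
        return vol(data)

    def test_union_of_disjoint_plateaus(self, two_plateau_volume):
        seeds = [SeedPoint((2, 2, 2)), SeedPoint((6, 6, 6))]
        roi = region_grow_multiseed(two_plateau_volume, seeds,
                                    ToleranceWindow(1200))
        d = two_plateau_volume.data
        oracle = (bfs_flood_fill(d, (2, 2, 2), 40000, 1200)
                  | bfs_flood_fill(d, (6, 6, 6), 20000, 1200))
        assert np.array_equal(roi.mask, oracle)
        assert roi.voxel_count == 54

    def test_duplicate_seeds_idempotent(self, two_plateau_volume):
        one = region_grow_multiseed(two_plateau_volume,
                                    [SeedPoint((2, 2, 2))])
        two = region_grow_multiseed(two_plateau_volume,
                                    [SeedPoint((2, 2, 2)),
                                     SeedPoint((2, 2, 2))])
        assert np.array_equal(one.mask, two.mask)

    def test_one_valid_one_rejected_warns(self, two_plateau_volume):
        seeds = [SeedPoint((2, 2, 2)),
                 SeedPoint((0, 0, 0), reference_gray=60000)]
        with pytest.warns(UserWarning, match="rejected"):
            roi = region_grow_multiseed(two_plateau_volume, seeds,
                                        ToleranceWindow(1200))
        assert roi.voxel_count == 27
        assert len(roi.seeds) == 1

    def test_all_rejected_raises(self, two_plateau_volume):
        seeds = [SeedPoint((0, 0, 0), reference_gray=60000)]
        with pytest.warns(UserWarning):
            with pytest.raises(SeedRejectedError):
                region_grow_multiseed(two_plateau_volume, seeds,
                                      ToleranceWindow(100))

    def test_no_seeds_raises(self, two_plateau_volume):
        with pytest.raises(ValueError):
            region_grow_multiseed(two_plateau_volume, [])


class TestRoiVolume:
    def test_thousand_voxels_at_10um(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:1000] = True
        assert roi_volume(ROIMask(mask), 10.0) == pytest.approx(0.001)

    def test_sphere_within_5pct_of_analytic(self):
        # radius 12 voxels at 5 um isotropic
        n = 30
        z, y, x = np.ogrid[:n, :n, :n]
        mask = (z - 15.0) ** 2 + (y - 15.0) ** 2 + (x - 15.0) ** 2 <= 12 ** 2
        measured = roi_volume(ROIMask(mask), 5.0)
        analytic = 4.0 / 3.0 * np.pi * 0.060 ** 3
        assert abs(measured - analytic) / analytic < 0.05

    def test_empty_mask_zero(self):
        assert roi_volume(ROIMask(np.zeros((4, 4, 4), bool)), 10.0) == 0.0

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(1)
        mask = rng.uniform(size=(6, 8, 10)) < 0.3
        vs = (12.0, 10.0, 8.0)
        base = roi_volume(ROIMask(mask), vs)
        perm = roi_volume(ROIMask(mask.transpose(2, 0, 1)),
                          (vs[2], vs[0], vs[1]))
        assert base == pytest.approx(perm)

    def test_linearity_in_voxel_count(self):
        m1 = np.zeros((5, 5, 5), bool)
        m1[0, 0, :3] = True
        m2 = np.zeros((5, 5, 5), bool)
        m2[0, 0, :] = True
        v1 = roi_volume(ROIMask(m1), 7.0)
        v2 = roi_volume(ROIMask(m2), 7.0)
        assert v2 == pytest.approx(v1 * 5 / 3)

    def test_bad_voxel_size(self):
        with pytest.raises(ValueError):
            roi_volume(ROIMask(np.ones((2, 2, 2), bool)), (0, 1, 1))


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (0.125, 0.13),       # half away from zero, not banker's
        (0.0733, 0.07),
        (2.675, 2.68),
        (-0.125, -0.13),
        (0.05666, 0.06),
        (28.204, 28.20),
    ])
    def test_printed_rounding(self, value, expected):
        assert round_printed(value) == pytest.approx(expected)


class TestRepairMaskDefects:
    def test_interior_cavity_filled(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[2:7, 2:7, 2:7] = True
        mask[4, 4, 4] = False
        fixed = repair_mask_defects(ROIMask(mask))
        assert fixed.mask[4, 4, 4]

    def test_never_removes_true_voxels(self):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(12, 12, 12)) < 0.2
        fixed = repair_mask_defects(ROIMask(mask))
        assert np.all(fixed.mask[mask])
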