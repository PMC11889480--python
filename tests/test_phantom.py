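"""Phantom generator: parametric trees, stage presets, rasterization."""

import math

import numpy as np
import pytest

from vascmorph.phantom import (GeometryError, IntensityModel, ParameterError,
                               PresetInfeasibleError, StagePreset, TreeSpec,
                               available_presets, fit_tree_to_grid,
                               generate_preset_tree, generate_tree,
                               load_branching_table, min_self_clearance,
                               rasterize, rasterize_mask, stage_preset)
from vascmorph.treestats import summarize


class TestGenerateTree:
    def test_degenerate_single_segment(self):
        tree = generate_tree(TreeSpec(max_generation=0))
        assert len(tree) == 1
        assert [s.generation for s in tree] == [0]

    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_perfect_binary_counts(self, depth):
        # oracle: 2^(G+1)-1 segments, 2^G terminals all at generation G
        tree = generate_tree(TreeSpec(max_generation=depth,
                                      prune_probability=0.0))
        assert len(tree) == 2 ** (depth + 1) - 1
        tips = tree.terminals()
        assert len(tips) == 2 ** depth
        assert {t.generation for t in tips} == {depth}

    def test_determinism_same_seed(self):
        spec = TreeSpec(max_generation=3, branching_mode="mixed",
                        prune_probability=0.2, seed=5)
        a = generate_tree(spec)
        b = generate_tree(spec)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.start, sb.start)
            assert np.array_equal(sa.end, sb.end)
            assert sa.radius == sb.radius

    def test_different_seed_differs(self):
        a = generate_tree(TreeSpec(max_generation=3, seed=1, angle_jitter=10))
        b = generate_tree(TreeSpec(max_generation=3, seed=2, angle_jitter=10))
        assert any(not np.array_equal(sa.end, sb.end)
                   for sa, sb in zip(a, b))

    @pytest.mark.parametrize("bad", [
        {"max_generation": -1},
        {"length_ratio": 0.0},
        {"length_ratio": 1.5},
        {"radius_exponent": 0.0},
        {"prune_probability": 1.0},
        {"branching_mode": "ternary"},
        {"root_radius": -0.1},
        {"branch_angle": 120.0},
    ])
    def test_parameter_errors(self, bad):
        with pytest.raises(ParameterError):
            generate_tree(TreeSpec(**bad))

    @pytest.mark.parametrize("seed", range(6))
    def test_generation_increments_by_one(self, seed):
        spec = TreeSpec(max_generation=4, branching_mode="mixed",
                        prune_probability=0.25, seed=seed)
        tree = generate_tree(spec)
        for seg in tree:
            if seg.parent is not None:
                assert seg.generation == \
                    tree.segments[seg.parent].generation + 1
            else:
                assert seg.generation == 0
        assert max(s.generation for s in tree) <= spec.max_generation


class TestPresets:
    def test_all_table_rows_reproduced_exactly(self):
        df = load_branching_table()
        total = df[df["scope"] == "total"]
        for row in total.itertuples():
            preset = stage_preset(row.stage, row.vessel)
            tree = generate_preset_tree(preset, seed=0)
            st = summarize(tree, "total")
            assert st.as_tuple() == (
                float(row.median_generation), int(row.maximum_generation),
                int(row.vessel_count),
            ), f"{row.stage} {row.vessel}"

    def test_presets_deterministic_and_seed_varied(self):
        p = stage_preset("57dpn", "PA")
        a = generate_preset_tree(p, seed=1)
        b = generate_preset_tree(p, seed=1)
        c = generate_preset_tree(p, seed=2)
        assert [tuple(s.end) for s in a] == [tuple(s.end) for s in b]
        assert summarize(c, "total").as_tuple() == \
            summarize(a, "total").as_tuple()

    def test_trivial_single_segment_preset(self):
        p = StagePreset("neonate", "PA", 0, 0, 1)
        tree = generate_preset_tree(p)
        assert len(tree) == 1
        assert summarize(tree, "total").as_tuple() == (0.0, 0, 1)

    @pytest.mark.parametrize("median,maximum,count", [
        (0, 0, 2),   # an extra segment forces a terminal at generation >= 1
        (3, 10, 5),  # count smaller than the spine that carries maximum 10
    ])
    def test_infeasible_triples_raise(self, median, maximum, count):
        p = StagePreset("neonate", "PA", median, maximum, count)
        with pytest.raises(PresetInfeasibleError):
            generate_preset_tree(p)

    def test_median_equal_maximum_with_extras_feasible(self):
        # side terminals can sit at the maximum generation itself
        tree = generate_preset_tree(StagePreset("neonate", "PA", 10, 10, 12))
        assert summarize(tree, "total").as_tuple() == (10.0, 10, 12)

    def test_half_integer_median_even_terminals(self):
        p = StagePreset("neonate", "PV", 4.5, 8, 14)  # spine 9 + 5 leaves
        tree = generate_preset_tree(p, seed=0)
        assert summarize(tree, "total").as_tuple() == (4.5, 8, 14)

    def test_half_integer_median_odd_terminals_infeasible(self):
        p = StagePreset("neonate", "PV", 4.5, 8, 13)  # 4 leaves -> 5 tips
        with pytest.raises(PresetInfeasibleError):
            generate_preset_tree(p, seed=0)

    def test_available_presets_cover_all_stages(self):
        names = available_presets()
        assert len(names) == 8
        assert ("neonate", "PA") in names and ("57dpn", "PV") in names


class TestRasterize:
    def test_noiseless_cylinder_matches_discretized_predicate(self):
        # single axis-aligned segment centred on a voxel column
        from vascmorph.trees import Segment, VesselTree

        vox = 10.0
        tree = VesselTree([Segment(0, None, [0.105, 0.205, 0.205],
                                   [0.405, 0.205, 0.205], 0.0205)])
        model = IntensityModel(noise_sd=0.0)
        vol = rasterize(tree, (52, 41, 41), vox, model, seed=0)
        mask = rasterize_mask(tree, (52, 41, 41), vox)
        # independent predicate: distance of voxel centre to the capsule
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in (52, 41, 41)),
                                 indexing="ij")
        pz, py, px = (zz + 0.5) * 0.01, (yy + 0.5) * 0.01, (xx + 0.5) * 0.01
        t = np.clip((pz - 0.105) / 0.3, 0, 1)
        d2 = (pz - (0.105 + 0.3 * t)) ** 2 + (py - 0.205) ** 2 + \
            (px - 0.205) ** 2
        expected = d2 <= 0.0205 ** 2
        assert np.array_equal(mask, expected)
        assert np.all(vol.data[mask] == model.vessel_gray)
        assert np.all(vol.data[~mask] == model.background_gray)

    @pytest.mark.parametrize("radius_vox", [5, 6, 8])
    def test_cylinder_volume_within_5pct_of_analytic(self, radius_vox):
        from vascmorph.trees import Segment, VesselTree

        vox = 10.0
        r = radius_vox * vox / 1000.0
        L = 60 * vox / 1000.0
        tree = VesselTree([Segment(0, None, [0.15, 0.3, 0.3],
                                   [0.15 + L, 0.3, 0.3], r)])
        mask = rasterize_mask(tree, (95, 60, 60), vox)
        voxvol = (vox / 1000.0) ** 3
        measured = mask.sum() * voxvol
        # capsule = cylinder + two hemispherical caps
        analytic = math.pi * r * r * L + 4.0 / 3.0 * math.pi * r ** 3
        assert abs(measured - analytic) / analytic < 0.05

    def test_noise_tail_fraction(self):
        # Gaussian tail: P(|N(0,300)| <= 1200) = erf(4/sqrt2) > 0.9999
        from vascmorph.trees import Segment, VesselTree

        model = IntensityModel(background_gray=12000, vessel_gray=32000,
                               noise_sd=300.0)
        tree = VesselTree([Segment(0, None, [0.1, 0.3, 0.3],
                                   [0.5, 0.3, 0.3], 0.06)])
        vol = rasterize(tree, (70, 60, 60), 10.0, model, seed=3)
        mask = rasterize_mask(tree, (70, 60, 60), 10.0)
        lumen = vol.data[mask].astype(float)
        frac = np.mean(np.abs(lumen - model.vessel_gray) <= 1200)
        assert frac > 0.99

    def test_rasterize_deterministic(self):
        tree = generate_tree(TreeSpec(max_generation=2))
        tree, shape = fit_tree_to_grid(tree, 20.0)
        a = rasterize(tree, shape, 20.0, seed=9)
        b = rasterize(tree, shape, 20.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_tree_outside_grid_raises_with_ids(self):
        tree = generate_tree(TreeSpec(max_generation=1))
        with pytest.raises(GeometryError) as err:
            rasterize_mask(tree, (5, 5, 5), 10.0)
        assert err.value.segment_ids  # offending segments listed

    def test_intensity_model_validation(self):
        with pytest.raises(ParameterError):
            IntensityModel(vessel_gray=70000).validate()
        with pytest.raises(ParameterError):
            IntensityModel(background_gray=39000, vessel_gray=39500,
                           noise_sd=300).validate()


class TestClearance:
    def test_separated_y_positive(self, y_tree):
        assert min_self_clearance(y_tree) > 0

    def test_colliding_branches_negative(self):
        from vascmorph.trees import Segment, VesselTree

        # two cousins crossing in space
        segs = [
            Segment(0, None, [0.0, 0, 0], [1.0, 0, 0], 0.05),
            Segment(1, 0, [1.0, 0, 0], [2.0, 1.0, 0], 0.05),
            Segment(2, 0, [1.0, 0, 0], [2.0, -1.0, 0], 0.05),
            Segment(3, 1, [2.0, 1.0, 0], [3.0, -1.0, 0], 0.05),
            Segment(4, 2, [2.0, -1.0, 0], [3.0, 1.0, 0], 0.05),
        ]
        assert min_self_clearance(VesselTree(segs)) < 0
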