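"""Lesion-interaction measures: voxelization, loads, Tractometry, lesionometry."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lesionometry.core import Bundle, VoxelGrid
from lesionometry.measures import (
    average_hemispheres,
    bundle_load,
    bundle_volume,
    lesion_load,
    lesionometry,
    split_by_lesion,
    tractogram_load,
    tractometry,
    voxelize,
)
from lesionometry.phantom import make_bundle, make_lesion_mask

from conftest import brute_force_voxels, straight_bundle


def helix_bundle(grid):
    t = np.linspace(0, 4 * np.pi, 400)
    sl = np.column_stack([9 + 5 * np.cos(t), 9 + 5 * np.sin(t), 2 + 3.5 * t / np.pi])
    return Bundle(name="helix", streamlines=[sl])


class TestVoxelize:
    def test_axis_aligned_line_hits_exact_voxels(self, unit_grid):
        bundle = straight_bundle(x0=0.0, x1=9.0)
        assert voxelize(bundle, unit_grid) == {(i, 10, 10) for i in range(10)}

    def test_helix_matches_brute_force_oracle(self, unit_grid):
        bundle = helix_bundle(unit_grid)
        step = unit_grid.voxel_size.min() / 2
        assert voxelize(bundle, unit_grid) == brute_force_voxels(
            bundle.streamlines, unit_grid, step
        )

    def test_empty_bundle_empty_set(self, unit_grid):
        assert voxelize(Bundle(name="none", streamlines=[]), unit_grid) == set()

    def test_out_of_grid_points_dropped_with_warning(self, unit_grid):
        bundle = straight_bundle(x0=-8.0, x1=5.0)
        with pytest.warns(UserWarning, match="outside"):
            voxels = voxelize(bundle, unit_grid)
        assert all(unit_grid.in_bounds(np.array(v)) for v in voxels)

    def test_finer_resampling_only_adds_grazing_voxels(self, unit_grid):
        bundle = helix_bundle(unit_grid)
        half = voxelize(bundle, unit_grid, step=0.5)
        quarter = voxelize(bundle, unit_grid, step=0.25)
        eighth = voxelize(bundle, unit_grid, step=0.125)
        # from half-voxel steps on, refinement is pure set growth ...
        assert half <= quarter <= eighth
        # ... and the additions are a few grazing voxels, not systematic misses
        assert len(eighth - half) <= 0.15 * len(half)


class TestLesionLoad:
    def test_empty_lesion_is_zero(self, unit_grid):
        brain = np.ones(unit_grid.shape, bool)
        assert lesion_load(np.zeros(unit_grid.shape, bool), brain) == 0.0

    def test_full_lesion_is_one(self, unit_grid):
        brain = np.ones(unit_grid.shape, bool)
        assert lesion_load(brain, brain) == 1.0

    def test_fraction_matches_counts(self):
        brain = np.ones((50, 50, 40), bool)  # 100000 voxels
        lesion = np.zeros((50, 50, 40), bool)
        lesion.flat[:550] = True
        assert lesion_load(lesion, brain) == pytest.approx(0.0055)

    def test_lesion_outside_brain_excluded_with_warning(self, unit_grid):
        brain = np.zeros(unit_grid.shape, bool)
        brain[:10] = True
        lesion = np.zeros(unit_grid.shape, bool)
        lesion[8:12] = True
        with pytest.warns(UserWarning, match="outside the brain"):
            load = lesion_load(lesion, brain)
        assert load == lesion[:10].sum() / brain.sum()

    def test_empty_brain_raises(self, unit_grid):
        with pytest.raises(ValueError, match="empty"):
            lesion_load(np.zeros(unit_grid.shape, bool), np.zeros(unit_grid.shape, bool))


class TestTractogramLoad:
    def test_no_lesions_zero(self, unit_grid):
        b = straight_bundle()
        assert tractogram_load([b], np.zeros(unit_grid.shape, bool), unit_grid) == 0.0

    def test_lesions_cover_tractogram_one(self, unit_grid):
        b = straight_bundle()
        assert tractogram_load([b], np.ones(unit_grid.shape, bool), unit_grid) == 1.0

    def test_two_disjoint_bundles_one_lesioned_matches_oracle(self, unit_grid):
        b1 = straight_bundle("b1", y=5.0, z=5.0)
        b2 = straight_bundle("b2", y=14.0, z=14.0)
        lesion = np.zeros(unit_grid.shape, bool)
        lesion[:, 4:7, 4:7] = True  # overlaps b1 only
        load = tractogram_load([b1, b2], lesion, unit_grid)
        step = unit_grid.voxel_size.min() / 2
        vox = brute_force_voxels(b1.streamlines + b2.streamlines, unit_grid, step)
        expected = sum(lesion[v] for v in vox) / len(vox)
        assert load == expected

    def test_empty_tractogram_raises(self, unit_grid):
        with pytest.raises(ValueError, match="empty"):
            tractogram_load([], np.zeros(unit_grid.shape, bool), unit_grid)


class TestBundleVolumeAndLoad:
    def test_volume_arithmetic(self):
        grid = VoxelGrid.isotropic((20, 20, 20), 2.0)
        sl = np.column_stack([np.linspace(0, 19 * 2, 40), np.full(40, 20.0), np.full(40, 20.0)])
        bundle = Bundle(name="line", streamlines=[sl])
        assert bundle_volume(bundle, grid) == pytest.approx(20 * 8.0)

    def test_duplicate_streamlines_leave_volume_unchanged(self, unit_grid):
        b1 = straight_bundle(n=1)
        b5 = straight_bundle(n=5)
        assert bundle_volume(b1, unit_grid) == bundle_volume(b5, unit_grid)

    def test_tube_phantom_matches_oracle(self, small_spec):
        grid = small_spec.grid()
        bundle = make_bundle(small_spec, "tube")
        step = grid.voxel_size.min() / 2
        oracle = brute_force_voxels(bundle.streamlines, grid, step)
        assert bundle_volume(bundle, grid) == len(oracle) * grid.voxel_volume

    def test_load_bounds(self, unit_grid):
        b = straight_bundle()
        assert bundle_load(b, np.zeros(unit_grid.shape, bool), unit_grid) == 0.0
        assert bundle_load(b, np.ones(unit_grid.shape, bool), unit_grid) == 1.0

    def test_sphere_on_tube_matches_enumeration_oracle(self, small_spec):
        grid = small_spec.grid()
        bundle = make_bundle(small_spec, "tube")
        lesion = make_lesion_mask(small_spec, grid)
        step = grid.voxel_size.min() / 2
        vox = brute_force_voxels(bundle.streamlines, grid, step)
        expected = sum(lesion[v] for v in vox) / len(vox)
        assert bundle_load(bundle, lesion, grid) == expected
        assert 0.0 < bundle_load(bundle, lesion, grid) < 1.0

    def test_lesion_growth_is_monotone(self, small_spec, rng):
        grid = small_spec.grid()
        bundle = make_bundle(small_spec, "tube")
        brain = np.ones(grid.shape, bool)
        lesion = make_lesion_mask(small_spec, grid)
        grown = lesion | (rng.random(grid.shape) < 0.2)
        assert bundle_load(bundle, grown, grid) >= bundle_load(bundle, lesion, grid)
        assert lesion_load(grown, brain) >= lesion_load(lesion, brain)
        assert tractogram_load([bundle], grown, grid) >= tractogram_load(
            [bundle], lesion, grid
        )


class TestSplitByLesion:
    def test_no_lesions_flags_none(self, unit_grid):
        inter = split_by_lesion(
            straight_bundle(n=4), np.zeros(unit_grid.shape, bool), unit_grid
        )
        assert inter.n_lesioned == 0

    def test_slab_flags_all(self, unit_grid):
        lesion = np.zeros(unit_grid.shape, bool)
        lesion[9:11] = True  # slab orthogonal to every streamline
        inter = split_by_lesion(straight_bundle(n=4), lesion, unit_grid)
        assert inter.n_lesioned == 4

    def test_partial_overlap_matches_per_point_oracle(self, small_spec):
        grid = small_spec.grid()
        bundle = make_bundle(small_spec, "tube")
        lesion = make_lesion_mask(small_spec, grid)
        inter = split_by_lesion(bundle, lesion, grid)
        from lesionometry.phantom import _resample_polyline

        expected = []
        inv = np.linalg.inv(grid.affine)
        for i, sl in enumerate(bundle.streamlines):
            hit = False
            for p in _resample_polyline(sl, grid.voxel_size.min() / 2):
                q = inv @ np.r_[p, 1.0]
                idx = tuple(int(round(v)) for v in q[:3])
                if all(0 <= idx[a] < grid.shape[a] for a in range(3)) and lesion[idx]:
                    hit = True
                    break
            if hit:
                expected.append(i)
        np.testing.assert_array_equal(inter.lesioned_indices, expected)
        assert 0 < inter.n_lesioned < len(bundle)
        assert inter.lesion_voxels <= inter.bundle_voxels


class TestTractometry:
    def test_constant_map(self, unit_grid):
        cmap = np.full(unit_grid.shape, 3.25)
        assert tractometry(straight_bundle(), cmap, unit_grid) == 3.25

    def test_two_valued_map_weighted_mean(self, unit_grid):
        vmap = np.zeros(unit_grid.shape)
        vmap[:10] = 1.0  # first half of the x-extent
        bundle = straight_bundle(x0=0.0, x1=19.0)
        # hand computation: resampled points at 0.5 mm spacing along x in [0, 19]
        xs = np.arange(0, 19.0 + 0.25, 0.5)
        expected = np.mean(np.round(xs) < 10)
        assert tractometry(bundle, vmap, unit_grid) == pytest.approx(expected)

    def test_nan_outside_bundle_ignored(self, unit_grid):
        vmap = np.full(unit_grid.shape, np.nan)
        vmap[:, 10, 10] = 2.0
        assert tractometry(straight_bundle(), vmap, unit_grid) == 2.0

    def test_all_nan_raises(self, unit_grid):
        vmap = np.full(unit_grid.shape, np.nan)
        with pytest.raises(ValueError, match="NaN"):
            tractometry(straight_bundle(), vmap, unit_grid)


class TestLesionometry:
    def test_constant_map_any_mode(self, unit_grid):
        lesion = np.zeros(unit_grid.shape, bool)
        lesion[:5] = True
        inter = split_by_lesion(straight_bundle(), lesion, unit_grid)
        cmap = np.full(unit_grid.shape, 1.5)
        assert lesionometry(inter, cmap, unit_grid, "portion") == 1.5
        assert lesionometry(inter, cmap, unit_grid, "full") == 1.5

    def test_half_in_lesion_portion_vs_full(self):
        grid = VoxelGrid.isotropic((20, 20, 20), 1.0)
        lesion = np.zeros(grid.shape, bool)
        lesion[:10] = True
        indicator = lesion.astype(float)
        # one streamline spanning exactly 10 lesion + 10 normal voxels
        sl = np.column_stack([np.arange(20.0), np.full(20, 10.0), np.full(20, 10.0)])
        bundle = Bundle(name="half", streamlines=[sl])
        inter = split_by_lesion(bundle, lesion, grid, step=1.0)
        assert lesionometry(inter, indicator, grid, "portion") == 1.0
        assert lesionometry(inter, indicator, grid, "full") == pytest.approx(0.5)

    def test_full_mode_equals_tractometry_when_all_lesioned(self, small_spec, rng):
        grid = small_spec.grid()
        bundle = make_bundle(small_spec, "tube")
        lesion = np.ones(grid.shape, bool)
        inter = split_by_lesion(bundle, lesion, grid)
        vmap = rng.random(grid.shape)
        assert lesionometry(inter, vmap, grid, "full") == tractometry(bundle, vmap, grid)

    def test_no_lesioned_streamlines_is_missing(self, unit_grid):
        inter = split_by_lesion(
            straight_bundle(), np.zeros(unit_grid.shape, bool), unit_grid
        )
        assert np.isnan(lesionometry(inter, np.ones(unit_grid.shape), unit_grid))

    def test_modes_match_brute_force_on_lesioned_phantom(self, small_spec):
        grid = small_spec.grid()
        bundle = make_bundle(small_spec, "tube")
        lesion = make_lesion_mask(small_spec, grid)
        maps = {"fa": np.where(lesion, 0.3, 0.8)}
        inter = split_by_lesion(bundle, lesion, grid)
        # brute-force: enumerate sampled values per mode
        vals = {"portion": [], "full": []}
        for i in inter.lesioned_indices:
            pts = inter.streamlines[i]
            idx = grid.nearest_voxel(pts)
            ok = grid.in_bounds(idx)
            v = maps["fa"][idx[ok, 0], idx[ok, 1], idx[ok, 2]]
            vals["full"].extend(v)
            vals["portion"].extend(v[lesion[idx[ok, 0], idx[ok, 1], idx[ok, 2]]])
        for mode in ("portion", "full"):
            assert lesionometry(inter, maps["fa"], grid, mode) == pytest.approx(
                np.mean(vals[mode])
            )
        whole = tractometry(bundle, maps["fa"], grid)
        assert abs(lesionometry(inter, maps["fa"], grid, "portion") - whole) >= abs(
            lesionometry(inter, maps["fa"], grid, "full") - whole
        )

    def test_unknown_mode_rejected(self, unit_grid):
        inter = split_by_lesion(
            straight_bundle(), np.ones(unit_grid.shape, bool), unit_grid
        )
        with pytest.raises(ValueError, match="mode"):
            lesionometry(inter, np.ones(unit_grid.shape), unit_grid, "middle")


class TestAverageHemispheres:
    def test_equal_sides_pass_value_through(self):
        df = pd.DataFrame({"slf_left|volume": [2.0], "slf_right|volume": [2.0]})
        assert average_hemispheres(df)["slf|volume"].iloc[0] == 2.0

    def test_simple_average(self):
        df = pd.DataFrame({"slf_left|load": [0.2], "slf_right|load": [0.4]})
        assert average_hemispheres(df)["slf|load"].iloc[0] == pytest.approx(0.3)

    def test_random_table_matches_columnwise_oracle(self, rng):
        df = pd.DataFrame(
            rng.random((6, 5)),
            columns=[
                "genu|volume",
                "slf_left|volume",
                "slf_right|volume",
                "slf_left|load",
                "slf_right|load",
            ],
        )
        out = average_hemispheres(df)
        np.testing.assert_allclose(
            out["slf|volume"], (df["slf_left|volume"] + df["slf_right|volume"]) / 2
        )
        np.testing.assert_allclose(out["genu|volume"], df["genu|volume"])
        assert set(out.columns) == {"genu|volume", "slf|volume", "slf|load"}

    def test_unpaired_side_raises(self):
        df = pd.DataFrame({"slf_left|volume": [1.0]})
        with pytest.raises(ValueError, match="unpaired"):
            average_hemispheres(df)

    def test_missing_side_propagates_missing(self):
        df = pd.DataFrame(
            {"slf_left|load": [0.2, np.nan], "slf_right|load": [0.4, 0.6]}
        )
        out = average_hemispheres(df)
        assert np.isnan(out["slf|load"].iloc[1])
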