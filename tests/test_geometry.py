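"""Rasterisation and the four comparison metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import cube_mask, make_pair, random_mask_pair
from contourqa.geometry import (
    GridError,
    GridSpec,
    VoxelMask,
    apl,
    build_grid,
    evaluate_pair,
    extract_surface,
    hd95,
    rasterize,
    sdsc,
    summarize_roi,
    vdsc,
)
from contourqa.rtstruct_io import ContourSet
from contourqa.synth import PerturbationSpec, ShapeSpec, make_contours, perturb


def square_set(side=20.0, z_planes=(0.0,), name="Sq", inner=None):
    planes = []
    h = side / 2
    for z in z_planes:
        polys = [np.array([[-h, -h, z], [h, -h, z], [h, h, z], [-h, h, z]])]
        if inner:
            hi = inner / 2
            polys.append(np.array([[-hi, -hi, z], [hi, -hi, z], [hi, hi, z], [-hi, hi, z]]))
        planes.append((z, polys))
    return ContourSet(roi_name=name, planes=planes)


class TestRasterize:
    def test_square_matches_point_in_polygon_oracle(self):
        cset = square_set(side=20.0)
        grid = build_grid(cset, cset, in_plane_spacing_mm=1.0)
        mask = rasterize(cset, grid)
        assert np.array_equal(mask.occupancy, oracles.rasterize_oracle(cset, grid))
        # half-voxel-offset centres put exactly side^2 centres inside
        assert mask.n_voxels == 400

    def test_nested_contour_is_hole(self):
        cset = square_set(side=20.0, inner=10.0)
        grid = build_grid(cset, cset, in_plane_spacing_mm=1.0)
        mask = rasterize(cset, grid)
        assert np.array_equal(mask.occupancy, oracles.rasterize_oracle(cset, grid))
        assert mask.n_voxels == 400 - 100

    def test_empty_contour_set_fails_at_grid_construction(self):
        empty = ContourSet(roi_name="E", planes=[])
        with pytest.raises(GridError):
            build_grid(empty, empty)

    def test_plane_outside_grid_is_fatal(self):
        cset = square_set(z_planes=(0.0,))
        far = square_set(z_planes=(500.0,))
        grid = build_grid(cset, cset)
        with pytest.raises(GridError):
            rasterize(far, grid)

    def test_grid_margin_covers_sdsc_tolerance(self):
        cset = square_set()
        grid = build_grid(cset, cset, sdsc_tol_mm=3.0)
        pts = cset.all_points()
        assert pts[:, 0].min() - grid.origin[0] >= 3.0
        edge = grid.origin[0] + grid.spacing[0] * (grid.shape[0] - 1)
        assert edge - pts[:, 0].max() >= 3.0


def small_grid(shape=(30, 30, 30)):
    return GridSpec(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), shape=shape)


class TestVdsc:
    def test_identity_and_disjoint(self):
        g = small_grid()
        a = cube_mask(g, (0, 0, 0), (20, 20, 20))
        b = cube_mask(g, (21, 21, 21), (25, 25, 25))
        assert vdsc(a, a) == 1.0
        assert vdsc(a, b) == 0.0

    def test_half_overlapping_cubes(self):
        g = small_grid()
        a = cube_mask(g, (0, 0, 0), (20, 20, 20))
        b = cube_mask(g, (10, 0, 0), (30, 20, 20))
        assert vdsc(a, b) == pytest.approx(2 * (10 * 20 * 20) / (8000 + 8000))

    def test_mismatched_grids_fatal(self):
        a = cube_mask(small_grid(), (0, 0, 0), (5, 5, 5))
        b = cube_mask(small_grid((10, 10, 10)), (0, 0, 0), (5, 5, 5))
        with pytest.raises(GridError):
            vdsc(a, b)


class TestSurface:
    def test_3x3x3_cube_has_26_surface_voxels(self):
        m = cube_mask(small_grid((7, 7, 7)), (2, 2, 2), (5, 5, 5))
        assert len(extract_surface(m)) == 26

    def test_single_voxel_is_its_own_surface(self):
        m = cube_mask(small_grid((5, 5, 5)), (2, 2, 2), (3, 3, 3))
        s = extract_surface(m)
        assert len(s) == 1
        assert np.allclose(s.coords_mm, [[2.0, 2.0, 2.0]])

    def test_thin_slab_is_all_surface(self):
        m = cube_mask(small_grid((8, 8, 8)), (1, 1, 4), (7, 7, 5))
        assert len(extract_surface(m)) == m.n_voxels


class TestSdscHd95:
    def test_identical_masks(self):
        m = cube_mask(small_grid(), (5, 5, 5), (15, 15, 15))
        assert sdsc(m, m) == 1.0
        assert hd95(m, m) == 0.0

    def test_concentric_spheres_within_tolerance(self):
        # radii 10 and 12 mm: max surface separation 2 mm < 3 mm tolerance
        g = small_grid((31, 31, 31))
        idx = np.indices(g.shape)
        d2 = (idx[0] - 15.0) ** 2 + (idx[1] - 15.0) ** 2 + (idx[2] - 15.0) ** 2
        a = VoxelMask(g, d2 <= 10.0**2)
        b = VoxelMask(g, d2 <= 12.0**2)
        assert sdsc(a, b, tol_mm=3.0) == 1.0

    def test_far_apart_masks_score_zero(self):
        g = GridSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (120, 5, 5))
        a = cube_mask(g, (0, 0, 0), (1, 1, 1))
        b = cube_mask(g, (100, 0, 0), (101, 1, 1))
        assert sdsc(a, b, tol_mm=3.0) == 0.0

    def test_negative_tolerance_fatal(self):
        m = cube_mask(small_grid(), (5, 5, 5), (15, 15, 15))
        with pytest.raises(ValueError):
            sdsc(m, m, tol_mm=-1.0)

    def test_shifted_cube_matches_bruteforce(self):
        g = small_grid()
        a = cube_mask(g, (5, 5, 5), (15, 15, 15))
        b = cube_mask(g, (7, 5, 5), (17, 15, 15))
        assert hd95(a, b) == pytest.approx(
            oracles.hd95_oracle(a.occupancy, b.occupancy, g), abs=1e-9
        )

    def test_hd95_below_exact_hausdorff(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = random_mask_pair(rng, max_extent=12)
            assert hd95(a, b, percentile=95) <= hd95(a, b, percentile=100) + 1e-12


class TestApl:
    def test_identical_masks_zero(self):
        m = cube_mask(small_grid(), (5, 5, 5), (15, 15, 15))
        assert apl(m, m) == 0

    def test_single_edited_slice(self):
        g = small_grid((20, 20, 10))
        dls = cube_mask(g, (5, 5, 2), (15, 15, 8))
        occ = dls.occupancy.copy()
        occ[5:17, 5:15, 4] = True  # widen one slice by 2 voxels in x
        cs = VoxelMask(g, occ)
        assert apl(dls, cs) == oracles.apl_oracle(dls.occupancy, cs.occupancy)
        # untouched slices contribute nothing
        assert apl(dls, cs) == int(
            np.count_nonzero(
                oracles.boundary_2d_oracle(cs.occupancy[:, :, 4])
                & ~oracles.boundary_2d_oracle(dls.occupancy[:, :, 4])
            )
        )

    def test_square_against_empty_dls_slice(self):
        g = small_grid((10, 10, 3))
        dls = cube_mask(g, (3, 3, 0), (7, 7, 1))  # only slice 0
        occ = dls.occupancy.copy()
        occ[3:7, 3:7, 1] = True  # CS adds a 4x4 square on empty slice 1
        cs = VoxelMask(g, occ)
        # a 4x4 square has 12 boundary voxels
        assert apl(dls, cs) == 12

    def test_apl_is_directional(self):
        g = small_grid((20, 20, 5))
        a = cube_mask(g, (5, 5, 1), (15, 15, 4))
        b = cube_mask(g, (5, 5, 1), (16, 15, 4))
        assert apl(a, b) != apl(b, a) or (apl(a, b) == 0 and apl(b, a) == 0)
        assert apl(a, b) == oracles.apl_oracle(a.occupancy, b.occupancy)
        assert apl(b, a) == oracles.apl_oracle(b.occupancy, a.occupancy)


class TestOracleEquivalence:
    def test_random_masks_match_bruteforce(self):
        """sdsc/hd95 vs all-pairs distances; vdsc/apl vs set counts."""
        rng = np.random.default_rng(12345)
        for _ in range(25):
            a, b = random_mask_pair(rng)
            g = a.grid
            assert sdsc(a, b, tol_mm=3.0) == pytest.approx(
                oracles.sdsc_oracle(a.occupancy, b.occupancy, g, 3.0), abs=1e-9
            )
            assert hd95(a, b) == pytest.approx(
                oracles.hd95_oracle(a.occupancy, b.occupancy, g), abs=1e-9
            )
            assert vdsc(a, b) == oracles.vdsc_oracle(a.occupancy, b.occupancy)
            assert apl(a, b) == oracles.apl_oracle(a.occupancy, b.occupancy)


class TestMetricProperties:
    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_ranges(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask_pair(rng, max_extent=12)
        assert vdsc(a, b) == vdsc(b, a)
        assert sdsc(a, b) == sdsc(b, a)
        assert hd95(a, b) == hd95(b, a)
        assert 0.0 <= vdsc(a, b) <= 1.0
        assert 0.0 <= sdsc(a, b) <= 1.0
        assert hd95(a, b) >= 0.0
        assert isinstance(apl(a, b), int) and apl(a, b) >= 0

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 3))
    def test_translation_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        a, b = random_mask_pair(rng, max_extent=12)
        pad = [(shift, 0)] * 3
        ga = a.grid
        grid2 = GridSpec(
            origin=ga.origin,
            spacing=ga.spacing,
            shape=tuple(s + shift for s in ga.shape),
        )
        a2 = VoxelMask(grid2, np.pad(a.occupancy, pad))
        b2 = VoxelMask(grid2, np.pad(b.occupancy, pad))
        assert vdsc(a2, b2) == vdsc(a, b)
        assert sdsc(a2, b2) == pytest.approx(sdsc(a, b), abs=1e-12)
        assert hd95(a2, b2) == pytest.approx(hd95(a, b), abs=1e-12)
        assert apl(a2, b2) == apl(a, b)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sdsc_monotone_in_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask_pair(rng, max_extent=12)
        scores = [sdsc(a, b, tol_mm=t) for t in (0.0, 1.0, 2.0, 3.0, 5.0)]
        assert all(s0 <= s1 for s0, s1 in zip(scores, scores[1:]))


class TestEvaluatePair:
    def test_identity_pair_gives_identity_metrics(self, identity_pair):
        rec = evaluate_pair(identity_pair)
        assert (rec.vdsc, rec.sdsc3, rec.hd95, rec.apl, rec.awc) == (1.0, 1.0, 0.0, 0, True)

    def test_translated_sphere_matches_direct_metric_calls(self, sphere_contours):
        moved = perturb(sphere_contours, PerturbationSpec(kind="translate", magnitude=3.0))
        pair = make_pair(sphere_contours, moved)
        rec = evaluate_pair(pair)
        grid = build_grid(sphere_contours, moved)
        a = rasterize(sphere_contours, grid)
        b = rasterize(moved, grid)
        assert rec.vdsc == pytest.approx(vdsc(a, b))
        assert rec.sdsc3 == pytest.approx(sdsc(a, b, tol_mm=3.0))
        assert rec.hd95 == pytest.approx(hd95(a, b))
        assert rec.apl == apl(a, b)
        assert rec.awc is False

    def test_single_edited_slice_breaks_awc(self, sphere_contours):
        edited = perturb(
            sphere_contours,
            PerturbationSpec(kind="edit_slices", magnitude=3.0, fraction=0.15, seed=3),
        )
        rec = evaluate_pair(make_pair(sphere_contours, edited))
        assert rec.awc is False and rec.apl > 0 and rec.vdsc < 1.0


class TestSummarizeRoi:
    def test_all_awc(self, identity_pair):
        rec = evaluate_pair(identity_pair)
        row = summarize_roi([rec] * 4)
        assert row["pct_awc"] == 100.0
        assert (row["vdsc_median"], row["sdsc3_median"]) == (1.0, 1.0)
        assert (row["hd95_median"], row["apl_median"]) == (0.0, 0.0)

    def test_awc_percentage(self, identity_pair):
        awc_rec = evaluate_pair(identity_pair)
        import dataclasses

        non = dataclasses.replace(awc_rec, vdsc=0.9, sdsc3=0.9, hd95=1.0, apl=10, awc=False)
        row = summarize_roi([awc_rec, awc_rec] + [non] * 8)
        assert row["pct_awc"] == pytest.approx(20.0)

    def test_hd95_summary_quantiles(self, identity_pair):
        import dataclasses

        base = evaluate_pair(identity_pair)
        recs = [
            dataclasses.replace(base, hd95=h, awc=False, vdsc=0.9) for h in (0, 0, 0, 1, 2)
        ]
        row = summarize_roi(recs)
        assert row["hd95_median"] == 0.0
        assert row["hd95_min"] == 0.0 and row["hd95_max"] == 2.0
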