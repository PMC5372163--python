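"""ROI geometry, watershed partitioning, Helmert transfer and pooling."""

import numpy as np
import pytest

from ftirlcm import roi_transfer as rt
from ftirlcm import synthetic as syn
from ftirlcm.errors import ConditioningError, InfeasibleError, ValidationError
from ftirlcm.hyperspec_io import LabelMap, ReferencePointSet


def make_map(mask, name="tumour"):
    return LabelMap(mask.astype(np.int32), {1: (name, "#ff0000")})


class TestExtractRois:
    def test_three_by_three_block_polygon(self):
        """A 3x3 block has 8 marginal pixels; the polygon walks their centers."""
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:4, 1:4] = True
        rois = rt.extract_rois(make_map(mask), "tumour", pixel_size=(1.0, 1.0))
        assert len(rois) == 1
        roi = rois[0]
        assert roi.pixels.shape[0] == 9
        assert roi.boundary_rc.shape == (8, 2)
        # starts at the top-most then left-most marginal pixel
        assert tuple(roi.boundary_rc[0]) == (1, 1)
        expected = {(r, c) for r in (1, 2, 3) for c in (1, 2, 3)} - {(2, 2)}
        assert {tuple(p) for p in roi.boundary_rc} == expected
        # pixel-center convention: (row, col) -> (col + 0.5, row + 0.5) um
        np.testing.assert_allclose(
            roi.boundary_polygon_um[0], [1.5, 1.5]
        )

    def test_diagonal_blocks_are_one_roi_under_8_connectivity(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:3, 1:3] = True
        mask[3:5, 3:5] = True
        rois = rt.extract_rois(make_map(mask), "tumour")
        assert len(rois) == 1

    def test_min_pixels_filters_isolated_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert rt.extract_rois(make_map(mask), "tumour", min_pixels=4) == []

    def test_absent_class_yields_empty_list(self):
        mask = np.zeros((4, 4), dtype=bool)
        lm = LabelMap(mask.astype(np.int32), {1: ("tumour", "#ff0000")})
        assert rt.extract_rois(lm, "tumour") == []
        with pytest.raises(ValidationError):
            rt.extract_rois(lm, "unknown-class")

    def test_boundary_vertices_are_exactly_marginal_pixels(self):
        """Polygon vertex set == 4-neighbor marginal set (re-rasterization
        fixed point) for solid shapes."""
        rng = np.random.default_rng(3)
        mask = np.zeros((30, 30), dtype=bool)
        rr, cc = np.ogrid[:30, :30]
        for _ in range(3):
            cy, cx, rad = rng.uniform(8, 22, 3)
            mask |= (rr - cy) ** 2 + (cc - cx) ** 2 <= (rad / 2 + 3) ** 2
        rois = rt.extract_rois(make_map(mask), "tumour")
        for roi in rois:
            region = np.zeros_like(mask)
            region[roi.pixels[:, 0], roi.pixels[:, 1]] = True
            marginal = rt.marginal_pixels(region)
            assert {tuple(p) for p in roi.boundary_rc} == set(
                map(tuple, np.argwhere(marginal))
            )


class TestWatershedSplit:
    def _roi(self, mask):
        return rt.extract_rois(make_map(mask), "tumour", pixel_size=(1.0, 1.0))[0]

    def test_small_roi_single_fragment(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:5, 2:5] = True
        roi = self._roi(mask)
        frags = rt.watershed_split(roi, np.ones(mask.shape), max_shape_area_um2=100.0)
        assert len(frags) == 1
        assert frags[0].pixels.shape[0] == 9

    def test_dumbbell_split_respects_limit_and_partitions(self):
        mask = np.zeros((12, 25), dtype=bool)
        mask[1:11, 1:11] = True
        mask[1:11, 14:24] = True
        mask[5, 11:14] = True
        roi = self._roi(mask)
        limit = 0.6 * roi.area_um2
        frags = rt.watershed_split(roi, np.ones(mask.shape), max_shape_area_um2=limit)
        assert len(frags) >= 2
        assert all(f.area_um2 <= limit for f in frags)
        assert sum(f.pixels.shape[0] for f in frags) == roi.pixels.shape[0]

    def test_integral_additivity(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:18, 2:18] = True
        amide = rng.uniform(10, 40, mask.shape)
        roi = self._roi(mask)
        frags = rt.watershed_split(roi, amide, max_shape_area_um2=60.0)
        total = sum(f.amide_integral_sum for f in frags)
        assert total == pytest.approx(amide[mask].sum(), rel=1e-12)
        assert all(f.pixels.shape[0] <= 60 for f in frags)

    def test_single_pixel_roi_returned_as_is(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        roi = self._roi(mask)
        frags = rt.watershed_split(roi, np.ones(mask.shape), max_shape_area_um2=1.0)
        assert len(frags) == 1 and frags[0].pixels.shape[0] == 1


class TestHelmert:
    def test_identity_from_identical_triangles(self):
        tri = [((0.0, 0.0), (0.0, 0.0)), ((10.0, 0.0), (10.0, 0.0)), ((0.0, 10.0), (0.0, 10.0))]
        est = rt.estimate_helmert(ReferencePointSet(tri))
        assert est.tx == pytest.approx(0.0, abs=1e-12)
        assert est.ty == pytest.approx(0.0, abs=1e-12)
        assert est.scale == pytest.approx(1.0)
        assert est.theta == pytest.approx(0.0, abs=1e-12)

    def test_constructed_90_degree_rotation(self):
        pairs = ReferencePointSet(
            [((0.0, 0.0), (10.0, 20.0)), ((1.0, 0.0), (10.0, 21.0)), ((0.0, 1.0), (9.0, 20.0))]
        )
        est = rt.estimate_helmert(pairs)
        assert est.scale == pytest.approx(1.0, abs=1e-12)
        assert np.rad2deg(est.theta) == pytest.approx(90.0, abs=1e-9)
        assert (est.tx, est.ty) == (pytest.approx(10.0), pytest.approx(20.0))
        assert est.rms_residual < 1e-12

    def test_random_transform_recovered_to_1e9(self):
        true = rt.HelmertTransform(
            tx=-250.0, ty=310.0, scale=1.37, theta=np.deg2rad(12.0)
        )
        points = syn.generate_reference_points(true, n=3, noise_sigma=0.0, seed=11)
        est = rt.estimate_helmert(points)
        assert abs(est.tx - true.tx) < 1e-9
        assert abs(est.ty - true.ty) < 1e-9
        assert abs(est.scale - true.scale) < 1e-9
        assert abs(est.theta - true.theta) < 1e-9
        # noiseless round trip through the estimate
        np.testing.assert_allclose(
            rt.apply_helmert(est, points.source), points.destination, atol=1e-9
        )

    def test_apply_translation_and_inverse_composition(self):
        shift = rt.HelmertTransform(tx=10.0, ty=-5.0, scale=1.0, theta=0.0)
        np.testing.assert_allclose(rt.apply_helmert(shift, np.array([0.0, 0.0])), [10.0, -5.0])
        t = rt.HelmertTransform(tx=3.0, ty=4.0, scale=2.5, theta=0.7)
        pts = np.random.default_rng(0).uniform(-100, 100, (20, 2))
        round_trip = rt.apply_helmert(t.inverse(), rt.apply_helmert(t, pts))
        np.testing.assert_allclose(round_trip, pts, atol=1e-9)

    def test_collinear_points_conditioning_error(self):
        pairs = ReferencePointSet(
            [((0.0, 0.0), (1.0, 1.0)), ((1.0, 1.0), (2.0, 2.0)), ((2.0, 2.0), (3.0, 3.0))]
        )
        with pytest.raises(ConditioningError):
            rt.estimate_helmert(pairs)

    def test_noisy_residual_matches_least_squares_law(self):
        """rms residual ~ sigma * sqrt(2(n-2)/n) within 20% over 200 seeds."""
        true = rt.HelmertTransform(tx=50.0, ty=-20.0, scale=1.05, theta=0.2)
        sigma, n = 1.0, 10
        rms = [
            rt.estimate_helmert(
                syn.generate_reference_points(true, n=n, noise_sigma=sigma, seed=s)
            ).rms_residual
            for s in range(200)
        ]
        expected = sigma * np.sqrt(2 * (n - 2) / n)
        assert np.mean(rms) == pytest.approx(expected, rel=0.2)


class TestAberrationCalibration:
    @staticmethod
    def _grid_pairs(sx, sy, phi_deg):
        grid = np.array([[i, j] for i in range(5) for j in range(5)], dtype=float)
        phi = np.deg2rad(phi_deg)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        dst = (grid @ rot.T) * np.array([sx, sy])
        return ReferencePointSet([(tuple(s), tuple(d)) for s, d in zip(grid, dst)])

    def test_recovers_fpa_pixel_size_and_rotation(self):
        """Planted 5.65 x 5.75 um pixel size and 0.06 deg rotation recovered."""
        cal = rt.calibrate_aberration(self._grid_pairs(5.65, 5.75, 0.06))
        assert cal.pixel_size_x_um == pytest.approx(5.65, abs=1e-6)
        assert cal.pixel_size_y_um == pytest.approx(5.75, abs=1e-6)
        assert cal.rotation_deg == pytest.approx(0.06, abs=1e-6)

    def test_undistorted_grid_identity(self):
        cal = rt.calibrate_aberration(self._grid_pairs(1.0, 1.0, 0.0))
        assert cal.pixel_size_x_um == pytest.approx(1.0)
        assert cal.pixel_size_y_um == pytest.approx(1.0)
        assert cal.rotation_deg == pytest.approx(0.0, abs=1e-12)

    def test_collinear_grid_rejected(self):
        pairs = ReferencePointSet(
            [((i, 0.0), (i * 2.0, 0.0)) for i in range(4)]
        )
        with pytest.raises(ConditioningError):
            rt.calibrate_aberration(pairs)


class TestEndToEndSpatialContract:
    def test_roi_polygon_survives_frame_round_trip(self):
        """Phantom ROI -> polygon -> LCM frame -> inverse, < 1e-6 um."""
        image, truth, *_ = syn.generate_phantom(syn.PhantomSpec(shape=(32, 32), seed=6))
        name = truth.legend[max(truth.legend)][0]
        rois = rt.extract_rois(
            truth, name, min_pixels=9,
            pixel_size=image.pixel_size, stage_origin=image.stage_origin,
        )
        assert rois, "phantom produced no usable ROI"
        transform = rt.HelmertTransform(tx=1500.0, ty=-900.0, scale=1.02, theta=0.05)
        for roi in rois:
            poly = roi.boundary_polygon_um
            back = rt.apply_helmert(transform.inverse(), rt.apply_helmert(transform, poly))
            np.testing.assert_allclose(back, poly, atol=1e-6)


class TestBalancedPooling:
    def test_greedy_matches_subset_sum_oracle(self):
        """{5, 3, 2}, target 5, tol 0: brute force admits {5} and {3,2};
        greedy returns the largest-first solution {5}."""
        values = [5.0, 3.0, 2.0]
        feasible = [
            frozenset(i for i in range(3) if (mask >> i) & 1)
            for mask in range(8)
            if abs(sum(values[i] for i in range(3) if (mask >> i) & 1) - 5.0) == 0.0
        ]
        assert frozenset([0]) in feasible and frozenset([1, 2]) in feasible
        result = rt.select_fragments_balanced({"s": values}, 5.0, 0.0)
        assert result["s"]["indices"] == [0]
        assert result["s"]["achieved_integral"] == 5.0

    def test_infeasible_target_names_sample(self):
        with pytest.raises(InfeasibleError, match="s2"):
            rt.select_fragments_balanced({"s1": [6.0, 5.0], "s2": [4.0, 6.0]}, 11.0, 0.5)

    def test_random_pools_within_tolerance(self):
        """4 samples x 20 U(1,10) fragments, target 40 +/- 1, 20 seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = {f"s{i}": rng.uniform(1, 10, 20).tolist() for i in range(4)}
            result = rt.select_fragments_balanced(samples, 40.0, 1.0)
            for info in result.values():
                assert abs(info["deviation"]) <= 1.0 + 1e-9
                assert info["cross_sample_spread"] <= 2.0 + 1e-9
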