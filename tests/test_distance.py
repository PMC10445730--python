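"""Distance readouts: geometry oracles, spline rasterization, the
normalized contour distance map, and probability histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perifish import (
    DistanceRecord,
    SplineROI,
    compare_conditions,
    max_project,
    max_project_composite,
    min_distance_3d,
    normalized_distance_map,
    normalized_position,
    pdf_histogram,
    rasterize_spline,
)
from perifish.stack import ImageStack


def circle_points(n, radius, center=(0.0, 0.0)):
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.sin(angles), center[1] + radius * np.cos(angles)]
    )


class TestMinDistance3D:
    def test_centre_of_spherical_cloud(self):
        rng = np.random.default_rng(0)
        directions = rng.normal(size=(200, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        cloud = 2.0 * directions
        assert min_distance_3d(np.zeros(3), cloud) == pytest.approx(2.0)

    def test_coincident_point_zero(self):
        cloud = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert min_distance_3d(np.array([4.0, 5.0, 6.0]), cloud) == 0.0

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            min_distance_3d(np.zeros(3), np.empty((0, 3)))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_and_invariances(self, seed):
        rng = np.random.default_rng(seed)
        cloud = rng.uniform(-5, 5, size=(100, 3))
        spots = rng.uniform(-5, 5, size=(10, 3))
        shift = rng.uniform(-50, 50, size=3)
        extra = rng.uniform(-5, 5, size=3)
        for spot in spots:
            brute = np.min(np.linalg.norm(cloud - spot, axis=1))
            fast = min_distance_3d(spot, cloud)
            assert fast == pytest.approx(brute, abs=1e-12)
            # translation invariance
            assert min_distance_3d(spot + shift, cloud + shift) == pytest.approx(
                fast, abs=1e-9
            )
            # adding a point never increases the minimum
            assert min_distance_3d(spot, np.vstack([cloud, extra])) <= fast + 1e-12


class TestMaxProjection:
    def test_single_slice_is_identity(self):
        data = np.random.default_rng(1).integers(0, 100, size=(3, 1, 8, 8))
        stack = ImageStack(data)
        assert np.array_equal(max_project(stack), data[:, 0])

    def test_value_at_single_z_survives_and_order_invariant(self):
        data = np.zeros((3, 5, 8, 8), dtype=np.uint16)
        data[1, 3, 4, 4] = 777
        stack = ImageStack(data)
        proj = max_project(stack)
        assert proj[1, 4, 4] == 777
        permuted = ImageStack(data[:, ::-1].copy())
        assert np.array_equal(max_project(permuted), proj)

    def test_composite_shape_and_range(self):
        data = np.random.default_rng(2).integers(0, 500, size=(3, 4, 16, 16))
        rgb = max_project_composite(ImageStack(data))
        assert rgb.shape == (16, 16, 3)
        assert rgb.min() >= 0.0 and rgb.max() <= 1.0


class TestSplineROI:
    def test_requires_five_control_points(self):
        with pytest.raises(ValueError, match="5"):
            SplineROI(0, circle_points(4, 10, (20, 20)))

    def test_circle_mask_area_close_to_analytic(self):
        radius = 20.0
        roi = SplineROI(0, circle_points(8, radius, (32, 32)))
        mask = rasterize_spline(roi, (64, 64))
        assert mask.sum() == pytest.approx(np.pi * radius**2, rel=0.05)

    def test_mask_single_component_contains_centroid(self):
        from scipy import ndimage

        roi = SplineROI(0, circle_points(7, 12, (20, 24)))
        mask = rasterize_spline(roi, (48, 48))
        labeled, n = ndimage.label(mask)  # default 4-connectivity
        assert n == 1
        cy, cx = roi.control_points.mean(axis=0)
        assert mask[int(round(cy)), int(round(cx))]

    def test_small_loop_encloses_target_pixel(self):
        mask = rasterize_spline(SplineROI(0, circle_points(6, 1.6, (10, 10))), (20, 20))
        assert mask[10, 10]

    def test_self_intersecting_spline_rejected(self):
        pts = np.array(
            [[10.0, 10.0], [10.0, 30.0], [30.0, 10.0], [30.0, 30.0], [20.0, 5.0]]
        )
        with pytest.raises(ValueError, match="self-intersect"):
            rasterize_spline(SplineROI(0, pts), (40, 40))


class TestNormalizedDistanceMap:
    def test_max_is_exactly_one(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((40, 40), dtype=bool)
        mask[8:30, 5:35] = True
        ndmap = normalized_distance_map(mask)
        assert ndmap.map.max() == 1.0
        assert ndmap.map.min() >= 0.0

    def test_disk_centre_is_one_boundary_near_zero(self):
        yy, xx = np.mgrid[0:61, 0:61]
        mask = (yy - 30) ** 2 + (xx - 30) ** 2 <= 25**2
        ndmap = normalized_distance_map(mask)
        assert ndmap.map[30, 30] == 1.0
        boundary = mask & ~np.pad(mask, 1)[2:, 1:-1]  # pixels with background above
        assert ndmap.map[boundary].max() <= 1.5 / ndmap.max_raw_distance

    def test_single_pixel_mask(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        ndmap = normalized_distance_map(mask)
        assert ndmap.map[2, 3] == 1.0
        assert ndmap.map.sum() == 1.0

    def test_translation_invariance(self):
        base = np.zeros((50, 50), dtype=bool)
        base[5:20, 5:25] = True
        shifted = np.roll(base, (17, 13), axis=(0, 1))
        a = normalized_distance_map(base).map[5:20, 5:25]
        b = normalized_distance_map(shifted).map[22:37, 18:38]
        np.testing.assert_allclose(a, b)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalized_distance_map(np.zeros((10, 10), dtype=bool))


class TestNormalizedPosition:
    def test_argmax_maps_to_one_and_contour_to_near_zero(self):
        yy, xx = np.mgrid[0:41, 0:41]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        ndmap = normalized_distance_map(mask)
        assert normalized_position(ndmap.max_location, ndmap) == pytest.approx(1.0)
        edge = (20.0, 20.0 + 14.6)
        assert normalized_position(edge, ndmap) <= 1.5 / ndmap.max_raw_distance

    def test_disk_recovers_true_radial_position(self):
        radius = 25
        yy, xx = np.mgrid[0:61, 0:61]
        mask = (yy - 30) ** 2 + (xx - 30) ** 2 <= radius**2
        ndmap = normalized_distance_map(mask)
        for true_r in [0.2, 0.5, 0.8]:
            spot = (30.0, 30.0 + (1 - true_r) * radius)
            assert normalized_position(spot, ndmap) == pytest.approx(true_r, abs=0.05)

    def test_spot_outside_mask_errors_with_nucleus_id(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:10, 5:10] = True
        ndmap = normalized_distance_map(mask, nucleus_id=7)
        with pytest.raises(ValueError, match="nucleus 7"):
            normalized_position((15.0, 15.0), ndmap)


class TestPdfHistogram:
    def test_bars_sum_to_one(self):
        rng = np.random.default_rng(5)
        for n in [1, 7, 500]:
            h = pdf_histogram(rng.uniform(0, 1, n), np.linspace(0, 1, 21))
            assert abs(h.heights.sum() - 1.0) <= 1e-12

    def test_single_bin_concentration(self):
        h = pdf_histogram([0.31, 0.32, 0.33], np.linspace(0, 1, 11))
        assert h.heights[3] == 1.0 and h.heights.sum() == 1.0

    def test_uniform_values_within_binomial_bound(self):
        rng = np.random.default_rng(6)
        h = pdf_histogram(rng.uniform(0, 1, 500), np.linspace(0, 1, 21))
        bound = 5 * np.sqrt(0.05 * 0.95 / 500)
        assert np.all(np.abs(h.heights - 0.05) <= bound)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pdf_histogram([], np.linspace(0, 1, 11))

    def test_bins_must_cover_data(self):
        with pytest.raises(ValueError, match="cover"):
            pdf_histogram([1.5], np.linspace(0, 1, 11))


class TestCompareConditions:
    @staticmethod
    def records(values, condition):
        return [
            DistanceRecord(nucleus_id=1, spot_id=i, normalized_position=v, condition=condition)
            for i, v in enumerate(values)
        ]

    def test_identical_conditions_zero_median_difference(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 1, 50)
        cmp = compare_conditions(self.records(vals, "A"), self.records(vals, "B"))
        assert cmp.median_difference == 0.0

    def test_single_value_conditions(self):
        a = [DistanceRecord(1, 0, distance_3d_um=1.0)]
        b = [DistanceRecord(1, 0, distance_3d_um=2.0)]
        cmp = compare_conditions(a, b, readout="distance_3d_um")
        assert cmp.median_difference == -1.0

    def test_tethered_below_released(self):
        rng = np.random.default_rng(8)
        tethered = np.clip(rng.normal(0.3, 0.1, 80), 0, 2)
        released = np.clip(rng.normal(0.9, 0.2, 80), 0, 2)
        a = [DistanceRecord(1, i, distance_3d_um=v) for i, v in enumerate(tethered)]
        b = [DistanceRecord(1, i, distance_3d_um=v) for i, v in enumerate(released)]
        cmp = compare_conditions(a, b, readout="distance_3d_um")
        assert cmp.median_a < cmp.median_b

    def test_mismatched_readouts_rejected(self):
        a = [DistanceRecord(1, 0, distance_3d_um=1.0)]
        b = [DistanceRecord(1, 0, normalized_position=0.5)]
        with pytest.raises(ValueError):
            compare_conditions(a, b, readout="distance_3d_um")

    def test_histogram_plot_written(self, tmp_path):
        a = self.records(np.linspace(0.1, 0.4, 20), "control")
        b = self.records(np.linspace(0.3, 0.9, 20), "shRNA")
        out = tmp_path / "pdf.png"
        compare_conditions(a, b, plot_path=out)
        assert out.exists() and out.stat().st_size > 0
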