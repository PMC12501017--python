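"""FWHM diameters, cross-sectional areas, the resolution filter, endpoints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octavasc import (
    LumenMask,
    apply_resolution_filter,
    cross_section_area,
    fwhm,
    local_tangent,
    radial_profile,
    summarize,
)
from octavasc.morphometry import VesselSegmentMetrics, orthonormal_frame

ISO = (5.0, 5.0, 5.0)


class TestLocalTangent:
    def test_straight_polyline_along_x(self):
        pts = np.array([[0.0, 0.0, t] for t in range(0, 50, 5)], dtype=float)
        t = local_tangent(pts, 4)
        np.testing.assert_allclose(t, [0, 0, 1], atol=1e-12)

    def test_two_point_polyline_is_normalized_difference(self):
        pts = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 4.0]])
        t = local_tangent(pts, 0)
        np.testing.assert_allclose(t, [0.6, 0.0, 0.8], atol=1e-12)

    def test_corner_tangent_is_near_bisector(self):
        # right angle in the (y, x) plane: arms along +x then +y
        arm1 = [[0.0, 0.0, s] for s in range(0, 25, 5)]
        arm2 = [[0.0, s, 20.0] for s in range(5, 25, 5)]
        pts = np.array(arm1 + arm2)
        t = local_tangent(pts, 4, half_window=4)
        bisector = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        angle = np.degrees(np.arccos(np.clip(abs(t @ bisector), -1, 1)))
        assert angle < 1.0

    def test_coincident_window_rejected(self):
        pts = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        with pytest.raises(ValueError):
            local_tangent(pts, 1)

    def test_frame_is_orthonormal(self):
        t = np.array([0.3, -0.5, 0.81])
        t /= np.linalg.norm(t)
        n1, n2 = orthonormal_frame(t)
        for v in (n1, n2):
            assert np.linalg.norm(v) == pytest.approx(1.0)
            assert abs(v @ t) < 1e-12
        assert abs(n1 @ n2) < 1e-12


class TestRadialProfile:
    def test_constant_volume_gives_constant_profile(self):
        vol = np.full((10, 10, 10), 4.2)
        p = radial_profile(vol, ISO, np.array([22.5, 22.5, 22.5]),
                           np.array([0.0, 1.0, 0.0]), 10.0, 2.5)
        np.testing.assert_allclose(p, 4.2, atol=1e-12)

    def test_linear_field_sampled_exactly(self):
        z, y, x = np.indices((10, 10, 10), dtype=float)
        vol = x * 5.0  # f = x_um; trilinear interpolation is exact on affine fields
        p = radial_profile(vol, ISO, np.array([22.5, 22.5, 22.5]),
                           np.array([0.0, 0.0, 1.0]), 10.0, 2.5)
        expected = 22.5 + np.arange(-4, 5) * 2.5
        np.testing.assert_allclose(p, expected, atol=1e-9)

    def test_out_of_volume_samples_are_zero(self):
        vol = np.ones((8, 8, 8))
        p = radial_profile(vol, ISO, np.array([17.5, 17.5, 0.0]),
                           np.array([0.0, 0.0, -1.0]), 25.0, 2.5)
        assert p[-1] == 0.0  # sample far outside the grid

    def test_step_above_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            radial_profile(np.ones((8, 8, 8)), ISO, np.zeros(3),
                           np.array([0, 0, 1.0]), 10.0, 6.0)


class TestFWHM:
    def test_gaussian_profile_closed_form(self):
        step = 1.0
        xs = np.arange(-60, 61) * step
        prof = np.exp(-(xs**2) / (2 * 10.0**2))
        expected = 2 * np.sqrt(2 * np.log(2)) * 10.0  # 23.548
        assert fwhm(prof, step) == pytest.approx(expected, abs=step)

    def test_triangle_profile(self):
        a = 20.0
        step = 2.5
        xs = np.arange(-12, 13) * step
        prof = np.clip(1 - np.abs(xs) / a, 0, None)
        assert fwhm(prof, step) == pytest.approx(a, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        w=st.floats(8.0, 60.0),
        step=st.floats(1.0, 4.0),
        shift=st.floats(-2.0, 2.0),
    )
    def test_top_hat_width_within_one_step(self, w, step, shift):
        xs = np.arange(-40, 41) * step
        prof = ((xs - shift) >= -w / 2) & ((xs - shift) <= w / 2)
        got = fwhm(prof.astype(float), step)
        assert w - step <= got <= w + step

    def test_flat_profile_is_nan(self):
        assert np.isnan(fwhm(np.full(11, 2.0), 1.0))

    def test_profile_not_falling_to_half_on_one_side_is_nan(self):
        # peak at the right edge: the profile never falls back to the
        # half level on that side (unresolved vessel)
        prof = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        assert np.isnan(fwhm(prof, 1.0))


def filled_cylinder(shape, radius_um, vs=ISO, axis_offset=0.25):
    z, y, x = np.indices(shape, dtype=float)
    cz = ((shape[0] - 1) // 2 + axis_offset) * vs[0]
    cy = ((shape[1] - 1) // 2 + axis_offset) * vs[1]
    r2 = (z * vs[0] - cz) ** 2 + (y * vs[1] - cy) ** 2
    return (r2 <= radius_um**2), np.array([cz, cy])


class TestCrossSectionArea:
    def test_center_outside_mask_is_zero(self):
        mask, _ = filled_cylinder((20, 20, 20), 15.0)
        lum = LumenMask(mask=mask, voxel_size=ISO)
        a = cross_section_area(lum, np.array([2.0, 2.0, 50.0]), np.array([0, 0, 1.0]))
        assert a == 0.0

    @pytest.mark.parametrize("radius", [15.0, 25.0])
    def test_perpendicular_plane_recovers_disc_area(self, radius):
        mask, c = filled_cylinder((24, 24, 20), radius)
        lum = LumenMask(mask=mask, voxel_size=ISO)
        a = cross_section_area(
            lum, np.array([c[0], c[1], 50.0]), np.array([0, 0, 1.0]),
            patch_extent_um=radius + 20,
        )
        assert a == pytest.approx(np.pi * radius**2, rel=0.10)

    def test_oblique_cylinder_with_correct_tangent(self):
        # cylinder at 45 degrees in the (y, x) plane; feeding the true
        # tangent must still give the perpendicular disc area, not the
        # sqrt(2)-elongated axis-aligned cut
        shape = (24, 40, 40)
        z, y, x = np.indices(shape, dtype=float)
        c = 19.5 * 5.0
        vy, vx = y * 5.0 - c, x * 5.0 - c
        par = (vy + vx) / np.sqrt(2)
        cz = 11.25 * 5.0
        r2 = (z * 5.0 - cz) ** 2 + vy**2 + vx**2 - par**2
        radius = 15.0
        lum = LumenMask(mask=r2 <= radius**2, voxel_size=ISO)
        tangent = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        a = cross_section_area(
            lum, np.array([cz, c, c]), tangent, patch_extent_um=radius + 20
        )
        assert a == pytest.approx(np.pi * radius**2, rel=0.10)
        # the axis-aligned cut really is larger
        a_cut = cross_section_area(
            lum, np.array([cz, c, c]), np.array([0.0, 0.0, 1.0]),
            patch_extent_um=2 * radius + 20,
        )
        assert a_cut > 1.25 * a

    def test_connected_region_excludes_other_vessels(self):
        mask1, c = filled_cylinder((24, 40, 20), 15.0)
        mask2 = np.zeros_like(mask1)
        mask2[:, 30:34, :] = True  # a second vessel crossing the patch plane
        lum = LumenMask(mask=mask1 | mask2, voxel_size=ISO)
        a = cross_section_area(
            lum, np.array([c[0], c[1], 50.0]), np.array([0, 0, 1.0]),
            patch_extent_um=80.0,
        )
        assert a == pytest.approx(np.pi * 15.0**2, rel=0.10)


def _metric(seg_id, length_um, diameter_um, area_um2=500.0, points=None):
    return VesselSegmentMetrics(
        segment_id=seg_id,
        arc_length_um=length_um,
        diameters_um=[diameter_um],
        areas_um2=[area_um2],
        points_um=points,
    )


class TestResolutionFilter:
    def test_default_threshold_keeps_strictly_above_15(self):
        metrics = [_metric(0, 100, 10.0), _metric(1, 100, 20.0), _metric(2, 100, 40.0)]
        kept = apply_resolution_filter(metrics)
        assert [m.diameter_um for m in kept] == [20.0, 40.0]

    def test_exactly_15_is_excluded(self):
        assert apply_resolution_filter([_metric(0, 100, 15.0)]) == []

    def test_empty_and_all_below(self):
        assert apply_resolution_filter([]) == []
        assert apply_resolution_filter([_metric(0, 100, 5.0), _metric(1, 100, 14.9)]) == []


class TestSummarize:
    def test_no_segments_gives_zero_endpoints(self):
        lum = LumenMask(mask=np.zeros((8, 8, 8), bool), voxel_size=ISO)
        s = summarize([], lum)
        assert s.vessel_length_density == 0.0
        assert s.perfused_vessel_area_fraction == 0.0
        assert s.n_vessels == 0

    def test_full_span_tube_in_unit_field_has_density_one(self):
        # 1 mm x 1 mm en-face field, one tube spanning the full x extent
        shape = (12, 100, 100)
        vs = (10.0, 10.0, 10.0)
        mask = np.zeros(shape, bool)
        mask[5:7, 49:51, :] = True
        lum = LumenMask(mask=mask, voxel_size=vs)
        pts = np.array([[55.0, 500.0, 0.0], [55.0, 500.0, 990.0]])
        m = _metric(0, 990.0, 30.0, points=pts)
        s = summarize([m], lum)
        assert s.vessel_length_density == pytest.approx(0.99, rel=1e-6)
        assert s.total_length_mm == pytest.approx(0.99)

    def test_mask_covering_field_gives_fraction_one(self):
        shape = (4, 10, 10)
        mask = np.ones(shape, bool)
        lum = LumenMask(mask=mask, voxel_size=ISO)
        pts = np.array([[5.0, 25.0, 0.0], [5.0, 25.0, 45.0]])
        s = summarize([_metric(0, 45.0, 30.0, points=pts)], lum)
        assert s.perfused_vessel_area_fraction == pytest.approx(1.0)

    def test_projection_bound(self, iso_result, iso_phantom):
        _, _, _ = iso_phantom
        s = iso_result.summary
        mask = iso_result.mask
        nz, ny, nx = mask.mask.shape
        bound = mask.mask.sum() / (ny * nx)
        assert s.perfused_vessel_area_fraction <= bound + 1e-12

    def test_raising_min_diameter_is_monotone(self, iso_result):
        from octavasc import apply_resolution_filter, summarize

        prev_density, prev_frac = np.inf, np.inf
        for cutoff in (15.0, 25.0, 45.0, 70.0):
            kept = apply_resolution_filter(iso_result.all_metrics, cutoff)
            s = summarize(kept, iso_result.mask)
            assert s.vessel_length_density <= prev_density + 1e-12
            assert s.perfused_vessel_area_fraction <= prev_frac + 1e-12
            prev_density = s.vessel_length_density
            prev_frac = s.perfused_vessel_area_fraction

    def test_length_weighted_mean_diameter(self):
        lum = LumenMask(mask=np.ones((4, 8, 8), bool), voxel_size=ISO)
        p = np.array([[5.0, 20.0, 0.0], [5.0, 20.0, 35.0]])
        ms = [_metric(0, 100.0, 20.0, points=p), _metric(1, 300.0, 40.0, points=p)]
        s = summarize(ms, lum)
        assert s.mean_diameter_um == pytest.approx((100 * 20 + 300 * 40) / 400)


class TestPhantomRecovery:
    def test_diameters_within_one_voxel(self, iso_result, iso_phantom):
        spec, _, truth = iso_phantom
        truths = sorted(truth.diameters_um)
        got = sorted(iso_result.segments["diameter_um"])
        assert len(got) == len(truths)
        for g, t in zip(got, truths):
            assert abs(g - t) <= 5.0

    def test_areas_within_15pct_of_analytic(self, iso_result, iso_phantom):
        spec, _, truth = iso_phantom
        truths = sorted(truth.diameters_um)
        got = iso_result.segments.sort_values("diameter_um")["area_um2"].to_numpy()
        for g, t in zip(got, truths):
            analytic = np.pi * (t / 2) ** 2
            assert abs(g - analytic) <= 0.15 * analytic

    def test_total_length_within_10pct(self, iso_result, iso_phantom):
        _, _, truth = iso_phantom
        got = iso_result.summary.total_length_mm * 1000
        assert abs(got - truth.total_centerline_length_um) <= 0.10 * truth.total_centerline_length_um
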