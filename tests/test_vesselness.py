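"""Hessian eigenvalues and the multi-scale tubularity response."""

import numpy as np
import pytest
from scipy import ndimage

from octavasc import hessian_eigenvalues, multiscale_vesselness

ISO = (5.0, 5.0, 5.0)


def gaussian_ridge(shape=(21, 21, 21), s_um=15.0, vs=ISO):
    """Bright ridge along z: I = exp(-(x^2 + y^2) / (2 s^2))."""
    z, y, x = np.indices(shape, dtype=float)
    cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
    yy = (y - cy) * vs[1]
    xx = (x - cx) * vs[2]
    return np.exp(-(xx**2 + yy**2) / (2 * s_um**2))


def straight_tube(shape=(24, 24, 24), radius_um=20.0, vs=ISO, axis=2):
    idx = np.indices(shape, dtype=float)
    center = [(n - 1) / 2 * v for n, v in zip(shape, vs)]
    dims = [d for d in range(3) if d != axis]
    r2 = sum(((idx[d] * vs[d]) - center[d]) ** 2 for d in dims)
    return (r2 <= radius_um**2).astype(float)


class TestHessianEigenvalues:
    def test_constant_volume_gives_zero_eigenvalues(self):
        l1, l2, l3 = hessian_eigenvalues(np.full((10, 10, 10), 3.0), ISO, 10.0)
        for l in (l1, l2, l3):
            np.testing.assert_allclose(l, 0.0, atol=1e-10)

    def test_gaussian_ridge_matches_finite_difference_oracle(self):
        vol = gaussian_ridge(s_um=15.0)
        sigma = 15.0
        l1, l2, l3 = hessian_eigenvalues(vol, ISO, sigma)
        c = (10, 10, 10)
        # oracle: central finite differences of the Gaussian-smoothed
        # volume, gamma-normalized the same way
        sm = ndimage.gaussian_filter(vol, sigma=np.array(sigma) / np.array(ISO),
                                     mode="nearest")
        H = np.zeros((3, 3))
        h = np.array(ISO)
        for i in range(3):
            for j in range(3):
                e_i = np.zeros(3, int); e_i[i] = 1
                e_j = np.zeros(3, int); e_j[j] = 1
                pij = tuple(np.array(c) + e_i + e_j)
                pmij = tuple(np.array(c) - e_i + e_j)
                pimj = tuple(np.array(c) + e_i - e_j)
                pmimj = tuple(np.array(c) - e_i - e_j)
                H[i, j] = (sm[pij] - sm[pmij] - sm[pimj] + sm[pmimj]) / (
                    4 * h[i] * h[j]
                )
        H *= sigma**2
        oracle = np.linalg.eigvalsh(H)
        oracle = oracle[np.argsort(np.abs(oracle))]
        got = np.array([l1[c], l2[c], l3[c]])
        np.testing.assert_allclose(got, oracle, rtol=0.15, atol=1e-3)
        # ridge signature: axis eigenvalue ~ 0, transverse pair negative, equal
        assert abs(l1[c]) < 0.05 * abs(l3[c])
        assert l2[c] < 0 and l3[c] < 0
        assert abs(l2[c] - l3[c]) < 0.05 * abs(l3[c])

    def test_negating_volume_negates_eigenvalues(self):
        rng = np.random.default_rng(0)
        vol = rng.random((10, 10, 10))
        lp = hessian_eigenvalues(vol, ISO, 10.0)
        ln = hessian_eigenvalues(-vol, ISO, 10.0)
        for a, b in zip(lp, ln):
            np.testing.assert_allclose(a, -b, atol=1e-10)

    def test_undersampled_sigma_rejected(self):
        with pytest.raises(ValueError):
            hessian_eigenvalues(np.ones((8, 8, 8)), (8.0, 4.0, 4.0), 7.0)


class TestMultiscaleVesselness:
    def test_constant_volume_has_zero_response(self):
        out = multiscale_vesselness(np.full((10, 10, 10), 2.0), voxel_size=ISO)
        assert np.all(out.response == 0.0)

    def test_tube_best_scale_tracks_radius(self):
        radius = 20.0
        vol = straight_tube((24, 24, 40), radius_um=radius)
        scales = (5.0, 10.0, 20.0, 40.0)
        out = multiscale_vesselness(vol, scales_um=scales, voxel_size=ISO)
        c = (11, 11)
        axis_scales = out.best_scale[c[0], c[1], 10:30]
        axis_resp = out.response[c[0], c[1], 10:30]
        ladder = np.array(scales)
        matched = ladder[np.argmin(np.abs(ladder - radius))]
        step = np.searchsorted(ladder, matched)
        allowed = set(ladder[max(0, step - 1): step + 2])
        assert set(np.unique(axis_scales)) <= allowed
        # on-axis response dominates the background
        bg = out.response[2, 2, 10:30]
        assert axis_resp.min() > 10 * max(bg.max(), 1e-6)

    def test_blob_response_below_half_of_tube_response(self):
        # equal-contrast Gaussian blob vs Gaussian-profile tube
        vs = ISO
        z, y, x = np.indices((24, 24, 24), dtype=float)
        s = 15.0
        r2_blob = sum(((g - 11.5) * v) ** 2 for g, v in zip((z, y, x), vs))
        blob = np.exp(-r2_blob / (2 * s**2))
        r2_tube = ((z - 11.5) * 5.0) ** 2 + ((y - 11.5) * 5.0) ** 2
        tube = np.exp(-r2_tube / (2 * s**2))
        scales = (10.0, 20.0, 40.0)
        # shared fixed c so the structure-strength normalization is the
        # same for both volumes and responses are directly comparable
        vb = multiscale_vesselness(blob, scales_um=scales, voxel_size=vs, c=0.25)
        vt = multiscale_vesselness(tube, scales_um=scales, voxel_size=vs, c=0.25)
        assert vb.response.max() < 0.5 * vt.response.max()

    def test_response_bounded_on_random_volume(self):
        rng = np.random.default_rng(1)
        vol = rng.random((12, 12, 12))
        out = multiscale_vesselness(vol, scales_um=(5.0, 10.0), voxel_size=ISO)
        assert np.all(out.response >= 0.0) and np.all(out.response <= 1.0)
        assert np.all(np.isin(out.best_scale[out.response > 0], (5.0, 10.0)))

    def test_adding_a_scale_never_decreases_response(self):
        vol = straight_tube((20, 20, 20), radius_um=15.0)
        small = multiscale_vesselness(vol, scales_um=(10.0, 20.0), voxel_size=ISO)
        big = multiscale_vesselness(vol, scales_um=(10.0, 20.0, 40.0), voxel_size=ISO)
        assert np.all(big.response >= small.response - 1e-12)

    def test_rotated_tube_response_within_15pct(self):
        # tube along x vs the same tube rotated 45 degrees in the (y, x) plane
        n = 40
        z, y, x = np.indices((20, n, n), dtype=float)
        cz, c = 9.5, (n - 1) / 2
        radius = 20.0
        d2_straight = ((z - cz) * 5.0) ** 2 + ((y - c) * 5.0) ** 2
        straight = (d2_straight <= radius**2).astype(float)
        # axis direction (0, 1, 1)/sqrt(2): remove the parallel component
        vy, vx = (y - c) * 5.0, (x - c) * 5.0
        par = (vy + vx) / np.sqrt(2)
        d2_rot = ((z - cz) * 5.0) ** 2 + vy**2 + vx**2 - par**2
        rotated = (d2_rot <= radius**2).astype(float)
        scales = (10.0, 20.0, 40.0)
        vs_ = multiscale_vesselness(straight, scales_um=scales, voxel_size=ISO)
        vr = multiscale_vesselness(rotated, scales_um=scales, voxel_size=ISO)
        interior = (slice(8, 12), slice(15, 25), slice(15, 25))
        peak_straight = vs_.response[interior].max()
        peak_rot = vr.response[interior].max()
        assert abs(peak_rot - peak_straight) < 0.15 * peak_straight

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError):
            multiscale_vesselness(np.ones((8, 8, 8)), scales_um=(), voxel_size=ISO)
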