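"""Planar/SPECT quantification: scatter, attenuation, calibration, VOIs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from marrowdose import (
    LU177_WINDOWS,
    MuProjectionMap,
    PlanarStudy,
    build_mu_projection,
    calibrate_planar,
    conjugate_view,
    fit_mu_calibration,
    percent_isocontour_voi,
    tew_scatter_correct,
    voi_activity,
)
from marrowdose.errors import (
    CalibrationError,
    EmptyRegionError,
    MissingSegmentError,
    ShapeError,
)


def make_study(peak, lower=None, upper=None, duration=1.0):
    peak = np.asarray(peak, float)
    z = np.zeros_like(peak)
    lower = z if lower is None else np.asarray(lower, float)
    upper = z if upper is None else np.asarray(upper, float)
    return PlanarStudy(
        ant_peak=peak,
        post_peak=peak.copy(),
        ant_lower=lower,
        post_lower=lower.copy(),
        ant_upper=upper,
        post_upper=upper.copy(),
        duration_s=duration,
        pixel_mm=2.4,
        time_h=24.0,
    )


class TestTewScatterCorrect:
    def test_window_scheme_absolute_widths(self):
        assert LU177_WINDOWS.absolute_widths() == pytest.approx((31.2, 25.5, 24.0))

    def test_zero_scatter_windows_leave_photopeak_unchanged(self):
        study = make_study([[1000.0, 10.0]])
        ant, post = tew_scatter_correct(study)
        np.testing.assert_allclose(ant, [[1000.0, 10.0]])
        np.testing.assert_allclose(post, ant)

    def test_hand_evaluated_trapezoid(self):
        study = make_study([[1000.0]], [[100.0]], [[50.0]])
        ant, _ = tew_scatter_correct(study)
        expected = 1000.0 - (100.0 / 25.5 + 50.0 / 24.0) * 31.2 / 2.0
        assert ant[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_overwhelming_scatter_floors_at_zero(self):
        study = make_study([[10.0]], [[1000.0]], [[1000.0]])
        ant, post = tew_scatter_correct(study)
        assert ant[0, 0] == 0.0 and post[0, 0] == 0.0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ShapeError):
            PlanarStudy(
                ant_peak=np.zeros((2, 2)),
                post_peak=np.zeros((2, 2)),
                ant_lower=np.zeros((3, 2)),
                post_lower=np.zeros((2, 2)),
                ant_upper=np.zeros((2, 2)),
                post_upper=np.zeros((2, 2)),
                duration_s=1.0,
                pixel_mm=2.4,
                time_h=24.0,
            )

    @given(
        peak=st.floats(0, 1e6),
        low=st.floats(0, 1e6),
        up=st.floats(0, 1e6),
    )
    def test_never_negative_and_never_exceeds_photopeak(self, peak, low, up):
        study = make_study([[peak]], [[low]], [[up]])
        ant, _ = tew_scatter_correct(study)
        assert 0.0 <= ant[0, 0] <= peak


class TestMuCalibration:
    def test_noiseless_bilinear_recovery(self):
        mu_water, s_neg, s_pos = 0.0095, 1.0e-5, 4.5e-6
        hu = np.array([-600.0, -300.0, -100.0, 100.0, 500.0, 1000.0])
        mu = mu_water + np.where(hu < 0, s_neg, s_pos) * hu
        cal = fit_mu_calibration(np.column_stack([hu, mu]))
        assert cal.mu_water == pytest.approx(mu_water, rel=1e-9)
        assert cal.slope_neg == pytest.approx(s_neg, rel=1e-9)
        assert cal.slope_pos == pytest.approx(s_pos, rel=1e-9)

    def test_continuity_at_zero_hu(self):
        cal = fit_mu_calibration([(-500, 0.004), (-200, 0.007), (300, 0.011), (900, 0.013)])
        assert cal(0.0) == pytest.approx(cal(-1e-12), rel=1e-9)

    def test_clamps_outside_calibrated_range(self):
        cal = fit_mu_calibration([(-500, 0.004), (-200, 0.007), (300, 0.011), (900, 0.013)])
        assert cal(2000.0) == pytest.approx(cal(1127.0))
        assert cal(-5000.0) == pytest.approx(cal(-688.0))

    def test_one_sided_rod_set_rejected(self):
        with pytest.raises(CalibrationError):
            fit_mu_calibration([(100, 0.01), (200, 0.011), (300, 0.012)])


class TestMuProjection:
    def test_uniform_water_slab_optical_depth(self):
        mu = np.full((4, 4, 100), 0.0095)  # 1/mm, 100 voxels of 2 mm = 200 mm
        seg = np.ones((4, 4), dtype=int)
        result = build_mu_projection(
            mu, seg, {}, blur_fwhm_mm=0.0, pixel_mm=2.4, voxel_depth_mm=2.0
        )
        np.testing.assert_allclose(result.optical_depth, 1.9, rtol=1e-12)
        assert (result.provenance == 0).all()

    def test_segment_default_assignment(self):
        seg = np.full((3, 3), 7, dtype=int)
        result = build_mu_projection(
            None, seg, {7: 1.2}, blur_fwhm_mm=0.0, pixel_mm=2.4
        )
        np.testing.assert_allclose(result.optical_depth, 1.2)
        assert (result.provenance == 1).all()

    def test_missing_segment_default_names_label(self):
        seg = np.full((2, 2), 3, dtype=int)
        with pytest.raises(MissingSegmentError) as exc:
            build_mu_projection(None, seg, {}, blur_fwhm_mm=0.0, pixel_mm=2.4)
        assert exc.value.label == 3

    def test_blur_matches_closed_form_gaussian(self):
        """A blurred delta map reproduces the normalised camera Gaussian."""
        n, pixel_mm, fwhm = 81, 2.4, 11.0
        seg = np.ones((n, n), dtype=int)
        mu = np.zeros((n, n, 1))
        mu[n // 2, n // 2, 0] = 1.0  # unit optical depth at the centre
        result = build_mu_projection(
            mu, seg, {}, blur_fwhm_mm=fwhm, pixel_mm=pixel_mm, voxel_depth_mm=1.0
        )
        sigma_px = fwhm / (2 * math.sqrt(2 * math.log(2))) / pixel_mm
        yy, xx = np.mgrid[0:n, 0:n]
        r2 = (yy - n // 2) ** 2 + (xx - n // 2) ** 2
        expected = np.exp(-r2 / (2 * sigma_px**2)) / (2 * math.pi * sigma_px**2)
        np.testing.assert_allclose(result.optical_depth, expected, atol=1e-6)


class TestConjugateView:
    def test_no_attenuation_is_geometric_mean_rate(self):
        ant = np.array([[100.0, 400.0]])
        post = np.array([[400.0, 100.0]])
        out = conjugate_view(ant, post, np.zeros((1, 2)), duration_s=2.0)
        np.testing.assert_allclose(out, [[100.0, 100.0]])

    def test_analytic_transmission_half(self):
        out = conjugate_view(
            np.array([[400.0]]), np.array([[400.0]]), np.array([[math.log(4)]]), 1.0
        )
        assert out[0, 0] == pytest.approx(800.0, rel=1e-12)

    def test_swap_invariance(self):
        rng = np.random.default_rng(3)
        ant, post = rng.uniform(0, 500, (2, 8, 8))
        depth = rng.uniform(0, 3, (8, 8))
        a = conjugate_view(ant, post, depth, 30.0)
        b = conjugate_view(post, ant, depth, 30.0)
        np.testing.assert_allclose(a, b)

    def test_zero_count_pixels_stay_zero(self):
        out = conjugate_view(
            np.array([[0.0]]), np.array([[500.0]]), np.array([[2.0]]), 1.0
        )
        assert out[0, 0] == 0.0


class TestPlanarCalibration:
    def test_simple_division(self):
        cal = calibrate_planar(2000.0, 1e6)
        assert cal.factor_bq_per_cps == pytest.approx(500.0)

    def test_identity(self):
        assert calibrate_planar(1.0, 1.0).factor_bq_per_cps == 1.0

    def test_zero_rate_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_planar(0.0, 1e6)


class TestIsocontourVoi:
    def test_uniform_region_fully_selected(self):
        vol = np.zeros((10, 10, 10))
        zz, yy, xx = np.mgrid[0:10, 0:10, 0:10]
        sphere = (zz - 5) ** 2 + (yy - 5) ** 2 + (xx - 5) ** 2 <= 9
        vol[sphere] = 100.0
        box = np.ones_like(vol, dtype=bool)
        voi = percent_isocontour_voi(vol, box, 0.40, "kidney_L")
        assert voi.n_voxels == sphere.sum()

    def test_gaussian_blob_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        zz, yy, xx = np.mgrid[0:16, 0:16, 0:16].astype(float)
        vol = np.exp(-((zz - 8) ** 2 + (yy - 7) ** 2 + (xx - 9) ** 2) / 18.0)
        vol += 0.01 * rng.random(vol.shape)
        box = np.ones_like(vol, dtype=bool)
        voi = percent_isocontour_voi(vol, box, 0.50)
        brute = sum(
            1
            for i in range(16)
            for j in range(16)
            for k in range(16)
            if vol[i, j, k] >= 0.5 * vol.max()
        )
        assert voi.n_voxels == brute

    def test_threshold_near_max_keeps_only_max_voxel(self):
        vol = np.zeros((5, 5, 5))
        vol[2, 2, 2] = 10.0
        vol[1, 1, 1] = 9.0
        voi = percent_isocontour_voi(vol, np.ones_like(vol, bool), 0.999)
        assert voi.n_voxels == 1 and voi.mask[2, 2, 2]

    def test_monotone_in_percent(self):
        rng = np.random.default_rng(5)
        vol = rng.random((8, 8, 8))
        box = np.ones_like(vol, dtype=bool)
        counts = [
            percent_isocontour_voi(vol, box, p).n_voxels
            for p in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_all_zero_region_rejected(self):
        with pytest.raises(EmptyRegionError):
            percent_isocontour_voi(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool), 0.4)


class TestVoiActivity:
    def test_uniform_product(self):
        vol = np.full((10, 10, 1), 1000.0)
        mask = np.zeros_like(vol, bool)
        mask.flat[:50] = True
        assert voi_activity(vol, mask, 0.1) == pytest.approx(5000.0)

    def test_tumour_subtraction_additivity(self):
        rng = np.random.default_rng(7)
        vol = rng.uniform(0, 2000, (12, 12, 12))
        organ = np.zeros_like(vol, bool)
        organ[2:10, 2:10, 2:10] = True
        tumour = np.zeros_like(vol, bool)
        tumour[4:6, 4:6, 4:6] = True
        healthy = voi_activity(vol, organ, 0.2, subtract=tumour)
        assert healthy == pytest.approx(
            voi_activity(vol, organ, 0.2) - voi_activity(vol, tumour, 0.2)
        )

    def test_matches_brute_force_voxel_loop(self):
        rng = np.random.default_rng(9)
        vol = rng.uniform(0, 100, (6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.5
        expected = sum(
            vol[i, j, k] * 0.25
            for i in range(6)
            for j in range(6)
            for k in range(6)
            if mask[i, j, k]
        )
        assert voi_activity(vol, mask, 0.25) == pytest.approx(expected)
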