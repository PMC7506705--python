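import math

import numpy as np
import pytest

from fireflysim.calibration import (AsrCurve, assess_linearity, dark_stats,
                                    default_scan_plan, estimate_asr,
                                    fit_fwhm_surface,
                                    fit_linear_calibrations, fwhm_from_asr,
                                    plan_wavelengths, simulate_scan,
                                    stray_light_metrics)
from fireflysim.exceptions import (CalibrationError, DegenerateFeatureError,
                                   DomainError)
from fireflysim.instrument import FwhmSurface, InstrumentModel


class TestScanPlan:
    def test_fine_ranges_have_91_samples(self):
        for start, end in [(690.0, 694.5), (707.0, 711.5),
                           (725.0, 729.5), (760.0, 764.5)]:
            samples = plan_wavelengths([(start, end, 0.05)])
            assert len(samples) == 91

    def test_default_plan_deduplicated(self):
        plan = default_scan_plan()
        assert len(plan) == len(set(plan))
        assert (742.0, 746.5, 0.15) in plan

    def test_out_of_range_plan_rejected(self):
        with pytest.raises(DomainError):
            plan_wavelengths([(650.0, 660.0, 1.0)])


class TestSimulateScan:
    def test_seed_determinism(self, instrument):
        plan = [(760.0, 761.0, 0.05)]
        a = simulate_scan(instrument, plan, seed=42)
        b = simulate_scan(instrument, plan, seed=42)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.dn, rb.dn)
            assert ra.wavelength == rb.wavelength or (
                math.isnan(ra.wavelength) and math.isnan(rb.wavelength))

    def test_line_at_band_center_maximizes_that_band(self, instrument):
        center = float(instrument.band_wavelength(1500))
        recs = simulate_scan(instrument, [(center, center, 0.05)],
                             add_noise=False)
        open_rec = next(r for r in recs if r.shutter == "open")
        assert int(np.argmax(open_rec.dn[0])) == 1500 - 1

    def test_records_alternate_with_backgrounds(self, instrument):
        recs = simulate_scan(instrument, [(760.0, 761.0, 0.05)], seed=0)
        states = [r.shutter for r in recs]
        assert states[0] == "background" and states[-1] == "background"
        assert "open" in states


class TestEstimateAsr:
    def test_parameter_recovery(self, asr_curves, instrument):
        assert len(asr_curves) >= 100
        errors = [abs(c.center - float(instrument.band_wavelength(c.band)))
                  for c in asr_curves]
        assert max(errors) < 0.005

    def test_high_wavelength_sd_records_excluded(self, instrument):
        import dataclasses
        plan = [(760.0, 762.0, 0.05)]
        recs = simulate_scan(instrument, plan, seed=1)
        # mark every open record as high-variance: nothing survives
        bad = [dataclasses.replace(r, wavelength_sd=0.05)
               if r.shutter == "open" else r for r in recs]
        assert estimate_asr(bad) == []

    def test_all_background_is_an_error(self, scan_records):
        backgrounds = [r for r in scan_records if r.shutter == "background"]
        with pytest.raises(CalibrationError, match="open"):
            estimate_asr(backgrounds)

    def test_order_independent(self, instrument):
        plan = [(760.0, 761.5, 0.05)]
        recs = simulate_scan(instrument, plan, seed=2)
        shuffled = list(recs)
        np.random.default_rng(0).shuffle(shuffled)
        a = {c.band: c.center for c in estimate_asr(recs)}
        b = {c.band: c.center for c in estimate_asr(shuffled)}
        assert a == b


class TestFwhmEstimators:
    def _gaussian_curve(self, sigma=0.07, height=1000.0):
        return AsrCurve(band=1, pixel=1, sample_wavelengths=np.array([]),
                        sample_values=np.array([]), center=700.0,
                        sigma=sigma, height=height)

    def test_gaussian_equivalent_width(self):
        br, fwhm_eq, fwhm_hm = fwhm_from_asr(self._gaussian_curve())
        # closed forms for a sigma = 0.07 nm Gaussian
        assert fwhm_eq == pytest.approx(0.07 * math.sqrt(2 * math.pi),
                                        rel=1e-3)
        assert fwhm_eq == pytest.approx(0.17547, abs=2e-4)
        assert fwhm_hm == pytest.approx(2.3548 * 0.07, rel=1e-3)
        assert fwhm_hm == pytest.approx(0.16484, abs=2e-4)

    def test_gaussian_estimator_ratio(self):
        _, fwhm_eq, fwhm_hm = fwhm_from_asr(self._gaussian_curve(0.05))
        ratio = math.sqrt(2 * math.pi) / (2 * math.sqrt(2 * math.log(2)))
        assert fwhm_eq / fwhm_hm == pytest.approx(ratio, rel=1e-3)
        assert ratio == pytest.approx(1.06447, abs=1e-5)

    def test_rectangular_asr(self):
        w = 0.1
        n = int(round(w / 0.001)) + 1
        grid = 700.0 + 0.001 * np.arange(n)
        curve = AsrCurve(band=1, pixel=1, sample_wavelengths=np.array([]),
                         sample_values=np.array([]), center=700.05,
                         sigma=0.03, height=5.0,
                         grid_wavelengths=grid,
                         grid_values=np.full(n, 5.0))
        br, fwhm_eq, fwhm_hm = fwhm_from_asr(curve)
        assert fwhm_eq == pytest.approx(w, rel=0.02)
        assert fwhm_hm == pytest.approx(w, rel=0.02)

    def test_zero_peak_degenerate(self):
        curve = self._gaussian_curve(height=0.0)
        with pytest.raises(DegenerateFeatureError):
            fwhm_from_asr(curve)


class TestLinearCalibrations:
    def test_closed_loop_recovery(self, asr_curves, instrument):
        cal = fit_linear_calibrations(asr_curves)
        assert abs(cal.band_slope - 0.0512) / 0.0512 < 1e-3
        assert abs(cal.band_intercept - 670.12) / 670.12 < 1e-3
        assert abs(cal.response_slope - (-185.67)) / 185.67 < 0.01
        assert cal.band_r2 > 0.999999

    def test_noise_free_r2_is_one(self, instrument):
        recs = simulate_scan(instrument, [(725.0, 729.5, 0.05)],
                             add_noise=False)
        curves = estimate_asr(recs)
        assert len(curves) >= 10
        cal = fit_linear_calibrations(curves)
        assert cal.band_r2 > 1.0 - 1e-8

    def test_needs_ten_bands(self, asr_curves):
        with pytest.raises(DomainError):
            fit_linear_calibrations(asr_curves[:5])


class TestFwhmSurfaceFit:
    def _samples(self, surface, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for d in (1, 40, 80, 133, 180, 220, 266):
            for w in np.linspace(675.0, 778.0, 9):
                f = surface.evaluate(d, w, clip=False)
                rows.append((d, w, f + rng.normal(0.0, jitter)))
        return rows

    def test_exact_recovery_noise_free(self):
        truth = FwhmSurface()
        fitted, resid_sd = fit_fwhm_surface(self._samples(truth))
        assert fitted.c_d2 == pytest.approx(truth.c_d2, rel=1e-8)
        assert fitted.c_d == pytest.approx(truth.c_d, rel=1e-8)
        assert fitted.c_w == pytest.approx(truth.c_w, rel=1e-8)
        assert fitted.c_0 == pytest.approx(truth.c_0, rel=1e-8)
        assert resid_sd == pytest.approx(0.0, abs=1e-12)

    def test_residual_sd_recovered_under_jitter(self):
        truth = FwhmSurface()
        _, resid_sd = fit_fwhm_surface(
            self._samples(truth, jitter=0.007, seed=4))
        assert abs(resid_sd - 0.007) / 0.007 < 0.20

    def test_single_pixel_is_collinear(self):
        rows = [(133, w, 0.15) for w in np.linspace(675.0, 778.0, 12)]
        with pytest.raises(DomainError, match="collinear"):
            fit_fwhm_surface(rows)


class TestStrayLight:
    def test_clean_truth_has_no_stray_light(self, instrument):
        recs = simulate_scan(instrument, [(690.0, 1000.0, 10.0)],
                             add_noise=False)
        metrics = stray_light_metrics(recs, instrument=instrument)
        assert metrics["off_diagonal_median"] < 1e-6
        assert metrics["far_field_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_injected_stray_floor_recovered(self, instrument):
        recs = simulate_scan(instrument, [(700.0, 760.0, 10.0)],
                             add_noise=False, stray_fraction=0.001)
        metrics = stray_light_metrics(recs, instrument=instrument)
        assert metrics["off_diagonal_median"] == pytest.approx(0.001,
                                                               rel=0.10)


class TestLinearity:
    def test_perfectly_linear_series(self):
        rad = np.linspace(200.0, 1200.0, 25)
        dn = 40.0 * rad + 100.0
        assert assess_linearity(list(zip(rad, dn))) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_cubic_distortion_detected(self):
        rad = np.linspace(200.0, 1200.0, 25)
        dn = 40.0 * rad + 100.0
        # 0.5%-amplitude cubic distortion, orthogonalized against the
        # linear term so a refit cannot absorb it
        x = (rad - 700.0) / 500.0
        dn = dn * (1.0 + 0.005 * (x ** 3 - 0.75 * x) / 0.25)
        assert assess_linearity(list(zip(rad, dn))) >= 0.004

    def test_default_truth_is_linear_enough(self, instrument):
        band = np.array([1080])
        rad = np.linspace(260.0, 1300.0, 30)
        dn = [float(instrument.radiance_to_dn(np.array([r]), 133,
                                              add_noise=False,
                                              band_indices=band)[0])
              for r in rad]
        assert assess_linearity(list(zip(rad, dn))) <= 0.003

    def test_window_coverage_required(self):
        with pytest.raises(DomainError):
            assess_linearity([(1.0, 100.0), (2.0, 200.0)])


class TestDarkStats:
    def test_profiles_match_model(self, instrument):
        frames = instrument.dark_frames(
            1000, seed=6, pixels=np.arange(10, 30),
            bands=np.array([1, 540, 1080, 1620, 2160]))
        stats = dark_stats(frames)
        assert stats.spectral_profile[2] == pytest.approx(100.0, abs=0.5)
        assert stats.spectral_profile[0] == pytest.approx(105.0, abs=0.5)
        assert np.all(np.abs(stats.sd_map - 2.0) / 2.0 < 0.10)

    def test_constant_frames_zero_sd(self):
        frames = np.full((5, 3, 4), 100.0)
        assert np.all(dark_stats(frames).sd_map == 0.0)

    def test_single_frame_rejected(self):
        with pytest.raises(DomainError, match="2 frames"):
            dark_stats(np.full((1, 3, 4), 100.0))
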