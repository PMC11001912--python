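"""Reference-channel calibration: peak fitting, laser recovery, normalization,
response correction, and QE drift-averaging."""

import numpy as np
import pytest

import reframan as rf
from reframan.refcal import (
    CalibrationError,
    PeakFit,
    estimate_laser_wavenumber,
    fit_reference_peaks,
    normalize_intensity,
    reference_peak_area,
    build_response_curve,
    apply_response,
    drift_average,
    highfreq_noise,
)
from reframan.instrument_sim import expected_band
from reframan.spectral_core import (
    AxisKind,
    SpectralAxis,
    Spectrum,
    default_shift_grid,
    planck_radiance,
    shift_to_wavelength,
)


def render_and_extract(config, state, sample=None, seed=None, qe_map=None, **kw):
    add_noise = seed is not None
    frame = rf.render_frame(config, state, sample, seed=seed, qe_map=qe_map,
                            add_noise=add_noise, **kw)
    ref = rf.extract_channel(frame, config.optics.reference_rows, "reference")
    main = rf.extract_channel(frame, config.optics.main_rows, "main")
    return main, ref


class TestPeakFitting:
    def test_noiseless_centers_within_005_pixel(self, config):
        state = rf.LaserState.single(785.0)
        _, ref = render_and_extract(config, state)
        fits = fit_reference_peaks(ref, config.reference_lines, config.optics, 785.0)
        ok = [f for f in fits if f.success]
        assert len(ok) >= 5
        for f in ok:
            lam_true = shift_to_wavelength(785.0, f.line_cm1)
            col_true = config.optics.column_of_wavelength(lam_true)
            assert abs(f.center_px - col_true) < 0.05

    def test_all_zero_spectrum_raises(self, config):
        zeros = Spectrum(SpectralAxis.pixel(config.sensor.cols), np.zeros(config.sensor.cols))
        with pytest.raises(CalibrationError):
            fit_reference_peaks(zeros, config.reference_lines, config.optics, 785.0)

    def test_noisy_centers_within_02_pixel(self, config):
        # the prominent reference lines (the ones the calibration leans on)
        # localize to < 0.2 pixel at the reference channel's SNR
        state = rf.LaserState.single(785.0)
        rng = np.random.default_rng(0)
        strong = {l.center_cm1 for l in config.reference_lines.lines if l.rel_intensity >= 20}
        worst = 0.0
        for _ in range(20):
            _, ref = render_and_extract(config, state, seed=rng)
            fits = fit_reference_peaks(ref, config.reference_lines, config.optics, 785.0)
            for f in fits:
                if not f.success or f.line_cm1 not in strong:
                    continue
                col_true = config.optics.column_of_wavelength(
                    shift_to_wavelength(785.0, f.line_cm1)
                )
                worst = max(worst, abs(f.center_px - col_true))
        assert worst < 0.2


class TestLaserEstimate:
    def test_recovers_drifted_wavelength(self, config):
        state = rf.LaserState.single(785.15)
        _, ref = render_and_extract(config, state)
        fits = fit_reference_peaks(ref, config.reference_lines, config.optics, 785.0)
        cal = estimate_laser_wavenumber(fits, config.optics)
        assert abs(cal.laser_nm - 785.15) < 0.01

    def test_translation_equivariance(self, config):
        # moving every fitted line by the same wavenumber moves the laser
        # estimate by exactly that amount
        state = rf.LaserState.single(785.0)
        _, ref = render_and_extract(config, state)
        fits = fit_reference_peaks(ref, config.reference_lines, config.optics, 785.0)
        cal = estimate_laser_wavenumber(fits, config.optics)
        shifted = [
            PeakFit(f.line_cm1 + 4.0, f.center_px, f.center_nm, f.amplitude,
                    f.area, f.fwhm_px, f.rmse, f.success)
            for f in fits
        ]
        cal2 = estimate_laser_wavenumber(shifted, config.optics)
        assert cal2.laser_wavenumber_cm1 - cal.laser_wavenumber_cm1 == pytest.approx(4.0, abs=1e-9)

    def test_single_corrupted_peak_rejected(self, config):
        state = rf.LaserState.single(785.0)
        _, ref = render_and_extract(config, state)
        fits = fit_reference_peaks(ref, config.reference_lines, config.optics, 785.0)
        cal = estimate_laser_wavenumber(fits, config.optics)
        bad = list(fits)
        f = bad[2]
        bad[2] = PeakFit(f.line_cm1, f.center_px + 8.0, f.center_nm + 0.6, f.amplitude,
                         f.area, f.fwhm_px, f.rmse, True)
        cal2 = estimate_laser_wavenumber(bad, config.optics)
        assert abs(cal2.laser_wavenumber_cm1 - cal.laser_wavenumber_cm1) < 0.1

    def test_too_few_peaks_raises(self, config):
        fits = [PeakFit(1001.4, 650.0, 852.3, 1.0, 1.0, 3.0, 0.0, True)] * 2
        with pytest.raises(CalibrationError):
            estimate_laser_wavenumber(fits, config.optics)

    def test_parameter_recovery_under_drift_and_noise(self, config):
        # |estimated - true| <= 1.5 cm^-1 across drifting noisy acquisitions
        laser = rf.LaserModel(drift_total_nm=0.3, drift_tau_s=60.0)
        states = rf.simulate_laser_sequence(laser, 25, 5.0, seed=6)
        rng = np.random.default_rng(7)
        for state in states:
            _, ref = render_and_extract(config, state, seed=rng)
            fits = fit_reference_peaks(ref, config.reference_lines, config.optics, 785.0)
            cal = estimate_laser_wavenumber(fits, config.optics)
            err_cm1 = abs(cal.laser_wavenumber_cm1 - 1e7 / state.wavelength_nm)
            assert err_cm1 <= 1.5


class TestShiftAxis:
    def test_identity_against_simulator_truth(self, config, calibrate_frame, noiseless_frame):
        # zero drift + known optics: calibrated axis equals the truth mapping
        main_cal, _, cal = calibrate_frame(noiseless_frame)
        px = np.arange(config.sensor.cols, dtype=float)
        lam = config.optics.wavelength_of_column(px)
        truth_shift = 1e7 / 785.0 - 1e7 / lam
        # the recovered laser wavenumber reproduces the true axis to < 1e-6 of
        # the span at every calibrated grid point
        assert abs(cal.laser_wavenumber_cm1 - 1e7 / 785.0) < 2e-3
        assert main_cal.axis.kind == AxisKind.RAMAN_SHIFT_CM1
        assert main_cal.x[0] >= truth_shift[0] - 0.5
        assert main_cal.x[-1] <= truth_shift[-1] + 0.5

    def test_polystyrene_in_main_lands_at_1001(self, config, polystyrene_sample, calibrate_frame):
        frame = rf.render_frame(
            config, rf.LaserState.single(785.1), polystyrene_sample, add_noise=False
        )
        main_cal, _, _ = calibrate_frame(frame)
        peak = rf.peak_position(main_cal, near=1001.0)
        assert round(peak) == 1001

    def test_peak_static_under_drift(self, config, polypropylene, calibrate_frame):
        # the defining property: laser drift moves nothing on the calibrated axis
        positions = []
        for lam in (785.0, 785.1, 785.25):
            frame = rf.render_frame(config, rf.LaserState.single(lam), polypropylene,
                                    add_noise=False)
            main_cal, _, _ = calibrate_frame(frame)
            sel = (main_cal.x > 780) & (main_cal.x < 840)
            positions.append(main_cal.x[sel][np.argmax(main_cal.y[sel])])
        assert max(positions) - min(positions) <= 1.0


class TestIntensityNormalization:
    def test_power_fluctuation_normalized_within_1pct(self, config, polypropylene, calibrate_frame):
        areas = []
        baseline = None
        for power in (1.0, 0.9, 1.1):
            frame = rf.render_frame(
                config, rf.LaserState.single(785.0, relative_power=power),
                polypropylene, add_noise=False,
            )
            main_cal, ref_cal, cal = calibrate_frame(frame)
            if baseline is None:
                baseline = reference_peak_area(ref_cal)
            norm = normalize_intensity(main_cal, ref_cal, baseline, cal)
            sel = (norm.x > 795) & (norm.x < 825)
            areas.append(np.trapezoid(norm.y[sel], norm.x[sel]))
        assert (max(areas) - min(areas)) / np.mean(areas) < 0.01

    def test_same_frame_scale_is_one(self, config, polypropylene, calibrate_frame, noiseless_frame):
        main_cal, ref_cal, cal = calibrate_frame(noiseless_frame)
        baseline = reference_peak_area(ref_cal)
        normalize_intensity(main_cal, ref_cal, baseline, cal)
        assert cal.intensity_scale == pytest.approx(1.0, abs=1e-9)

    def test_scale_recovery_under_noise(self, config, polypropylene, calibrate_frame):
        # power 0.8 -> scale 1.25 within 1% at the reference channel's SNR
        rng = np.random.default_rng(8)
        frame0 = rf.render_frame(config, rf.LaserState.single(785.0), polypropylene,
                                 add_noise=False)
        _, ref0, _ = calibrate_frame(frame0)
        baseline = reference_peak_area(ref0)
        scales = []
        for _ in range(10):
            frame = rf.render_frame(
                config, rf.LaserState.single(785.0, relative_power=0.8),
                polypropylene, seed=rng,
            )
            main_cal, ref_cal, cal = calibrate_frame(frame)
            normalize_intensity(main_cal, ref_cal, baseline, cal)
            scales.append(cal.intensity_scale)
        assert np.mean(scales) == pytest.approx(1.25, abs=0.0125)

    def test_nonpositive_reference_area_raises(self, config, calibrate_frame, noiseless_frame):
        main_cal, ref_cal, cal = calibrate_frame(noiseless_frame)
        flat = ref_cal.copy(intensities=np.zeros_like(ref_cal.y))
        with pytest.raises(ValueError):
            normalize_intensity(main_cal, flat, 100.0, cal)


class TestResponseCurve:
    def _lamp_on_band(self, response=None):
        lam = np.arange(800.0, 960.0, 0.25)
        planck = planck_radiance(3000.0, lam)
        measured = planck if response is None else planck * response(lam)
        axis = SpectralAxis(AxisKind.WAVELENGTH_NM, lam)
        return Spectrum(axis, measured)

    def test_flat_instrument_gives_flat_response(self):
        lamp = self._lamp_on_band()
        curve = build_response_curve(lamp)
        assert np.ptp(curve.response) < 1e-9
        flattened = apply_response(lamp, curve)
        # dividing the lamp spectrum by the recovered response reproduces Planck
        np.testing.assert_allclose(flattened.y, lamp.y, rtol=1e-9)

    def test_synthetic_linear_response_recovered(self):
        resp = lambda lam: 1.0 - 0.5 * (lam - 800.0) / 160.0
        lamp = self._lamp_on_band(resp)
        curve = build_response_curve(lamp)
        expected = resp(curve.wavelength_nm)
        expected = expected / expected.max()
        np.testing.assert_allclose(curve.response, expected, rtol=0.01)

    def test_apply_then_undo_is_identity(self):
        resp = lambda lam: 1.0 - 0.4 * (lam - 800.0) / 160.0
        lamp = self._lamp_on_band(resp)
        curve = build_response_curve(lamp)
        grid = default_shift_grid(400, 2300)
        spec = Spectrum(grid, 1.0 + np.hanning(len(grid)))
        corrected = apply_response(spec, curve, laser_nm=785.0)
        back = apply_response(corrected, curve, laser_nm=785.0, undo=True)
        np.testing.assert_allclose(back.y, spec.y, rtol=1e-9)

    def test_nonpositive_lamp_rejected(self):
        lam = np.arange(800.0, 960.0, 1.0)
        axis = SpectralAxis(AxisKind.WAVELENGTH_NM, lam)
        with pytest.raises(ValueError):
            build_response_curve(Spectrum(axis, np.zeros(lam.size)))


@pytest.fixture(scope="module")
def qe_instrument():
    config = rf.default_config(sensor=rf.SensorModel(qe_sigma=0.003))
    qe_map = rf.make_qe_map(config.sensor, seed=13)
    return config, qe_map


class TestDriftAverage:
    def _qe_sequence(self, config, n_align, qe_map, drift_per_frame_nm=0.08):
        """Calibrated smooth-fluorescence spectra at n distinct pixel alignments."""
        lam_cols = config.optics.wavelength_of_column(np.arange(config.sensor.cols))
        fluo = Spectrum(
            SpectralAxis(AxisKind.WAVELENGTH_NM, lam_cols),
            500.0 * np.exp(-(((lam_cols - 865.0) / 55.0) ** 2)),
        )
        grid = default_shift_grid(600, 2000)
        spectra, cals, truths = [], [], []
        for m in range(n_align):
            state = rf.LaserState.single(785.0 + m * drift_per_frame_nm)
            frame = rf.render_frame(config, state, None, fluorescence=fluo,
                                    qe_map=qe_map, add_noise=False)
            truth_frame = rf.render_frame(config, state, None, fluorescence=fluo,
                                          qe_map=np.ones_like(qe_map), add_noise=False)
            ref = rf.extract_channel(frame, config.optics.reference_rows, "reference")
            main = rf.extract_channel(frame, config.optics.main_rows, "main")
            fits = fit_reference_peaks(ref, config.reference_lines, config.optics, 785.0)
            cal = estimate_laser_wavenumber(fits, config.optics)
            spectra.append(rf.calibrate_shift_axis(main, cal, config.optics, grid=grid))
            truth_main = rf.extract_channel(truth_frame, config.optics.main_rows, "main")
            truths.append(rf.calibrate_shift_axis(truth_main, cal, config.optics, grid=grid))
            cals.append(cal)
        return spectra, cals, truths

    def test_no_drift_keeps_qe_noise(self, qe_instrument):
        # negative control: without drift the same pixels are averaged and the
        # QE pattern is not reduced
        config, qe_map = qe_instrument
        spectra, cals, _ = self._qe_sequence(config, 4, qe_map, drift_per_frame_nm=0.0)
        with pytest.warns(UserWarning, match="ineffective"):
            mean, report = drift_average(spectra, cals, noise_window=(700, 1900))
        assert report["reduction_factor"] == pytest.approx(1.0, abs=0.05)

    def test_sqrt_m_reduction_against_truth(self, qe_instrument):
        # pointwise QE-noise std vs the QE-free truth drops ~ 1/sqrt(M) for
        # M distinct pixel alignments (independent gains per alignment)
        config, qe_map = qe_instrument
        M = 10
        spectra, cals, truths = self._qe_sequence(config, M, qe_map)
        sel = (spectra[0].x > 700) & (spectra[0].x < 1900)
        before = np.mean([
            np.std((s.y - t.y)[sel] / t.y[sel]) for s, t in zip(spectra, truths)
        ])
        mean, _ = drift_average(spectra, cals)
        truth_mean = np.mean([t.y for t in truths], axis=0)
        after = np.std((mean.y - truth_mean)[sel] / truth_mean[sel])
        assert before / after == pytest.approx(np.sqrt(M), rel=0.25)

    def test_monotone_improvement_with_alignments(self, qe_instrument):
        config, qe_map = qe_instrument
        reductions = []
        for M in (2, 10):
            spectra, cals, _ = self._qe_sequence(config, M, qe_map)
            _, report = drift_average(spectra, cals, noise_window=(700, 1900))
            reductions.append(report["reduction_factor"])
        assert reductions[1] > reductions[0] > 1.0

    def test_requires_two_spectra(self, qe_instrument):
        config, qe_map = qe_instrument
        spectra, cals, _ = self._qe_sequence(config, 2, qe_map)
        with pytest.raises(ValueError):
            drift_average(spectra[:1])

    def test_highfreq_noise_metric(self):
        grid = default_shift_grid(400, 1000)
        rng = np.random.default_rng(5)
        smooth = np.polyval([1e-6, -0.01, 30], grid.values)
        noisy = smooth * (1 + 0.003 * rng.standard_normal(len(grid)))
        est = highfreq_noise(Spectrum(grid, noisy))
        assert est == pytest.approx(np.std(noisy - smooth), rel=0.3)
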