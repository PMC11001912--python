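"""Mode-hop kernel estimation, Richardson-Lucy deconvolution, apparatus
function measurement, deblurring and resolution accounting."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

import reframan as rf
from reframan.decon import (
    ApparatusFunction,
    BroadeningKernel,
    KernelUnreliableError,
    deblur,
    deconvolve_with_kernel,
    estimate_apparatus_function,
    estimate_hop_kernel,
    fit_line_fwhm,
    fwhm_of_profile,
    resolution_from_fwhm,
    richardson_lucy,
)
from reframan.spectral_core import (
    Line,
    LineList,
    PeakShape,
    SpectralAxis,
    Spectrum,
    default_shift_grid,
    load_line_list,
    synthesize_spectrum,
)


@pytest.fixture(scope="module")
def clean_reference(config):
    """Noise-free reference band on the pixel axis."""
    counts = rf.expected_band(config, rf.LaserState.single(785.0), "reference")
    return Spectrum(SpectralAxis.pixel(counts.size), counts, {"channel": "reference"})


class TestHopKernel:
    def test_identity_kernel_for_identical_spectra(self, clean_reference):
        k = estimate_hop_kernel(clean_reference, clean_reference)
        assert k.dominant_offset == 0
        assert k.weights[np.argmax(k.weights)] > 0.95

    def test_recovers_exact_integer_hop(self, clean_reference):
        # construct the blurred reference directly with a 2-spike kernel so the
        # true offsets are exact integers
        c = clean_reference.y
        blurred = 0.7 * c + 0.3 * np.roll(c, 3)
        obs = Spectrum(clean_reference.axis, blurred)
        k = estimate_hop_kernel(obs, clean_reference)
        w = dict(zip(k.offsets.tolist(), k.weights.tolist()))
        assert w.get(0, 0.0) == pytest.approx(0.7, abs=0.05)
        assert w.get(3, 0.0) == pytest.approx(0.3, abs=0.05)
        # nothing substantial anywhere else
        other = sum(v for o, v in w.items() if o not in (0, 3))
        assert other < 0.05

    def test_pure_noise_raises(self, clean_reference):
        rng = np.random.default_rng(0)
        noise = Spectrum(clean_reference.axis, np.abs(rng.normal(0, 30, clean_reference.y.size)))
        with pytest.raises(KernelUnreliableError):
            estimate_hop_kernel(noise, clean_reference)

    def test_kernel_invariants(self):
        k = BroadeningKernel(np.array([-1, 0, 2]), np.array([0.2, 0.5, 0.3]))
        assert k.weights.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            BroadeningKernel(np.arange(20), np.ones(20))
        with pytest.raises(ValueError):
            BroadeningKernel(np.array([0]), np.array([-1.0]))


class TestRichardsonLucy:
    def test_delta_kernel_is_identity(self, clean_reference):
        out = deconvolve_with_kernel(clean_reference, BroadeningKernel.delta())
        np.testing.assert_allclose(out.y, clean_reference.y, rtol=1e-12)

    def test_flux_conserved(self, clean_reference):
        c = clean_reference.y
        obs = Spectrum(clean_reference.axis, 0.6 * c + 0.4 * np.roll(c, 2))
        k = estimate_hop_kernel(obs, clean_reference)
        out = deconvolve_with_kernel(obs, k, iterations=50)
        assert out.y.sum() == pytest.approx(obs.y.sum(), rel=1e-3)
        assert np.all(out.y >= 0)

    def test_hop_blur_restored(self, config, polypropylene):
        # blurred polypropylene recovers the hop-free peak shape
        optics = config.optics
        lam0 = 785.0
        disp = optics.dispersion_nm_per_col(1000)
        state_hop = rf.LaserState(((lam0, 0.7), (lam0 + 3 * disp, 0.3)))
        state_1 = rf.LaserState.single(lam0)
        main_hop = Spectrum(
            SpectralAxis.pixel(config.sensor.cols),
            rf.expected_band(config, state_hop, "main", polypropylene),
        )
        main_clean = rf.expected_band(config, state_1, "main", polypropylene)
        ref_obs = Spectrum(
            SpectralAxis.pixel(config.sensor.cols),
            rf.expected_band(config, state_hop, "reference"),
        )
        clean_ref = Spectrum(
            SpectralAxis.pixel(config.sensor.cols),
            rf.expected_band(config, state_1, "reference"),
        )
        k = estimate_hop_kernel(ref_obs, clean_ref)
        restored = deconvolve_with_kernel(main_hop, k, iterations=60)
        i = int(np.argmax(main_clean))
        window = slice(i - 15, i + 16)
        x = np.arange(config.sensor.cols, dtype=float)
        fw_clean = fwhm_of_profile(x[window], main_clean[window])
        fw_restored = fwhm_of_profile(x[window], restored.y[window])
        assert fw_restored == pytest.approx(fw_clean, rel=0.10)
        assert restored.y[window].max() == pytest.approx(main_clean[window].max(), rel=0.05)

    def test_nonnegative_output_on_noisy_input(self):
        rng = np.random.default_rng(1)
        data = np.clip(rng.normal(10, 5, 256), 0, None)
        kern = np.array([0.25, 0.5, 0.25])
        out = richardson_lucy(data, kern, center=1, iterations=20)
        assert np.all(out >= 0)


class TestApparatusFunction:
    def _blurred_diamond(self, gauss_fwhm, noise=0.0, seed=0, step=0.5):
        grid = default_shift_grid(1130, 1530, step=step)
        shape = PeakShape("voigt", gauss_fwhm=gauss_fwhm, lorentz_fwhm=1.8)
        spec = synthesize_spectrum(LineList("d", (Line(1332.5, 100.0, shape),)), grid)
        y = spec.y
        if noise > 0:
            y = y + noise * y.max() * np.random.default_rng(seed).standard_normal(y.size)
        return Spectrum(grid, y)

    def test_recovers_gaussian_apparatus_width(self):
        app = estimate_apparatus_function(self._blurred_diamond(6.0))
        assert app.fwhm_cm1 == pytest.approx(6.0, abs=0.2)

    def test_pure_natural_line_gives_near_delta(self):
        app = estimate_apparatus_function(self._blurred_diamond(1e-6))
        assert app.fwhm_cm1 <= 2 * app.step

    def test_stable_under_noise(self):
        fwhms = [
            estimate_apparatus_function(self._blurred_diamond(6.0, noise=0.01, seed=s)).fwhm_cm1
            for s in range(50)
        ]
        assert np.std(fwhms) / np.mean(fwhms) < 0.05
        assert np.mean(fwhms) == pytest.approx(6.0, rel=0.05)

    def test_no_line_raises(self):
        grid = default_shift_grid(1130, 1530)
        with pytest.raises(ValueError):
            estimate_apparatus_function(Spectrum(grid, np.zeros(len(grid))))

    def test_unit_area_and_nonnegative(self):
        app = estimate_apparatus_function(self._blurred_diamond(5.0))
        assert np.all(app.profile >= 0)
        assert app.profile.sum() * app.step == pytest.approx(1.0, rel=1e-6)


class TestDeblur:
    def _gaussian_apparatus(self, fwhm, step=0.5):
        x = np.arange(-4 * fwhm, 4 * fwhm + step / 2, step)
        prof = PeakShape.from_fwhm(fwhm, "gaussian").profile(x, 0.0)
        return ApparatusFunction(x, prof, fwhm)

    def test_narrow_line_sharpened_below_7(self):
        # 10 cm^-1 apparatus blur on a 1.8 cm^-1 line, high SNR: deblurring
        # restores resolution to better than 7 cm^-1
        grid = default_shift_grid(1130, 1530)
        blurred_shape = PeakShape("voigt", gauss_fwhm=10.0, lorentz_fwhm=1.8)
        spec = synthesize_spectrum(LineList("d", (Line(1332.5, 100.0, blurred_shape),)), grid)
        rng = np.random.default_rng(2)
        noisy = Spectrum(grid, spec.y + spec.y.max() / 300.0 * rng.standard_normal(spec.y.size))
        out = deblur(noisy, self._gaussian_apparatus(10.0), iterations=200)
        fwhm, report = fit_line_fwhm(out, 1332.5)
        assert report["success"]
        assert fwhm <= 7.0

    def test_delta_apparatus_is_identity(self):
        grid = default_shift_grid(1200, 1400)
        spec = synthesize_spectrum(load_line_list("diamond"), grid)
        x = np.arange(-5.0, 5.01, 0.5)
        delta = np.zeros(x.size)
        delta[x.size // 2] = 1.0
        out = deblur(spec, ApparatusFunction(x, delta, 0.5))
        np.testing.assert_allclose(out.y, spec.y, rtol=1e-6, atol=1e-9 * spec.y.max())

    def test_unresolved_doublet_resolved(self):
        grid = default_shift_grid(900, 1100)
        shape = PeakShape("voigt", gauss_fwhm=8.0, lorentz_fwhm=2.0)
        doublet = LineList("pair", (Line(996.0, 50.0, shape), Line(1004.0, 50.0, shape)))
        spec = synthesize_spectrum(doublet, grid)
        mid = np.argmin(np.abs(grid.values - 1000.0))
        # unresolved before: no local minimum between the lines
        assert spec.y[mid] > 0.9 * spec.y.max()
        out = deblur(spec, self._gaussian_apparatus(8.0), iterations=300)
        i_l = np.argmin(np.abs(grid.values - 996.0))
        i_r = np.argmin(np.abs(grid.values - 1004.0))
        assert out.y[mid] < 0.8 * min(out.y[i_l], out.y[i_r])

    def test_flux_conserved(self):
        grid = default_shift_grid(1130, 1530)
        spec = synthesize_spectrum(load_line_list("diamond").scaled(1000.0), grid)
        out = deblur(spec, self._gaussian_apparatus(6.0), iterations=100)
        assert out.y.sum() == pytest.approx(spec.y.sum(), rel=1e-3)


class TestVoigtFit:
    def test_recovers_both_widths(self):
        grid = default_shift_grid(900, 1100, step=0.25)
        shape = PeakShape("voigt", gauss_fwhm=4.0, lorentz_fwhm=3.0)
        spec = synthesize_spectrum(LineList("v", (Line(1000.0, 10.0, shape),)), grid)
        fwhm, report = fit_line_fwhm(spec, 1000.0)
        assert report["gauss_fwhm"] == pytest.approx(4.0, rel=0.02)
        assert report["lorentz_fwhm"] == pytest.approx(3.0, rel=0.02)
        assert fwhm == pytest.approx(shape.fwhm, rel=0.02)

    def test_resolution_quadrature(self):
        # printed pair: 7.4 cm^-1 measured Voigt width -> 6.6 cm^-1 resolution
        assert resolution_from_fwhm(7.4, 3.35) == pytest.approx(6.6, abs=0.05)
        assert resolution_from_fwhm(5.0, 0.0) == 5.0
        with pytest.raises(ValueError):
            resolution_from_fwhm(3.0, 4.0)


class TestConvolutionOracle:
    def test_fft_equals_direct_summation(self):
        rng = np.random.default_rng(3)
        a = rng.random(256)
        b = rng.random(31)
        direct = np.convolve(a, b, mode="same")
        viafft = fftconvolve(a, b, mode="same")
        np.testing.assert_allclose(direct, viafft, atol=1e-9)
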