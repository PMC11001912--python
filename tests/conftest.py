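"""Shared fixtures: a standard simulated instrument and helper factories."""

import warnings

import numpy as np
import pytest

import reframan as rf
from reframan.spectral_core import Spectrum, default_shift_grid, synthesize_spectrum


@pytest.fixture(scope="session")
def config():
    """Standard instrument: 785 nm laser, 64x2000 sensor, polystyrene reference."""
    return rf.default_config()


@pytest.fixture(scope="session")
def polypropylene():
    pp = rf.load_line_list("polypropylene")
    return pp.scaled(2e5 / sum(l.rel_intensity for l in pp.lines))


@pytest.fixture(scope="session")
def polystyrene_sample(config):
    """Polystyrene scaled for use as a main-channel sample."""
    ps = config.reference_lines
    return ps.scaled(2e5 / sum(l.rel_intensity for l in ps.lines))


@pytest.fixture(scope="session")
def noiseless_frame(config, polypropylene):
    state = rf.LaserState.single(785.0)
    return rf.render_frame(config, state, polypropylene, add_noise=False)


@pytest.fixture
def calibrate_frame(config):
    """Extract + calibrate one frame; returns (main_calibrated, ref_calibrated, cal)."""

    def _run(frame, grid=None):
        ref = rf.extract_channel(frame, config.optics.reference_rows, "reference")
        main = rf.extract_channel(frame, config.optics.main_rows, "main")
        fits = rf.fit_reference_peaks(ref, config.reference_lines, config.optics, 785.0)
        cal = rf.estimate_laser_wavenumber(fits, config.optics)
        main_cal = rf.calibrate_shift_axis(main, cal, config.optics, grid=grid)
        ref_cal = rf.calibrate_shift_axis(ref, cal, config.optics)
        return main_cal, ref_cal, cal

    return _run


@pytest.fixture(autouse=True)
def _quiet_line_warnings():
    """Line-outside-axis warnings are expected noise in band-limited tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*outside axis span.*")
        yield


def make_serds_inputs(n_acq=5, span_cm1=4.0, fluo_scale=5.0, noise=0.0, seed=0):
    """Synthetic shifted-excitation sequence: static Raman + moving fluorescence."""
    grid = default_shift_grid(400, 1800)
    pp = rf.load_line_list("polypropylene")
    raman = synthesize_spectrum(pp, grid).y * 10
    amp = raman.max()
    x = grid.values
    offsets = np.linspace(0.0, span_cm1, n_acq)
    rng = np.random.default_rng(seed)
    spectra = []
    for d in offsets:
        u = (x - d - 400.0) / 1400.0
        fluo = fluo_scale * amp * (0.5 + u - 0.3 * u**2 - 0.4 * u**3 + 0.2 * u**4)
        y = raman + fluo
        if noise > 0:
            y = y + noise * amp * rng.standard_normal(x.size)
        spectra.append(Spectrum(grid, y))
    return spectra, offsets, raman, grid
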