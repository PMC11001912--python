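"""Synthetic dual-channel CMOS frame renderer.

Emulates the physics that the downstream processing chain has to undo: laser
thermal wavelength drift with an exponential warm-up, discrete Fabry-Perot
mode hops (multi-component emission inside one exposure), relative power
fluctuation (AR(1)), slit/pixel apparatus blur, wavelength-dependent sensor
QE, static per-pixel QE gain variation, dark/read and shot noise, hot pixels,
and in-focus plus spatially offset fluorescence bands.

Each rendered :class:`SensorFrame` carries a truth sidecar (laser state, seed,
exposure, config hash) so every estimator can be tested against ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .spectral_core import (
    LineList,
    PeakShape,
    Spectrum,
    SpectralAxis,
    AxisKind,
    load_line_list,
    shift_to_wavelength,
)

__all__ = [
    "LaserModel",
    "LaserState",
    "SensorModel",
    "OpticsModel",
    "InstrumentConfig",
    "SensorFrame",
    "simulate_laser_sequence",
    "render_frame",
    "expected_band",
    "make_qe_map",
    "default_config",
]


@dataclass(frozen=True)
class LaserModel:
    """Non-stabilized Fabry-Perot diode laser.

    Defaults follow the fingerprint-range source: 785 nm center, 0.2 nm
    linewidth, 200 mW maximum power. Warm-up drift approaches
    ``drift_total_nm`` with time constant ``drift_tau_s``; mode hops move the
    emission by +-``hop_spacing_nm`` with ``hop_probability`` per frame;
    relative power follows a stationary AR(1) around 1 with std
    ``power_rel_std`` and lag-1 correlation ``power_corr``.
    """

    nominal_nm: float = 785.0
    linewidth_fwhm_nm: float = 0.2
    max_power_mw: float = 200.0
    drift_total_nm: float = 0.3
    drift_tau_s: float = 60.0
    hop_spacing_nm: float = 0.1
    hop_probability: float = 0.0
    power_rel_std: float = 0.0
    power_corr: float = 0.9

    def __post_init__(self):
        if self.nominal_nm <= 0 or self.linewidth_fwhm_nm <= 0 or self.max_power_mw <= 0:
            raise ValueError("laser wavelength/linewidth/power must be positive")
        if not 0.0 <= self.hop_probability <= 1.0:
            raise ValueError("hop probability must lie in [0, 1]")
        if self.power_rel_std < 0:
            raise ValueError("power std must be >= 0")


@dataclass(frozen=True)
class LaserState:
    """Emission within one exposure: (wavelength nm, weight) components.

    A mode hop inside the exposure yields more than one component; weights are
    exposure-time fractions and sum to 1.
    """

    components: tuple
    relative_power: float = 1.0

    def __post_init__(self):
        comps = tuple((float(w_nm), float(w)) for w_nm, w in self.components)
        if not comps:
            raise ValueError("laser state needs at least one component")
        total = sum(w for _, w in comps)
        if any(w < 0 for _, w in comps) or total <= 0:
            raise ValueError("component weights must be >= 0 with positive sum")
        comps = tuple((w_nm, w / total) for w_nm, w in comps)
        object.__setattr__(self, "components", comps)

    @property
    def wavelength_nm(self) -> float:
        """Weight-averaged emission wavelength."""
        return sum(w_nm * w for w_nm, w in self.components)

    @classmethod
    def single(cls, wavelength_nm: float, relative_power: float = 1.0) -> "LaserState":
        return cls(((wavelength_nm, 1.0),), relative_power)


@dataclass(frozen=True)
class SensorModel:
    """Non-cooled NIR CMOS sensor.

    ``dark_noise_std`` is the Gaussian dark+read noise std per pixel for a 1 s
    exposure; it scales with sqrt(exposure) (dark-current shot noise). The QE
    curve is piecewise linear through (840 nm, 0.60) and (940 nm, 0.40) and is
    linearly extrapolated outside the anchors. ``qe_sigma`` is the static
    per-pixel multiplicative gain variation (0.1-0.5% is typical).
    """

    rows: int = 64
    cols: int = 2000
    pixel_pitch_um: float = 4.0
    dark_noise_std: float = 12.0
    saturation: int = 65535
    hot_pixel_fraction: float = 0.0
    qe_sigma: float = 0.0
    qe_anchors: tuple = ((840.0, 0.60), (940.0, 0.40))

    def __post_init__(self):
        if not 0.0 <= self.qe_sigma <= 0.01:
            raise ValueError("qe_sigma must lie in [0, 0.01]")
        if self.dark_noise_std < 0:
            raise ValueError("dark noise std must be >= 0")

    def qe(self, wavelength_nm) -> np.ndarray | float:
        lam = np.asarray(wavelength_nm, dtype=float)
        xs = np.array([a[0] for a in self.qe_anchors])
        ys = np.array([a[1] for a in self.qe_anchors])
        slope_lo = (ys[1] - ys[0]) / (xs[1] - xs[0])
        slope_hi = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.interp(lam, xs, ys)
        out = np.where(lam < xs[0], ys[0] + slope_lo * (lam - xs[0]), out)
        out = np.where(lam > xs[-1], ys[-1] + slope_hi * (lam - xs[-1]), out)
        out = np.clip(out, 1e-6, 1.0)
        return float(out) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class OpticsModel:
    """Dispersion map, apparatus blur and band geometry on the sensor.

    ``wavelength_coeffs`` (a, b, c) give lambda(col) = a + b*col + c*col^2 nm,
    spanning ~800-960 nm over 2000 columns by default. The apparatus function
    is the 5.4 um slit image convolved with the 4 um pixel aperture. Row
    windows are half-open [start, stop) and must be disjoint.
    """

    wavelength_coeffs: tuple = (800.0, 0.08, 1e-7)
    slit_image_um: float = 5.4
    pixel_um: float = 4.0
    throughput: float = 0.92
    reference_rows: tuple = (8, 13)
    main_rows: tuple = (40, 45)
    offset_rows: tuple = (50, 61)

    def __post_init__(self):
        windows = sorted([self.reference_rows, self.main_rows, self.offset_rows])
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError("band row windows must be disjoint")

    def wavelength_of_column(self, col) -> np.ndarray | float:
        a, b, c = self.wavelength_coeffs
        col = np.asarray(col, dtype=float)
        out = a + b * col + c * col**2
        return float(out) if out.ndim == 0 else out

    def column_of_wavelength(self, wavelength_nm, n_cols: int = 4000):
        """Invert the (monotone) dispersion polynomial by interpolation."""
        grid = np.linspace(0.0, float(n_cols), 8 * n_cols)
        lam = self.wavelength_of_column(grid)
        out = np.interp(np.asarray(wavelength_nm, dtype=float), lam, grid)
        return float(out) if np.isscalar(wavelength_nm) else out

    def dispersion_nm_per_col(self, col) -> np.ndarray | float:
        a, b, c = self.wavelength_coeffs
        col = np.asarray(col, dtype=float)
        out = b + 2.0 * c * col
        return float(out) if out.ndim == 0 else out

    def apparatus_kernel(self, oversample: int = 41) -> np.ndarray:
        """Unit-sum blur kernel in pixel units: slit-image box (x) pixel box."""
        half = 4
        centers = np.arange(-half, half + 1, dtype=float)
        sub = (np.arange(oversample) + 0.5) / oversample - 0.5
        w_slit = self.slit_image_um / self.pixel_um
        kernel = np.zeros_like(centers)
        # integrate the slit-image box over each pixel aperture
        for i, c in enumerate(centers):
            x = c + sub
            kernel[i] = np.mean(np.abs(x) <= w_slit / 2.0)
        total = kernel.sum()
        if total <= 0:
            kernel[half] = 1.0
            total = 1.0
        return kernel / total


def _band_span_ok(laser_nm: float, lo_cm1: float, hi_cm1: float, optics: OpticsModel, cols: int) -> bool:
    lam = shift_to_wavelength(laser_nm, np.array([lo_cm1, hi_cm1]))
    lam_lo = optics.wavelength_of_column(0)
    lam_hi = optics.wavelength_of_column(cols - 1)
    return bool(lam[0] >= lam_lo - 1e-9 and lam[1] <= lam_hi + 1e-9)


@dataclass(frozen=True)
class InstrumentConfig:
    """Full instrument parameterization: lasers, sensor, optics, reference.

    The fingerprint laser (785 nm) covers 400-2300 cm^-1 inside the 800-960 nm
    sensor band; the high-frequency laser (675 nm) covers 2700-4000 cm^-1 on
    the same sensor. The built-in polystyrene reference is rendered into the
    reference band of every frame with total area ``reference_amplitude``
    (expected counts per second at nominal power).
    """

    laser: LaserModel = field(default_factory=LaserModel)
    laser_hf: LaserModel = field(default_factory=lambda: LaserModel(nominal_nm=675.0))
    sensor: SensorModel = field(default_factory=SensorModel)
    optics: OpticsModel = field(default_factory=OpticsModel)
    reference_lines: LineList | None = None
    reference_amplitude: float = 2e5

    def __post_init__(self):
        if self.reference_lines is None:
            object.__setattr__(self, "reference_lines", load_line_list("polystyrene"))

    def check_band_coverage(self) -> None:
        """Verify the printed shift ranges land inside the sensor band."""
        if not _band_span_ok(self.laser.nominal_nm, 400.0, 2300.0, self.optics, self.sensor.cols):
            raise ValueError("fingerprint range 400-2300 cm^-1 falls outside the sensor band")
        if not _band_span_ok(self.laser_hf.nominal_nm, 2700.0, 4000.0, self.optics, self.sensor.cols):
            raise ValueError("high-frequency range 2700-4000 cm^-1 falls outside the sensor band")

    def hash(self) -> str:
        payload = json.dumps(
            {
                "laser": asdict(self.laser),
                "laser_hf": asdict(self.laser_hf),
                "sensor": asdict(self.sensor),
                "optics": asdict(self.optics),
                "reference_amplitude": self.reference_amplitude,
                "reference_material": self.reference_lines.material,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SensorFrame:
    """2-D count image plus simulation truth sidecar.

    ``counts`` are clipped to [0, saturation]; they are integer-valued when
    noise was simulated and kept at float precision for noiseless renders.
    """

    counts: np.ndarray
    sidecar: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("frame must be 2-D")
        if self.counts.min() < 0 or self.counts.max() > 65535:
            raise ValueError("counts must lie in [0, 65535]")


def default_config(**overrides) -> InstrumentConfig:
    """The standard simulated instrument used throughout tests and examples."""
    cfg = InstrumentConfig(**overrides)
    cfg.check_band_coverage()
    return cfg


def simulate_laser_sequence(
    model: LaserModel,
    n_frames: int,
    frame_period_s: float = 1.0,
    seed: int | np.random.Generator = 0,
    start_time_s: float = 0.0,
) -> list[LaserState]:
    """Laser states over a warm-up: drift + accumulated mode hops + AR(1) power.

    Wavelength follows ``nominal + drift_total*(1 - exp(-t/tau))`` plus the
    accumulated hop offset. A frame in which a hop fires gets a two-component
    state (pre/post-hop wavelengths with a random time split); at most 3
    components per exposure. Identical seeds give identical sequences.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = []
    hop_offset = 0.0
    power_dev = 0.0
    if model.power_rel_std > 0:
        power_dev = model.power_rel_std * rng.standard_normal()
    rho = model.power_corr
    for i in range(n_frames):
        t = start_time_s + i * frame_period_s
        drift = model.drift_total_nm * (1.0 - np.exp(-t / model.drift_tau_s)) if model.drift_tau_s > 0 else model.drift_total_nm
        base = model.nominal_nm + drift + hop_offset
        comps = [(base, 1.0)]
        n_hops = 0
        while n_hops < 2 and rng.random() < model.hop_probability:
            hop_offset += model.hop_spacing_nm * rng.choice([-1.0, 1.0])
            split = rng.uniform(0.2, 0.8)
            comps = [(w_nm, w * split) for w_nm, w in comps]
            comps.append((model.nominal_nm + drift + hop_offset, 1.0 - split))
            n_hops += 1
        if model.power_rel_std > 0 and i > 0:
            power_dev = rho * power_dev + model.power_rel_std * np.sqrt(1 - rho**2) * rng.standard_normal()
        states.append(LaserState(tuple(comps), 1.0 + power_dev))
    return states


def make_qe_map(sensor: SensorModel, qe_sigma: float | None = None, seed: int = 0) -> np.ndarray:
    """Static per-pixel multiplicative gain map, i.i.d. Normal(1, sigma).

    The map is fixed per instrument instance: pixel-to-pixel QE variation
    cannot be averaged out in time, only across pixels via laser drift.
    """
    sigma = sensor.qe_sigma if qe_sigma is None else qe_sigma
    if not 0.0 <= sigma <= 0.01:
        raise ValueError("qe_sigma must lie in [0, 0.01]")
    rng = np.random.default_rng(seed)
    if sigma == 0.0:
        return np.ones((sensor.rows, sensor.cols))
    return 1.0 + sigma * rng.standard_normal((sensor.rows, sensor.cols))


def _component_column_profile(
    config: InstrumentConfig,
    line_list: LineList,
    laser_nm: float,
    cols: np.ndarray,
) -> np.ndarray:
    """Expected per-column counts (unit area per unit line area) for one emission line set."""
    optics = config.optics
    sensor = config.sensor
    y = np.zeros(cols.size)
    lam_lo = optics.wavelength_of_column(cols[0])
    lam_hi = optics.wavelength_of_column(cols[-1])
    for line in line_list.lines:
        lam_c = shift_to_wavelength(laser_nm, line.center_cm1)
        if not (lam_lo <= lam_c <= lam_hi):
            continue
        col_c = optics.column_of_wavelength(lam_c, n_cols=sensor.cols)
        jac_nm = lam_c**2 / 1e7  # nm per cm^-1
        disp = optics.dispersion_nm_per_col(col_c)  # nm per column
        scale = jac_nm / disp  # columns per cm^-1
        shape = PeakShape(
            line.shape.family,
            line.shape.gauss_fwhm * scale,
            line.shape.lorentz_fwhm * scale,
        )
        y += line.rel_intensity * sensor.qe(lam_c) * shape.profile(cols, col_c)
    return y


def expected_band(
    config: InstrumentConfig,
    state: LaserState,
    band: str = "main",
    sample: LineList | None = None,
    fluorescence: Spectrum | None = None,
    exposure_s: float = 1.0,
) -> np.ndarray:
    """Noise-free expected counts per column (summed over the band rows).

    This is the simulator's own truth used as the oracle for extraction and
    calibration tests. ``fluorescence`` is a wavelength-axis spectrum of
    expected counts/s/column at nominal power; being fixed in absolute
    wavelength it does not move with the laser.
    """
    sensor, optics = config.sensor, config.optics
    cols = np.arange(sensor.cols, dtype=float)
    total = np.zeros(sensor.cols)
    if band == "reference":
        lines = config.reference_lines.scaled(
            config.reference_amplitude / sum(l.rel_intensity for l in config.reference_lines.lines)
        )
    elif band in ("main", "offset"):
        lines = sample
    else:
        raise ValueError(f"unknown band {band!r}")
    if lines is not None:
        for lam_nm, w in state.components:
            total += w * _component_column_profile(config, lines, lam_nm, cols)
        kernel = optics.apparatus_kernel()
        total = np.convolve(total, kernel, mode="same")
    if fluorescence is not None:
        if fluorescence.axis.kind != AxisKind.WAVELENGTH_NM:
            raise ValueError("fluorescence profile must be on a wavelength axis")
        lam_cols = optics.wavelength_of_column(cols)
        fl = np.interp(lam_cols, fluorescence.axis.values, fluorescence.intensities, left=0, right=0)
        total += fl * sensor.qe(lam_cols)
    return total * exposure_s * state.relative_power * optics.throughput


def render_frame(
    config: InstrumentConfig,
    state: LaserState,
    sample: LineList | None = None,
    exposure_s: float = 1.0,
    seed: int | np.random.Generator | None = None,
    fluorescence: Spectrum | None = None,
    offset_fluorescence: Spectrum | None = None,
    qe_map: np.ndarray | None = None,
    add_noise: bool = True,
) -> SensorFrame:
    """Render one dual-channel frame: reference + main (+ offset) bands.

    Pipeline per band: lines -> absolute wavelength (per emission component)
    -> columns via the dispersion map -> apparatus-function blur -> scaling by
    component weight, power, exposure, throughput and QE(lambda) -> deposit
    uniformly over the band's rows -> per-pixel QE gain -> Poisson shot noise
    + Gaussian dark noise -> hot pixels -> clip to 16 bits.
    """
    if exposure_s <= 0:
        raise ValueError("exposure must be positive")
    sensor, optics = config.sensor, config.optics
    frame = np.zeros((sensor.rows, sensor.cols))

    bands = {
        "reference": (optics.reference_rows, None, None),
        "main": (optics.main_rows, sample, fluorescence),
        "offset": (optics.offset_rows, None, offset_fluorescence),
    }
    any_signal = False
    for band, (rows, lines, fluo) in bands.items():
        if band != "reference" and lines is None and fluo is None:
            continue
        expected = expected_band(config, state, band, lines, fluo, exposure_s)
        if band == "main" and lines is not None and expected.max() <= 0:
            raise ValueError("sample invisible: no line falls inside the sensor band")
        n_rows = rows[1] - rows[0]
        frame[rows[0]:rows[1], :] += expected / n_rows
        any_signal = any_signal or expected.max() > 0
    if not any_signal:
        raise ValueError("nothing to render: no band receives signal")

    if qe_map is not None:
        frame = frame * qe_map
    elif sensor.qe_sigma > 0:
        raise ValueError("sensor.qe_sigma > 0 requires an explicit qe_map (static per instrument)")

    sidecar = {
        "laser_state": {
            "components": [list(c) for c in state.components],
            "relative_power": state.relative_power,
        },
        "exposure_s": exposure_s,
        "config_sha": config.hash(),
        "noise": bool(add_noise),
    }
    if not add_noise:
        return SensorFrame(np.clip(frame, 0, sensor.saturation), sidecar)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sidecar["seed"] = None if isinstance(seed, np.random.Generator) else seed
    noisy = rng.poisson(np.clip(frame, 0, None)).astype(float)
    noisy += sensor.dark_noise_std * np.sqrt(exposure_s) * rng.standard_normal(frame.shape)
    if sensor.hot_pixel_fraction > 0:
        n_hot = int(round(sensor.hot_pixel_fraction * frame.size))
        if n_hot > 0:
            idx = rng.choice(frame.size, size=n_hot, replace=False)
            noisy.flat[idx] = rng.uniform(0.3 * sensor.saturation, sensor.saturation, size=n_hot)
            sidecar["hot_pixels"] = int(n_hot)
    counts = np.clip(np.round(noisy), 0, sensor.saturation)
    return SensorFrame(counts, sidecar)
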