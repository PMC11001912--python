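"""Reference-channel calibration: per-acquisition wavenumber and intensity.

The instrument records the Raman spectrum of a built-in polystyrene sample in
a second band of every frame. Fitting its catalog lines pins the laser
wavenumber for that acquisition; the same correction is applied to the main
channel, making Raman-shift axes stable against laser drift and the
integrated reference-line area normalizes away laser power fluctuation.

Also here: QE drift-averaging (pixel-to-pixel gain noise averages out across
drift-shifted, recalibrated spectra) and the blackbody-lamp response
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import ConstantModel, PseudoVoigtModel
from scipy.signal import savgol_filter

from .spectral_core import (
    AxisKind,
    LineList,
    SpectralAxis,
    Spectrum,
    planck_radiance,
    resample_spectrum,
    shift_to_wavelength,
)
from .instrument_sim import OpticsModel

__all__ = [
    "CalibrationError",
    "PeakFit",
    "CalibrationResult",
    "ResponseCurve",
    "fit_reference_peaks",
    "estimate_laser_wavenumber",
    "calibrate_shift_axis",
    "reference_peak_area",
    "normalize_intensity",
    "build_response_curve",
    "apply_response",
    "drift_average",
    "highfreq_noise",
]


class CalibrationError(RuntimeError):
    """Raised when the reference channel cannot support a calibration."""


@dataclass(frozen=True)
class PeakFit:
    """Single reference-line fit in the (pixel-axis) reference spectrum."""

    line_cm1: float
    center_px: float
    center_nm: float
    amplitude: float
    area: float
    fwhm_px: float
    rmse: float
    success: bool


@dataclass
class CalibrationResult:
    """Laser wavenumber estimate and intensity scale for one acquisition."""

    laser_wavenumber_cm1: float
    residuals_cm1: np.ndarray
    n_peaks: int
    intensity_scale: float = 1.0
    acquisition_id: str | None = None
    peak_fits: list = field(default_factory=list)

    @property
    def laser_nm(self) -> float:
        return 1e7 / self.laser_wavenumber_cm1

    @property
    def residual_spread_cm1(self) -> float:
        return float(np.std(self.residuals_cm1)) if self.residuals_cm1.size else np.nan

    def to_dict(self) -> dict:
        return {
            "laser_wavenumber_cm1": self.laser_wavenumber_cm1,
            "laser_nm": self.laser_nm,
            "residuals_cm1": [float(r) for r in self.residuals_cm1],
            "n_peaks": self.n_peaks,
            "intensity_scale": self.intensity_scale,
            "acquisition_id": self.acquisition_id,
        }


@dataclass(frozen=True)
class ResponseCurve:
    """Relative spectral response (max-normalized, strictly positive)."""

    wavelength_nm: np.ndarray
    response: np.ndarray
    note: str = ""

    def __post_init__(self):
        resp = np.asarray(self.response, dtype=float)
        if np.any(resp <= 0):
            raise ValueError("response must be strictly positive")
        object.__setattr__(self, "response", resp / resp.max())
        object.__setattr__(self, "wavelength_nm", np.asarray(self.wavelength_nm, dtype=float))


def fit_reference_peaks(
    ref_spectrum: Spectrum,
    line_list: LineList,
    optics: OpticsModel,
    laser_nm_nominal: float,
    search_halfwidth_nm: float = 1.0,
    min_amplitude_frac: float = 0.02,
) -> list[PeakFit]:
    """Least-squares pseudo-Voigt fits of the catalog lines in pixel space.

    Each catalog line is fitted in a window around its predicted pixel (from
    the nominal laser wavelength, widened by the laser search half-width).
    Fits that fail to converge, run to the window edge, or have negligible
    amplitude are flagged unsuccessful.
    """
    if ref_spectrum.axis.kind != AxisKind.PIXEL:
        raise ValueError("reference spectrum must be on a pixel axis")
    x, y = ref_spectrum.x, ref_spectrum.y
    n = x.size
    y_span = float(y.max() - y.min())
    if y_span <= 0:
        raise CalibrationError("reference spectrum is flat: no peaks to fit")
    fits: list[PeakFit] = []
    model = PseudoVoigtModel(prefix="p_") + ConstantModel(prefix="c_")
    for line in line_list.lines:
        lam_pred = shift_to_wavelength(laser_nm_nominal, line.center_cm1)
        col_pred = optics.column_of_wavelength(lam_pred, n_cols=n)
        disp = optics.dispersion_nm_per_col(col_pred)
        jac_nm = lam_pred**2 / 1e7
        width_px = max(line.fwhm_cm1 * jac_nm / disp, 1.5)
        half = int(np.ceil(search_halfwidth_nm / disp + 3 * width_px))
        i0, i1 = int(round(col_pred)) - half, int(round(col_pred)) + half + 1
        if i0 < 0 or i1 > n:
            continue  # predicted position too close to the sensor edge
        xs, ys = x[i0:i1], y[i0:i1]
        # the laser can only move the line by the search half-width: bound the
        # center there so a stronger neighbor inside the window cannot steal it
        c_half = search_halfwidth_nm / disp + width_px
        c_lo, c_hi = col_pred - c_half, col_pred + c_half
        in_c = (xs >= c_lo) & (xs <= c_hi)
        i_max = int(np.flatnonzero(in_c)[np.argmax(ys[in_c])]) if in_c.any() else int(np.argmax(ys))
        amp0 = float(ys[i_max] - np.median(ys))
        params = model.make_params(
            p_center=float(xs[i_max]),
            p_sigma=max(width_px / 2.0, 0.7),
            p_amplitude=max(amp0 * width_px * 1.6, 1e-9),
            p_fraction=0.5,
            c_c=float(np.median(ys)),
        )
        params["p_center"].set(min=max(c_lo, xs[0]), max=min(c_hi, xs[-1]))
        params["p_sigma"].set(min=0.3, max=half)
        params["p_amplitude"].set(min=0.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(ys, params, x=xs)
        except Exception:
            fits.append(PeakFit(line.center_cm1, np.nan, np.nan, 0.0, 0.0, np.nan, np.inf, False))
            continue
        center = float(result.params["p_center"].value)
        amplitude = float(result.params["p_height"].value)
        area = float(result.params["p_amplitude"].value)
        fwhm = float(result.params["p_fwhm"].value)
        rmse = float(np.sqrt(np.mean(result.residual**2)))
        at_edge = center <= max(c_lo, xs[0]) + 0.5 or center >= min(c_hi, xs[-1]) - 0.5
        weak = y_span > 0 and amplitude < min_amplitude_frac * y_span
        success = bool(result.success) and not at_edge and not weak and fwhm > 0
        center_nm = float(optics.wavelength_of_column(center))
        fits.append(PeakFit(line.center_cm1, center, center_nm, amplitude, area, fwhm, rmse, success))
    if not any(f.success for f in fits):
        raise CalibrationError("no reference peak could be fitted")
    return fits


def estimate_laser_wavenumber(
    peak_fits: list[PeakFit],
    optics: OpticsModel,
    acquisition_id: str | None = None,
    max_spread_cm1: float = 5.0,
) -> CalibrationResult:
    """Laser wavenumber from fitted reference lines (median, one MAD pass).

    Per peak: nu_laser = 1e7/lambda_fit + known shift. The estimate is the
    median over usable peaks after a single >3xMAD outlier-rejection pass;
    at least 3 usable peaks are required and the post-rejection residual
    spread must stay below ``max_spread_cm1``.
    """
    good = [f for f in peak_fits if f.success]
    if len(good) < 3:
        raise CalibrationError(f"only {len(good)} reference peaks usable (need >= 3)")
    nu = np.array([1e7 / f.center_nm + f.line_cm1 for f in good])
    med = np.median(nu)
    mad = np.median(np.abs(nu - med))
    if mad > 0:
        keep = np.abs(nu - med) <= 3.0 * mad
        if np.count_nonzero(keep) >= 3:
            nu = nu[keep]
            good = [f for f, k in zip(good, keep) if k]
    estimate = float(np.median(nu))
    residuals = nu - estimate
    if np.std(residuals) > max_spread_cm1:
        raise CalibrationError(
            f"unstable calibration: residual spread {np.std(residuals):.2f} cm^-1"
        )
    return CalibrationResult(estimate, residuals, len(good), 1.0, acquisition_id, good)


def calibrate_shift_axis(
    main_spectrum: Spectrum,
    calibration: CalibrationResult,
    optics: OpticsModel,
    grid: SpectralAxis | None = None,
    grid_step: float = 0.5,
    as_density: bool = True,
) -> Spectrum:
    """Pixel axis -> calibrated Raman-shift axis, resampled to a uniform grid.

    shift(pixel) = nu_laser - 1e7/lambda(pixel). With ``as_density`` the
    counts-per-pixel are converted to counts per cm^-1 (division by the local
    dispersion) so that integrated line areas are preserved on the uniform
    grid. Default grid: ``grid_step`` (0.5 cm^-1) spacing over the covered span.
    """
    if main_spectrum.axis.kind != AxisKind.PIXEL:
        raise ValueError("expected a pixel-axis spectrum")
    px = main_spectrum.x
    lam = optics.wavelength_of_column(px)
    shift = calibration.laser_wavenumber_cm1 - 1e7 / lam
    y = main_spectrum.intensities
    if as_density:
        dnu_dpx = (1e7 / lam**2) * optics.dispersion_nm_per_col(px)
        y = y / dnu_dpx
    native = Spectrum(
        SpectralAxis(AxisKind.RAMAN_SHIFT_CM1, shift), y, dict(main_spectrum.meta)
    )
    if grid is None:
        lo = np.ceil(shift[0] / grid_step) * grid_step
        hi = np.floor(shift[-1] / grid_step) * grid_step
        grid = SpectralAxis(AxisKind.RAMAN_SHIFT_CM1, np.arange(lo, hi + grid_step / 2, grid_step))
    out = resample_spectrum(native, grid)
    out.meta["laser_wavenumber_cm1"] = calibration.laser_wavenumber_cm1
    return out


def reference_peak_area(
    ref_calibrated: Spectrum,
    line_cm1: float = 1001.4,
    half_width: float = 15.0,
    flank: float = 10.0,
) -> float:
    """Baseline-subtracted integrated area of one designated reference line.

    The baseline is a linear least-squares fit over the two ``flank`` regions
    just outside the integration window: averaging over wide flanks keeps the
    baseline noise well below the shot noise of the peak itself.
    """
    x, y = ref_calibrated.x, ref_calibrated.y
    in_win = (x >= line_cm1 - half_width) & (x <= line_cm1 + half_width)
    if np.count_nonzero(in_win) < 5:
        raise ValueError("reference line window outside axis")
    xs, ys = x[in_win], y[in_win]
    in_flank = (
        ((x >= line_cm1 - half_width - flank) & (x < line_cm1 - half_width))
        | ((x > line_cm1 + half_width) & (x <= line_cm1 + half_width + flank))
    )
    if np.count_nonzero(in_flank) >= 6:
        coef = np.polyfit(x[in_flank], y[in_flank], 1)
        baseline = np.polyval(coef, xs)
    else:  # window at the axis edge: fall back to window-edge medians
        idx = np.flatnonzero(in_win)
        edge = max(2, idx.size // 10)
        base_l, base_r = np.median(y[idx[:edge]]), np.median(y[idx[-edge:]])
        baseline = np.interp(xs, [x[idx[0]], x[idx[-1]]], [base_l, base_r])
    return float(np.trapezoid(ys - baseline, xs))


def normalize_intensity(
    main: Spectrum,
    ref: Spectrum,
    baseline_ref_area: float,
    calibration: CalibrationResult | None = None,
    line_cm1: float = 1001.4,
) -> Spectrum:
    """Scale the main channel by the reference-line area ratio.

    ``baseline_ref_area`` is the designated reference-line area at nominal
    power (e.g. from a warm-up acquisition); the acquisition's scale factor is
    ``baseline / observed`` and is recorded on the calibration result.
    """
    area = reference_peak_area(ref, line_cm1)
    if area <= 0:
        raise ValueError("reference line area must be positive")
    scale = baseline_ref_area / area
    if calibration is not None:
        calibration.intensity_scale = scale
    return main.copy(intensities=main.intensities * scale, intensity_scale=scale)


def build_response_curve(measured_lamp: Spectrum, temperature_K: float = 3000.0) -> ResponseCurve:
    """Instrument response from a blackbody (tungsten-halogen) lamp spectrum.

    response(lambda) = measured(lambda) / Planck(lambda, T), max-normalized.
    """
    if measured_lamp.axis.kind != AxisKind.WAVELENGTH_NM:
        raise ValueError("lamp spectrum must be on a wavelength axis")
    if np.any(measured_lamp.intensities <= 0):
        raise ValueError("lamp spectrum must be strictly positive over the band")
    planck = planck_radiance(temperature_K, measured_lamp.x)
    resp = measured_lamp.intensities / planck
    return ResponseCurve(measured_lamp.x.copy(), resp, f"blackbody {temperature_K:.0f} K")


def apply_response(
    spectrum: Spectrum,
    curve: ResponseCurve,
    laser_nm: float | None = None,
    undo: bool = False,
) -> Spectrum:
    """Divide (or re-multiply, ``undo=True``) the relative response out.

    Wavelength-axis spectra are corrected directly; Raman-shift spectra need
    ``laser_nm`` to map shift to absolute wavelength.
    """
    if spectrum.axis.kind == AxisKind.WAVELENGTH_NM:
        lam = spectrum.x
    elif spectrum.axis.kind == AxisKind.RAMAN_SHIFT_CM1:
        if laser_nm is None:
            raise ValueError("laser_nm required to correct a Raman-shift spectrum")
        lam = shift_to_wavelength(laser_nm, spectrum.x)
    else:
        raise ValueError("cannot apply a response to a pixel-axis spectrum")
    resp = np.interp(lam, curve.wavelength_nm, curve.response)
    resp = np.clip(resp, 1e-6, None)
    y = spectrum.intensities * resp if undo else spectrum.intensities / resp
    return spectrum.copy(intensities=y)


def highfreq_noise(
    spectrum: Spectrum,
    window: tuple[float, float] | None = None,
    savgol_window: int = 11,
    savgol_order: int = 3,
) -> float:
    """High-frequency (QE-like) noise: std of (y - Savitzky-Golay smooth).

    Evaluate in a peak-free window so genuine narrow Raman lines do not count
    as noise.
    """
    x, y = spectrum.x, spectrum.y
    if window is not None:
        sel = (x >= window[0]) & (x <= window[1])
        x, y = x[sel], y[sel]
    if y.size <= savgol_window:
        raise ValueError("too few points for the smoothing window")
    smooth = savgol_filter(y, savgol_window, savgol_order)
    return float(np.std(y - smooth))


def drift_average(
    spectra: list[Spectrum],
    calibrations: list[CalibrationResult] | None = None,
    noise_window: tuple[float, float] | None = None,
    min_drift_cm1: float = 0.5,
) -> tuple[Spectrum, dict]:
    """Mean of drift-shifted, recalibrated spectra + QE-noise report.

    Because calibration re-pins the shift axis, each acquisition samples a
    given wavenumber with a different physical pixel once the laser has
    drifted; static pixel-to-pixel QE gain noise then averages down ~ 1/sqrt(M)
    over M distinct alignments. Without drift the same pixels are hit every
    time and the QE pattern is NOT reduced (the report shows it).
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to average")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if not np.array_equal(s.x, axis.values):
            raise ValueError("spectra must share a common grid")
    if calibrations is not None:
        nus = np.array([c.laser_wavenumber_cm1 for c in calibrations])
        if np.ptp(nus) < min_drift_cm1:
            warnings.warn("QE averaging ineffective: laser drift span below one grid step")
    stack = np.vstack([s.intensities for s in spectra])
    mean = stack.mean(axis=0)
    out = Spectrum(axis, mean, {"n_averaged": len(spectra)})
    report = {
        "n": len(spectra),
        "noise_before": float(
            np.mean([highfreq_noise(s, noise_window) for s in spectra])
        ),
        "noise_after": highfreq_noise(out, noise_window),
    }
    report["reduction_factor"] = (
        report["noise_before"] / report["noise_after"] if report["noise_after"] > 0 else np.inf
    )
    return out, report
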