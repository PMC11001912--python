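"""Spectral primitives: axes, unit conversion, line-profile synthesis, resampling.

Conventions used throughout the package:

* Raman shifts are in cm^-1, wavelengths in nm, and the two are linked through
  the excitation (laser) wavelength by ``shift = 1e7/laser_nm - 1e7/line_nm``.
* Line intensities in a :class:`LineList` are integrated areas, so a synthesized
  spectrum integrates to the sum of its line areas (plus baseline).
* Axes are stored ascending; display order is a presentation concern.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import voigt_profile

__all__ = [
    "AxisKind",
    "SpectralAxis",
    "Spectrum",
    "PeakShape",
    "Line",
    "LineList",
    "DEFAULT_SHIFT_GRID",
    "default_shift_grid",
    "shift_to_wavelength",
    "wavelength_to_shift",
    "synthesize_spectrum",
    "planck_radiance",
    "resample_spectrum",
    "load_line_list",
    "read_spectrum",
    "write_spectrum",
]

_GAUSS_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class AxisKind:
    """String constants for the supported axis kinds."""

    PIXEL = "pixel"
    WAVELENGTH_NM = "wavelength_nm"
    RAMAN_SHIFT_CM1 = "raman_shift_cm1"

    ALL = (PIXEL, WAVELENGTH_NM, RAMAN_SHIFT_CM1)


@dataclass(frozen=True)
class SpectralAxis:
    """Strictly increasing spectral axis of a declared kind."""

    kind: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if self.kind not in AxisKind.ALL:
            raise ValueError(f"unknown axis kind {self.kind!r}")
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least 2 points")
        if not np.all(np.diff(values) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.kind == AxisKind.PIXEL and not np.allclose(values, np.round(values)):
            raise ValueError("pixel axis must be integer-valued")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        """Median grid step (exact for uniform axes)."""
        return float(np.median(np.diff(self.values)))

    @classmethod
    def pixel(cls, n: int) -> "SpectralAxis":
        return cls(AxisKind.PIXEL, np.arange(n, dtype=float))

    @classmethod
    def shift(cls, values: Iterable[float]) -> "SpectralAxis":
        return cls(AxisKind.RAMAN_SHIFT_CM1, np.asarray(list(values), dtype=float))


#: Standard working grid for calibrated spectra: 0.5 cm^-1 step over 400-4000
#: cm^-1 (>= 10 points per ~7 cm^-1 resolution element).
DEFAULT_SHIFT_GRID = SpectralAxis(
    AxisKind.RAMAN_SHIFT_CM1, np.arange(400.0, 4000.0 + 0.25, 0.5)
)


def default_shift_grid(lo: float = 400.0, hi: float = 4000.0, step: float = 0.5) -> SpectralAxis:
    return SpectralAxis(AxisKind.RAMAN_SHIFT_CM1, np.arange(lo, hi + step / 2, step))


@dataclass
class Spectrum:
    """1-D intensity trace on a typed axis with acquisition metadata.

    ``meta`` carries free-form acquisition metadata; recognised keys are
    ``channel`` ("main" | "reference"), ``exposure_s`` and ``acquisition_id``.
    ``mask`` flags points without source support after resampling (True = valid).
    """

    axis: SpectralAxis
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.axis),):
            raise ValueError("intensities length must match axis length")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensities.shape:
                raise ValueError("mask length must match axis length")

    def copy(self, intensities: np.ndarray | None = None, **meta) -> "Spectrum":
        new = Spectrum(
            self.axis,
            self.intensities.copy() if intensities is None else intensities,
            dict(self.meta, **meta),
            None if self.mask is None else self.mask.copy(),
        )
        return new

    @property
    def x(self) -> np.ndarray:
        return self.axis.values

    @property
    def y(self) -> np.ndarray:
        return self.intensities


@dataclass(frozen=True)
class PeakShape:
    """Line-profile family with Gaussian/Lorentzian FWHM components (cm^-1).

    The realized profile FWHM for a Voigt is computed with the
    Olivero-Longbothum approximation (accurate to ~0.02%).
    """

    family: str = "lorentzian"
    gauss_fwhm: float = 0.0
    lorentz_fwhm: float = 0.0

    def __post_init__(self):
        if self.family not in ("gaussian", "lorentzian", "voigt"):
            raise ValueError(f"unknown profile family {self.family!r}")
        if self.family == "voigt" and not (self.gauss_fwhm > 0 and self.lorentz_fwhm > 0):
            raise ValueError("voigt requires both gaussian and lorentzian FWHM > 0")
        if self.family == "gaussian" and not self.gauss_fwhm > 0:
            raise ValueError("gaussian requires gauss_fwhm > 0")
        if self.family == "lorentzian" and not self.lorentz_fwhm > 0:
            raise ValueError("lorentzian requires lorentz_fwhm > 0")

    @property
    def fwhm(self) -> float:
        """FWHM of the realized profile."""
        fg, fl = self.gauss_fwhm, self.lorentz_fwhm
        if self.family == "gaussian":
            return fg
        if self.family == "lorentzian":
            return fl
        # Olivero & Longbothum approximation for the Voigt FWHM
        return 0.5346 * fl + np.sqrt(0.2166 * fl**2 + fg**2)

    def profile(self, x: np.ndarray, center: float) -> np.ndarray:
        """Unit-area profile evaluated at ``x`` (same units as the FWHMs)."""
        sigma = self.gauss_fwhm * _GAUSS_SIGMA_PER_FWHM if self.family != "lorentzian" else 0.0
        gamma = self.lorentz_fwhm / 2.0 if self.family != "gaussian" else 0.0
        return voigt_profile(np.asarray(x, dtype=float) - center, sigma, gamma)

    @classmethod
    def from_fwhm(cls, fwhm: float, family: str = "lorentzian") -> "PeakShape":
        if family == "gaussian":
            return cls("gaussian", gauss_fwhm=fwhm)
        if family == "lorentzian":
            return cls("lorentzian", lorentz_fwhm=fwhm)
        raise ValueError("use the full constructor for voigt shapes")


@dataclass(frozen=True)
class Line:
    """One Raman line: center (cm^-1), integrated area (a.u.), profile shape."""

    center_cm1: float
    rel_intensity: float
    shape: PeakShape

    def __post_init__(self):
        if self.rel_intensity < 0:
            raise ValueError("line intensity must be >= 0")

    @property
    def fwhm_cm1(self) -> float:
        return self.shape.fwhm


@dataclass(frozen=True)
class LineList:
    """Catalog of Raman lines for one material, sorted by center."""

    material: str
    lines: tuple

    def __post_init__(self):
        lines = tuple(sorted(self.lines, key=lambda l: l.center_cm1))
        if not lines:
            raise ValueError("line list needs at least one line")
        centers = [l.center_cm1 for l in lines]
        if len(set(centers)) != len(centers):
            raise ValueError("line centers must be unique")
        object.__setattr__(self, "lines", lines)

    @property
    def centers(self) -> np.ndarray:
        return np.array([l.center_cm1 for l in self.lines])

    @property
    def strongest(self) -> Line:
        return max(self.lines, key=lambda l: l.rel_intensity)

    def scaled(self, factor: float) -> "LineList":
        return LineList(
            self.material,
            tuple(Line(l.center_cm1, l.rel_intensity * factor, l.shape) for l in self.lines),
        )


def shift_to_wavelength(laser_nm: float, shift_cm1) -> np.ndarray | float:
    """Absolute wavelength (nm) of a Raman line at ``shift_cm1`` from ``laser_nm``.

    lambda = 1e7 / (1e7/laser_nm - shift).
    """
    if laser_nm <= 0:
        raise ValueError("laser wavelength must be positive")
    nu = 1e7 / laser_nm - np.asarray(shift_cm1, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("resulting wavenumber must be positive")
    out = 1e7 / nu
    return float(out) if np.isscalar(shift_cm1) else out


def wavelength_to_shift(laser_nm: float, line_nm) -> np.ndarray | float:
    """Raman shift (cm^-1) of an absolute wavelength; inverse of shift_to_wavelength."""
    if laser_nm <= 0 or np.any(np.asarray(line_nm, dtype=float) <= 0):
        raise ValueError("wavelengths must be positive")
    out = 1e7 / laser_nm - 1e7 / np.asarray(line_nm, dtype=float)
    return float(out) if np.isscalar(line_nm) else out


def synthesize_spectrum(
    line_list: LineList,
    axis: SpectralAxis,
    baseline: Spectrum | None = None,
    laser_nm: float | None = None,
) -> Spectrum:
    """Render analytic line profiles on ``axis`` (cm^-1 or nm) plus a baseline.

    On a wavelength axis the line centers and widths are converted via
    ``laser_nm``; widths use the local Jacobian d(lambda)/d(shift) = lambda^2/1e7
    and areas are preserved. Lines whose center lies outside the axis span are
    skipped with a warning.
    """
    x = axis.values
    y = np.zeros_like(x)
    if axis.kind == AxisKind.RAMAN_SHIFT_CM1:
        for line in line_list.lines:
            if not (x[0] <= line.center_cm1 <= x[-1]):
                warnings.warn(
                    f"line at {line.center_cm1:.1f} cm^-1 outside axis span; skipped"
                )
                continue
            y += line.rel_intensity * line.shape.profile(x, line.center_cm1)
    elif axis.kind == AxisKind.WAVELENGTH_NM:
        if laser_nm is None:
            raise ValueError("laser_nm required for a wavelength axis")
        for line in line_list.lines:
            c_nm = shift_to_wavelength(laser_nm, line.center_cm1)
            if not (x[0] <= c_nm <= x[-1]):
                warnings.warn(f"line at {c_nm:.2f} nm outside axis span; skipped")
                continue
            jac = c_nm**2 / 1e7  # nm per cm^-1 at the line center
            shape = PeakShape(
                line.shape.family,
                line.shape.gauss_fwhm * jac,
                line.shape.lorentz_fwhm * jac,
            )
            y += line.rel_intensity * shape.profile(x, c_nm)
    else:
        raise ValueError("synthesis requires a cm^-1 or nm axis")
    if baseline is not None:
        if baseline.axis.kind != axis.kind:
            raise ValueError("baseline axis kind mismatch")
        y += resample_spectrum(baseline, axis).intensities
    return Spectrum(axis, y, {"material": line_list.material})


def planck_radiance(temperature_K: float, wavelength_nm) -> np.ndarray | float:
    """Relative blackbody spectral radiance per unit wavelength (Planck law).

    Arbitrary common scale -- only ratios are meaningful; used to build the
    instrument response from a 3000 K tungsten-halogen lamp measurement.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    lam_m = np.asarray(wavelength_nm, dtype=float) * 1e-9
    if np.any(lam_m <= 0):
        raise ValueError("wavelength must be positive")
    h = 6.62607015e-34
    c = 2.99792458e8
    kB = 1.380649e-23
    out = 1.0 / (lam_m**5 * np.expm1(h * c / (lam_m * kB * temperature_K)))
    # scale to order unity in the NIR to avoid huge magnitudes
    out = out * 1e-27
    return float(out) if np.isscalar(wavelength_nm) else out


def resample_spectrum(
    spectrum: Spectrum, target_axis: SpectralAxis, fill_value: float = 0.0
) -> Spectrum:
    """Piecewise-linear resampling onto ``target_axis`` (same axis kind).

    Points outside the source support are set to ``fill_value`` and flagged
    False in the output mask.
    """
    if target_axis.kind != spectrum.axis.kind:
        raise ValueError("target axis kind must match source axis kind")
    xs, xt = spectrum.axis.values, target_axis.values
    if xt[-1] < xs[0] or xt[0] > xs[-1]:
        raise ValueError("target axis does not overlap source axis")
    y = np.interp(xt, xs, spectrum.intensities, left=np.nan, right=np.nan)
    inside = np.isfinite(y)
    y[~inside] = fill_value
    mask = inside
    if spectrum.mask is not None:
        src_ok = np.interp(xt, xs, spectrum.mask.astype(float), left=0, right=0)
        mask = mask & (src_ok >= 1.0 - 1e-12)
    return Spectrum(target_axis, y, dict(spectrum.meta), mask)


# ---------------------------------------------------------------------------
# File formats: JSON line lists, two-column delimited spectra


def _line_from_dict(d: dict) -> Line:
    family = d.get("shape", "lorentzian")
    if family == "voigt":
        shape = PeakShape("voigt", float(d["gauss_fwhm"]), float(d["lorentz_fwhm"]))
    elif family == "gaussian":
        shape = PeakShape("gaussian", gauss_fwhm=float(d.get("fwhm_cm1", d.get("gauss_fwhm"))))
    else:
        shape = PeakShape("lorentzian", lorentz_fwhm=float(d.get("fwhm_cm1", d.get("lorentz_fwhm"))))
    return Line(float(d["center_cm1"]), float(d.get("rel_intensity", 1.0)), shape)


def load_line_list(source: str | Path) -> LineList:
    """Load a line list from a JSON file or a bundled material name.

    Bundled materials: "polystyrene" (ASTM E1840 consensus positions),
    "polypropylene", "diamond".
    """
    path = Path(source)
    if path.suffix == ".json" and path.exists():
        payload = json.loads(path.read_text())
    else:
        ref = resources.files("reframan.data").joinpath(f"{source}.json")
        try:
            payload = json.loads(ref.read_text())
        except FileNotFoundError:
            raise FileNotFoundError(f"no line list file or bundled material {source!r}")
    lines = tuple(_line_from_dict(d) for d in payload["lines"])
    return LineList(payload.get("material", str(source)), lines)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column delimited text with a '#' header."""
    path = Path(path)
    header = [f"axis_kind: {spectrum.axis.kind}"]
    for key, val in spectrum.meta.items():
        header.append(f"{key}: {val}")
    np.savetxt(
        path,
        np.column_stack([spectrum.axis.values, spectrum.intensities]),
        header="\n".join(header),
        fmt="%.8g",
    )


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column delimited text spectrum written by :func:`write_spectrum`."""
    path = Path(path)
    meta: dict = {}
    kind = AxisKind.RAMAN_SHIFT_CM1
    with open(path) as fh:
        for raw in fh:
            if not raw.startswith("#"):
                break
            text = raw.lstrip("#").strip()
            if ":" in text:
                key, val = text.split(":", 1)
                if key.strip() == "axis_kind":
                    kind = val.strip()
                else:
                    meta[key.strip()] = val.strip()
    data = np.loadtxt(path)
    return Spectrum(SpectralAxis(kind, data[:, 0]), data[:, 1], meta)
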