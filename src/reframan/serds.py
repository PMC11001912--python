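"""Shifted-excitation separation of Raman and fluorescence.

The non-stabilized laser drifts during warm-up; the reference-channel
calibration pins the Raman features to fixed positions on the shift axis,
while fluorescence -- fixed in absolute wavelength -- moves across the shift
axis by exactly the excitation offset. Given >= 2 acquisitions with distinct
excitation wavenumbers, the Raman spectrum R (static, non-negative) and a
smooth fluorescence profile F (shifting) are recovered jointly by penalized
least squares:

    min_{R >= 0, F}  sum_i || S_i - R - T_i F ||^2 + lam * || D2 F ||^2

where T_i shifts F by the calibrated excitation offset delta_i and D2 is the
second difference. A classical two-spectrum difference mode is provided for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .spectral_core import AxisKind, Spectrum
from .refcal import CalibrationResult

__all__ = [
    "InsufficientShiftError",
    "SerdsResult",
    "estimate_excitation_shifts",
    "separate_raman_fluorescence",
    "serds_difference",
]


class InsufficientShiftError(RuntimeError):
    """Raised when the excitation wavelengths do not span enough drift."""


@dataclass
class SerdsResult:
    """Separated Raman spectrum and fluorescence profile."""

    raman: Spectrum
    fluorescence: Spectrum
    offsets_cm1: np.ndarray
    residual_norm: float
    iterations: int
    converged: bool


def estimate_excitation_shifts(
    calibrations: list[CalibrationResult], min_span_cm1: float = 0.5
) -> np.ndarray:
    """Excitation offsets delta_i = nu_laser,i - nu_laser,1 (cm^-1).

    Taken directly from the per-acquisition reference-channel calibration.
    Raises :class:`InsufficientShiftError` when the span is below one grid
    step (0.5 cm^-1): with no drift the decomposition is unidentifiable.
    """
    if len(calibrations) < 2:
        raise ValueError("need at least 2 acquisitions")
    nus = np.array([c.laser_wavenumber_cm1 for c in calibrations])
    offsets = nus - nus[0]
    if np.max(np.abs(offsets)) < min_span_cm1:
        raise InsufficientShiftError(
            f"excitation span {np.max(np.abs(offsets)):.3f} cm^-1 below {min_span_cm1} cm^-1"
        )
    return offsets


def _shift_matrix(n: int, delta_steps: float) -> sp.csr_matrix:
    """Linear-interpolation shift operator: (T f)(x) = f(x - delta).

    On the calibrated shift axis the fluorescence moves by the excitation
    offset; ``delta_steps`` is that offset in grid-step units. Out-of-range
    samples clamp to the edge value (the profile is smooth and wide).
    """
    idx = np.arange(n, dtype=float) - delta_steps
    idx = np.clip(idx, 0, n - 1)
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w_hi = idx - lo
    rows = np.concatenate([np.arange(n), np.arange(n)])
    cols = np.concatenate([lo, hi])
    vals = np.concatenate([1.0 - w_hi, w_hi])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def separate_raman_fluorescence(
    spectra: list[Spectrum],
    offsets_cm1: np.ndarray,
    smoothness: float = 1e4,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SerdsResult:
    """Joint non-negative Raman / smooth fluorescence decomposition.

    ``spectra`` must share one uniform shift grid; ``offsets_cm1`` are the
    calibrated excitation offsets. Because the Raman part is static on the
    calibrated shift axis, it cancels exactly in the differences
    S_i - S_1 = (T_i - T_1) F, so F is solved first from the differences by
    penalized least squares (``smoothness`` weights ||D2 F||^2), then
    R = max(0, mean_i(S_i - T_i F)). The additive constant that the
    differences cannot determine is fixed by putting R's minimum at zero.
    A few extra alternating refinements run until the relative objective
    change falls below ``tol``.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra")
    offsets = np.asarray(offsets_cm1, dtype=float)
    if offsets.size != len(spectra):
        raise ValueError("one offset per spectrum required")
    if np.max(np.abs(offsets)) < 0.5:
        raise InsufficientShiftError("offset span below one grid step (0.5 cm^-1)")
    axis = spectra[0].axis
    if axis.kind != AxisKind.RAMAN_SHIFT_CM1:
        raise ValueError("SERDS separation expects calibrated shift-axis spectra")
    x = axis.values
    step = float(np.median(np.diff(x)))
    if not np.allclose(np.diff(x), step, rtol=1e-6):
        raise ValueError("spectra must be on a uniform grid")
    S = np.vstack([s.intensities for s in spectra])
    m, n = S.shape

    # a feature fixed at absolute wavenumber nu_abs sits at shift =
    # nu_laser - nu_abs, so fluorescence moves by +delta_i on the shift axis
    # while calibration keeps the Raman features static
    T = [_shift_matrix(n, d / step) for d in offsets]
    D2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = smoothness * (D2.T @ D2)

    # stage 1: F from the Raman-free differences (T_i - T_1) F = S_i - S_1;
    # a tiny ridge pins the constant the differences cannot see
    A_diff = sum(((T[i] - T[0]).T @ (T[i] - T[0]) for i in range(1, m)), penalty * 1.0)
    A_diff = A_diff + 1e-9 * sp.eye(n)
    rhs = np.zeros(n)
    for i in range(1, m):
        rhs += (T[i] - T[0]).T @ (S[i] - S[0])
    F = spsolve(sp.csc_matrix(A_diff), rhs)

    def raman_update(F):
        R_raw = np.mean([S[i] - T[i] @ F for i in range(m)], axis=0)
        shift_c = float(np.min(R_raw))  # gauge: Raman baseline at zero
        return np.clip(R_raw - shift_c, 0, None), F + shift_c

    R, F = raman_update(F)

    def objective(R, F):
        resid = sum(float(np.sum((S[i] - R - T[i] @ F) ** 2)) for i in range(m))
        return resid + smoothness * float(np.sum((D2 @ F) ** 2))

    # stage 2: a few alternating refinements (mostly relevant when the
    # non-negativity clip was active)
    lhs = sp.csc_matrix(sum((Ti.T @ Ti for Ti in T), penalty * 1.0) + 1e-9 * sp.eye(n))
    prev_obj = objective(R, F)
    it = 1
    converged = True
    for it in range(2, max_iter + 1):
        rhs = np.zeros(n)
        for i in range(m):
            rhs += T[i].T @ (S[i] - R)
        F = spsolve(lhs, rhs)
        R, F = raman_update(F)
        obj = objective(R, F)
        if abs(prev_obj - obj) <= tol * max(prev_obj, 1e-12 * float(np.sum(S**2))):
            converged = True
            break
        prev_obj = obj
        converged = False
    if not converged:
        warnings.warn(f"SERDS separation did not converge in {max_iter} iterations")

    resid_norm = float(
        np.sqrt(sum(float(np.sum((S[i] - R - T[i] @ F) ** 2)) for i in range(m)) / S.size)
    )
    raman = Spectrum(axis, R, {"channel": "main", "serds": True})
    fluo = Spectrum(axis, np.asarray(F), {"serds_fluorescence": True})
    return SerdsResult(raman, fluo, offsets, resid_norm, it, converged)


def serds_difference(
    spectrum_a: Spectrum, spectrum_b: Spectrum, offset_cm1: float
) -> Spectrum:
    """Classical two-spectrum SERDS: difference then cumulative reconstruction.

    Kept for comparison with the joint estimator; the difference of two
    calibrated spectra cancels the (static-in-wavelength, hence shifted)
    fluorescence only approximately, and the Raman spectrum is recovered by
    integrating the difference. Output is clipped to non-negative.
    """
    if abs(offset_cm1) < 0.5:
        raise InsufficientShiftError("offset below one grid step (0.5 cm^-1)")
    if not np.array_equal(spectrum_a.x, spectrum_b.x):
        raise ValueError("spectra must share one grid")
    diff = spectrum_a.intensities - spectrum_b.intensities
    step = float(np.median(np.diff(spectrum_a.x)))
    # the fluorescence difference is small and smooth; remove its residual slope
    diff = diff - np.polyval(np.polyfit(spectrum_a.x, diff, 3), spectrum_a.x)
    recon = np.cumsum(diff) * step / (-offset_cm1)
    recon = recon - np.minimum.accumulate(np.minimum(recon, 0))
    return spectrum_a.copy(intensities=np.clip(recon, 0, None), serds="difference")
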