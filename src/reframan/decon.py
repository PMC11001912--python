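"""Mode-hop deconvolution and apparatus-function deblurring.

A mode hop inside one exposure multiplies the spectrum (in pixel space) by a
few-spike kernel: each emission component deposits a shifted copy. The
reference channel sees the same kernel acting on a known polystyrene
spectrum, so the kernel can be estimated there (non-negative least squares
with Tikhonov smoothing) and deconvolved out of the main channel.

The spectrometer's own line-spread function (apparatus function) is measured
by deconvolving the known 1.8 cm^-1 natural Lorentzian of diamond from an
observed diamond line; Richardson-Lucy deblurring with that kernel restores
resolution. Both deconvolutions preserve non-negativity and conserve flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit.models import ConstantModel, VoigtModel
from scipy.optimize import nnls

from .spectral_core import AxisKind, PeakShape, Spectrum

__all__ = [
    "BroadeningKernel",
    "ApparatusFunction",
    "KernelUnreliableError",
    "estimate_hop_kernel",
    "deconvolve_with_kernel",
    "richardson_lucy",
    "estimate_apparatus_function",
    "deblur",
    "fit_line_fwhm",
    "resolution_from_fwhm",
    "fwhm_of_profile",
]

MAX_KERNEL_SUPPORT = 15


class KernelUnreliableError(RuntimeError):
    """Raised when the hop-kernel fit does not explain the observed reference."""


@dataclass(frozen=True)
class BroadeningKernel:
    """Discrete convolution kernel on integer pixel offsets, unit sum."""

    offsets: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        off = np.asarray(self.offsets, dtype=int)
        w = np.asarray(self.weights, dtype=float)
        if off.shape != w.shape or off.ndim != 1:
            raise ValueError("offsets and weights must be matching 1-D arrays")
        if off.size > MAX_KERNEL_SUPPORT:
            raise ValueError(f"kernel support limited to {MAX_KERNEL_SUPPORT} pixels")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive sum")
        order = np.argsort(off)
        object.__setattr__(self, "offsets", off[order])
        object.__setattr__(self, "weights", w[order] / w.sum())

    @classmethod
    def delta(cls) -> "BroadeningKernel":
        return cls(np.array([0]), np.array([1.0]))

    def as_array(self) -> tuple[np.ndarray, int]:
        """Dense kernel on symmetric support [-m, m] and its center index."""
        m = int(np.max(np.abs(self.offsets)))
        dense = np.zeros(2 * m + 1)
        dense[self.offsets + m] = self.weights
        return dense, m

    @property
    def dominant_offset(self) -> int:
        return int(self.offsets[np.argmax(self.weights)])


@dataclass(frozen=True)
class ApparatusFunction:
    """Line-spread function sampled on a uniform cm^-1 grid, unit area."""

    offsets_cm1: np.ndarray
    profile: np.ndarray
    fwhm_cm1: float

    def __post_init__(self):
        off = np.asarray(self.offsets_cm1, dtype=float)
        prof = np.asarray(self.profile, dtype=float)
        if off.shape != prof.shape:
            raise ValueError("grid/profile size mismatch")
        if np.any(prof < 0):
            raise ValueError("apparatus function must be non-negative")
        step = float(np.median(np.diff(off)))
        area = prof.sum() * step
        if area <= 0:
            raise ValueError("apparatus function must have positive area")
        object.__setattr__(self, "offsets_cm1", off)
        object.__setattr__(self, "profile", prof / area)

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.offsets_cm1)))

    def sampled(self, step: float) -> np.ndarray:
        """Unit-sum discrete kernel at the requested grid step."""
        if not np.isclose(step, self.step, rtol=1e-6):
            half = self.offsets_cm1[-1]
            grid = np.arange(-half, half + step / 2, step)
            prof = np.interp(grid, self.offsets_cm1, self.profile)
        else:
            prof = self.profile.copy()
        total = prof.sum()
        return prof / total


def fwhm_of_profile(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM by linear interpolation of the half-maximum crossings."""
    i_max = int(np.argmax(y))
    half = y[i_max] / 2.0
    above = y >= half
    if not above.any() or y[i_max] <= 0:
        return np.nan
    # walk outwards from the maximum
    i_l = i_max
    while i_l > 0 and y[i_l - 1] >= half:
        i_l -= 1
    i_r = i_max
    while i_r < y.size - 1 and y[i_r + 1] >= half:
        i_r += 1
    if i_l == 0 or i_r == y.size - 1:
        return float(x[i_r] - x[i_l])
    x_l = np.interp(half, [y[i_l - 1], y[i_l]], [x[i_l - 1], x[i_l]])
    x_r = np.interp(half, [y[i_r + 1], y[i_r]], [x[i_r + 1], x[i_r]])
    return float(x_r - x_l)


def estimate_hop_kernel(
    observed_ref: Spectrum,
    clean_ref: Spectrum,
    support: int = 7,
    tikhonov: float | None = None,
    max_residual_frac: float = 0.10,
) -> BroadeningKernel:
    """Solve observed ~= clean (*) k by NNLS with Tikhonov smoothing on k.

    ``support`` is the half-width in pixels (kernel offsets -support..support,
    capped at the 15-pixel total support). If ``tikhonov`` is None the weight
    is chosen by the discrepancy principle: the largest weight whose residual
    stays within the noise level estimated from second differences of the
    observed spectrum. A residual above ``max_residual_frac`` of the observed
    energy raises :class:`KernelUnreliableError`.
    """
    if not np.array_equal(observed_ref.x, clean_ref.x):
        raise ValueError("observed and clean reference must share one grid")
    support = min(support, MAX_KERNEL_SUPPORT // 2)
    # a reference band is sparse lines on a flat pedestal (clipped dark noise,
    # stray light): the median is a robust baseline for both sides
    y = observed_ref.intensities - np.median(observed_ref.intensities)
    c = np.clip(clean_ref.intensities - np.median(clean_ref.intensities), 0, None)
    offsets = np.arange(-support, support + 1)
    n = y.size
    # column o holds clean shifted by o pixels (content moves right for o>0)
    A = np.zeros((n, offsets.size))
    for j, o in enumerate(offsets):
        if o >= 0:
            A[o:, j] = c[: n - o]
        else:
            A[:o, j] = c[-o:]
    y_norm = float(np.linalg.norm(y))
    if y_norm == 0:
        raise KernelUnreliableError("observed reference is empty")

    # noise level from the second-difference MAD (smooth signal cancels)
    d2 = np.diff(y, 2)
    sigma = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)
    noise_norm = sigma * np.sqrt(n)

    scale = float(np.abs(A).sum(axis=0).max())

    def solve(lam: float):
        A_aug = np.vstack([A, lam * scale * np.eye(offsets.size)])
        y_aug = np.concatenate([y, np.zeros(offsets.size)])
        w, _ = nnls(A_aug, y_aug)
        resid = float(np.linalg.norm(A @ w - y))
        return w, resid

    if tikhonov is not None:
        w, resid = solve(tikhonov)
    else:
        w, resid = solve(0.0)
        best = (w, resid)
        target = max(1.2 * noise_norm, 1e-12)
        for lam in np.logspace(-4, -1, 7):
            w_l, r_l = solve(lam)
            if r_l <= target:
                best = (w_l, r_l)
            else:
                break
        w, resid = best
    signal_norm = np.sqrt(max(y_norm**2 - noise_norm**2, 0.0))
    if signal_norm < max(noise_norm, 1e-12 * y_norm):
        raise KernelUnreliableError("observed reference carries no signal above noise")
    # noiseless data must be explained to 10%; noisy data to the noise floor
    threshold = max(max_residual_frac * y_norm, 1.3 * noise_norm)
    if w.sum() <= 0 or resid > threshold:
        raise KernelUnreliableError(
            f"kernel fit residual {resid / y_norm:.1%} of observed energy"
        )
    keep = w > 1e-3 * w.max()
    return BroadeningKernel(offsets[keep], w[keep])


def richardson_lucy(
    data: np.ndarray,
    kernel: np.ndarray,
    center: int,
    iterations: int = 30,
    tol: float = 1e-5,
) -> np.ndarray:
    """1-D Richardson-Lucy deconvolution with edge padding and flux control.

    ``kernel`` is a dense non-negative array whose index ``center`` is the
    zero offset. Input is edge-padded by the kernel length to suppress
    boundary ringing; iterations stop early when the relative update falls
    below ``tol``. The output is renormalized to the input total (RL conserves
    flux up to boundary effects).
    """
    kernel = np.asarray(kernel, dtype=float)
    if np.any(kernel < 0) or kernel.sum() <= 0:
        raise ValueError("kernel must be non-negative with positive sum")
    kernel = kernel / kernel.sum()
    # embed on symmetric support so that np.convolve(..., 'same') aligns zero offset
    m = max(center, kernel.size - 1 - center)
    sym = np.zeros(2 * m + 1)
    sym[m - center : m - center + kernel.size] = kernel
    pad = sym.size
    d = np.clip(np.asarray(data, dtype=float), 0, None)
    total_in = d.sum()
    if total_in == 0:
        return d.copy()
    dp = np.pad(d, pad, mode="edge")
    est = dp.copy()
    flipped = sym[::-1]
    eps = 1e-12
    for _ in range(iterations):
        conv = np.convolve(est, sym, mode="same")
        ratio = dp / np.clip(conv, eps, None)
        update = np.convolve(ratio, flipped, mode="same")
        new = est * update
        if np.max(np.abs(new - est)) <= tol * max(np.max(np.abs(est)), eps):
            est = new
            break
        est = new
    out = est[pad:-pad]
    if out.sum() > 0:
        out = out * (total_in / out.sum())
    return out


def deconvolve_with_kernel(
    main: Spectrum, kernel: BroadeningKernel, iterations: int = 30
) -> Spectrum:
    """Richardson-Lucy deconvolution of the hop kernel out of the main channel."""
    dense, center = kernel.as_array()
    if dense.size == 1:
        return main.copy()
    out = richardson_lucy(main.intensities, dense, center, iterations)
    return main.copy(intensities=out, hop_deconvolved=True)


def estimate_apparatus_function(
    diamond_spectrum: Spectrum,
    natural_fwhm_cm1: float = 1.8,
    window_halfwidth_cm1: float = 40.0,
    regularization: float | None = None,
) -> ApparatusFunction:
    """Apparatus function from a line of known natural width (diamond).

    The known natural Lorentzian is deconvolved from the measured line by
    Wiener-regularized division in the Fourier domain; the result is clipped
    to non-negative, renormalized to unit area and its FWHM reported. With
    ``regularization=None`` the Wiener constant adapts to the estimated
    noise-to-signal ratio (floor 1e-3 for noise-free data).
    """
    if diamond_spectrum.axis.kind != AxisKind.RAMAN_SHIFT_CM1:
        raise ValueError("expected a calibrated cm^-1 spectrum")
    x, y = diamond_spectrum.x, diamond_spectrum.y
    step = float(np.median(np.diff(x)))
    i_max = int(np.argmax(y))
    if y[i_max] <= 0:
        raise ValueError("no line found in the spectrum")
    half_n = int(round(window_halfwidth_cm1 / step))
    i0, i1 = i_max - half_n, i_max + half_n + 1
    if i0 < 0 or i1 > x.size:
        raise ValueError("dominant line too close to the axis edge")
    seg = y[i0:i1].astype(float)
    edge = max(3, seg.size // 10)
    base = np.linspace(np.median(seg[:edge]), np.median(seg[-edge:]), seg.size)
    seg = np.clip(seg - base, 0, None)
    if seg.sum() <= 0:
        raise ValueError("no line found in the window")
    L = seg.size
    if regularization is None:
        d2 = np.diff(y, 2)
        sigma = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)
        nsr2 = (sigma * np.sqrt(L) / seg.sum()) ** 2
        regularization = float(np.clip(200.0 * nsr2, 1e-3, 0.05))
    center = L // 2
    # sub-pixel alignment: centroid of the blurred line relative to window center
    centroid = float(np.sum(np.arange(L) * seg) / seg.sum())
    rel = (np.arange(L) - center) * step
    natural = PeakShape.from_fwhm(natural_fwhm_cm1, "lorentzian").profile(rel, 0.0)
    natural = natural / natural.sum()
    seg_hat = np.fft.rfft(np.fft.ifftshift(seg))
    # shift the measured line so its centroid sits at the window center
    freqs = np.fft.rfftfreq(L)
    seg_hat = seg_hat * np.exp(2j * np.pi * freqs * (centroid - center))
    nat_hat = np.fft.rfft(np.fft.ifftshift(natural))
    power = np.abs(nat_hat) ** 2
    app_hat = seg_hat * np.conj(nat_hat) / (power + regularization * power.max())
    app = np.fft.fftshift(np.fft.irfft(app_hat, n=L))
    app = np.clip(app, 0, None)
    fwhm = fwhm_of_profile(rel, app)
    return ApparatusFunction(rel, app, fwhm)


def deblur(
    spectrum: Spectrum,
    apparatus: ApparatusFunction,
    iterations: int = 30,
    tol: float = 1e-5,
) -> Spectrum:
    """Richardson-Lucy deblurring of a uniform-grid spectrum."""
    step = float(np.median(np.diff(spectrum.x)))
    if not np.allclose(np.diff(spectrum.x), step, rtol=1e-6):
        raise ValueError("deblurring requires a uniform grid")
    kern = apparatus.sampled(step)
    center = kern.size // 2
    out = richardson_lucy(spectrum.intensities, kern, center, iterations, tol)
    return spectrum.copy(intensities=out, deblurred=True)


def fit_line_fwhm(
    spectrum: Spectrum,
    approx_center: float,
    window_halfwidth: float = 30.0,
    shape: str = "voigt",
) -> tuple[float, dict]:
    """Least-squares Voigt fit of one line; returns (FWHM, fit report).

    The report carries the fitted center, the Gaussian/Lorentzian FWHM
    components (gauss = sigma*2*sqrt(2 ln 2), lorentz = 2*gamma) and the RMSE.
    """
    if shape != "voigt":
        raise ValueError("only voigt fits are supported")
    x, y = spectrum.x, spectrum.y
    sel = (x >= approx_center - window_halfwidth) & (x <= approx_center + window_halfwidth)
    if np.count_nonzero(sel) < 7:
        raise ValueError("line window outside axis")
    xs, ys = x[sel], y[sel]
    model = VoigtModel(prefix="v_") + ConstantModel(prefix="c_")
    i_max = int(np.argmax(ys))
    width0 = max(fwhm_of_profile(xs, ys - np.min(ys)) / 2.0, np.median(np.diff(xs)))
    params = model.make_params(
        v_center=float(xs[i_max]),
        v_sigma=width0 / 2.355,
        v_amplitude=float((ys[i_max] - np.min(ys)) * width0 * 1.5),
        c_c=float(np.min(ys)),
    )
    params["v_gamma"].set(vary=True, min=0.0, value=width0 / 4.0)
    params["v_sigma"].set(min=1e-4)
    result = model.fit(ys, params, x=xs)
    fwhm = float(result.params["v_fwhm"].value)
    report = {
        "center": float(result.params["v_center"].value),
        "fwhm": fwhm,
        "gauss_fwhm": float(result.params["v_sigma"].value) * 2.3548200450309493,
        "lorentz_fwhm": 2.0 * float(result.params["v_gamma"].value),
        "rmse": float(np.sqrt(np.mean(result.residual**2))),
        "success": bool(result.success),
    }
    return fwhm, report


def resolution_from_fwhm(measured_fwhm: float, intrinsic_fwhm: float) -> float:
    """Quadrature deconvolution: resolution = sqrt(measured^2 - intrinsic^2)."""
    if measured_fwhm < intrinsic_fwhm:
        raise ValueError("measured FWHM must be >= intrinsic FWHM")
    return float(np.sqrt(measured_fwhm**2 - intrinsic_fwhm**2))
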