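"""Quantification: PLS calibration/prediction, detection limits, map averaging.

PLS1 regression (mean-centered, via scikit-learn) maps preprocessed spectra
to concentrations. The component count can be chosen automatically by
leave-one-level-out cross-validation with the one-standard-error rule (all
replicates of one concentration level are held out together, so replicate
noise cannot leak between folds). Detection limits use the blank-replicate
convention: LoD = 3 sigma_blank / slope, LoQ = 10 sigma_blank / slope, with
the slope taken from the low-range predicted-vs-true line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .spectral_core import SpectralAxis, Spectrum

__all__ = [
    "CalibrationSet",
    "PLSModel",
    "DetectionLimits",
    "fit_pls",
    "predict",
    "detection_limits",
    "aggregate_map",
]


@dataclass
class CalibrationSet:
    """Concentration-labelled spectra matrix on one common grid."""

    concentrations: np.ndarray
    spectra: np.ndarray
    axis: SpectralAxis | None = None
    units: str = ""
    replicate_ids: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.spectra.shape[0] != self.concentrations.size:
            raise ValueError("one concentration per spectrum required")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.concentrations)

    @classmethod
    def from_spectra(cls, concentrations, spectra: list[Spectrum], units: str = "") -> "CalibrationSet":
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not np.array_equal(s.x, axis.values):
                raise ValueError("spectra must share one grid")
        return cls(np.asarray(concentrations, float), np.vstack([s.y for s in spectra]), axis, units)


@dataclass
class PLSModel:
    """Fitted PLS1 model with its cross-validation curve."""

    n_components: int
    estimator: PLSRegression
    x_mean: np.ndarray
    y_mean: float
    training_range: tuple
    cv_rmse: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        return np.ravel(self.estimator.coef_)


@dataclass(frozen=True)
class DetectionLimits:
    """Blank-replicate detection/quantification limits."""

    slope: float
    sigma_blank: float
    lod: float
    loq: float
    formula: str = "3sigma/10sigma"

    def __post_init__(self):
        if self.lod > 0 and not self.loq > self.lod:
            raise ValueError("LoQ must exceed LoD")


def _loo_level_rmse(calibration: CalibrationSet, n_comp: int) -> float:
    """Leave-one-level-out CV RMSE for a given component count."""
    X, y = calibration.spectra, calibration.concentrations
    errs = []
    for level in calibration.levels:
        test = calibration.concentrations == level
        if test.all():
            raise ValueError("cannot cross-validate a single-level set")
        est = PLSRegression(n_components=n_comp, scale=False)
        est.fit(X[~test], y[~test])
        pred = np.ravel(est.predict(X[test]))
        errs.extend((pred - y[test]) ** 2)
    return float(np.sqrt(np.mean(errs)))


def fit_pls(
    calibration: CalibrationSet,
    n_components: int | str = "auto",
    max_components: int = 10,
) -> PLSModel:
    """Fit mean-centered PLS1; 'auto' picks components by CV + 1-SE rule.

    The automatic choice minimizes the leave-one-level-out RMSE, then takes
    the smallest component count whose RMSE is within one standard error of
    that minimum (parsimony against overfitting).
    """
    X, y = calibration.spectra, calibration.concentrations
    n, p = X.shape
    if np.unique(y).size < 2:
        raise ValueError("degenerate calibration set: a single concentration level")
    limit = min(n - 1, p, max_components)
    if limit < 1:
        raise ValueError("not enough samples/variables for PLS")
    cv_rmse: dict[int, float] = {}
    if n_components == "auto":
        # the CV folds hold out a whole level, so the scan must respect the
        # smallest training fold
        largest_level = max(np.count_nonzero(y == lv) for lv in np.unique(y))
        limit = min(limit, n - largest_level - 1)
        if limit < 1:
            raise ValueError("not enough samples per fold for automatic selection")
        for k in range(1, limit + 1):
            cv_rmse[k] = _loo_level_rmse(calibration, k)
        best_k = min(cv_rmse, key=cv_rmse.get)
        best = cv_rmse[best_k]
        # 1-SE rule with the SE of squared errors approximated by RMSE/sqrt(n)
        threshold = best * (1.0 + 1.0 / np.sqrt(n))
        n_comp = min(k for k, v in cv_rmse.items() if v <= threshold)
    else:
        n_comp = int(n_components)
        if not 1 <= n_comp <= limit:
            raise ValueError(f"n_components must lie in [1, {limit}]")
    est = PLSRegression(n_components=n_comp, scale=False)
    est.fit(X, y)
    return PLSModel(
        n_comp,
        est,
        X.mean(axis=0),
        float(np.mean(y)),
        (float(y.min()), float(y.max())),
        cv_rmse,
    )


def predict(model: PLSModel, spectra: np.ndarray | list[Spectrum]) -> np.ndarray:
    """Predict concentrations; flags extrapolation beyond the training range."""
    if isinstance(spectra, list) and spectra and isinstance(spectra[0], Spectrum):
        X = np.vstack([s.y for s in spectra])
    else:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"grid mismatch: model expects {model.x_mean.size} variables, got {X.shape[1]}"
        )
    pred = np.ravel(model.estimator.predict(X))
    lo, hi = model.training_range
    span = hi - lo
    if np.any((pred < lo - 0.1 * span) | (pred > hi + 0.1 * span)):
        import warnings

        warnings.warn("prediction extrapolates beyond the training concentration range")
    return pred


def detection_limits(
    model: PLSModel,
    calibration: CalibrationSet,
    low_range_fraction: float = 0.25,
) -> DetectionLimits:
    """LoD/LoQ from predicted blank replicates and the low-range slope.

    sigma_blank is the std of the predictions for the zero-concentration
    replicates; the slope comes from a linear fit of predicted vs true over
    the low quarter of the calibrated range (where the limits live).
    """
    blanks = calibration.concentrations == 0
    if not np.any(blanks):
        raise ValueError("detection limits require replicate blank (zero-level) samples")
    if calibration.levels.size < 5:
        raise ValueError("LoD estimation requires >= 5 distinct concentration levels")
    pred = predict(model, calibration.spectra)
    sigma_blank = float(np.std(pred[blanks], ddof=1)) if np.count_nonzero(blanks) > 1 else 0.0
    y = calibration.concentrations
    low = y <= low_range_fraction * y.max()
    if np.unique(y[low]).size < 2:
        low = y <= np.sort(calibration.levels)[2]
    slope = float(np.polyfit(y[low], pred[low], 1)[0])
    if slope <= 0:
        raise ValueError("non-positive calibration slope")
    lod = 3.0 * sigma_blank / slope
    loq = 10.0 * sigma_blank / slope
    return DetectionLimits(slope, sigma_blank, lod, loq)


def aggregate_map(
    spectra: list[Spectrum] | np.ndarray,
    quality_mask: np.ndarray | None = None,
    axis: SpectralAxis | None = None,
) -> tuple[Spectrum, int]:
    """Pointwise mean over unmasked mapping points (e.g. a SERS map).

    ``quality_mask`` is True for points to keep (saturated or
    failed-calibration points are excluded upstream); returns the mean
    spectrum and the number of points averaged.
    """
    if isinstance(spectra, list) and spectra and isinstance(spectra[0], Spectrum):
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not np.array_equal(s.x, axis.values):
                raise ValueError("map spectra must share one grid")
        X = np.vstack([s.y for s in spectra])
    else:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
        if axis is None:
            axis = SpectralAxis.pixel(X.shape[1])
    if quality_mask is None:
        quality_mask = np.ones(X.shape[0], dtype=bool)
    quality_mask = np.asarray(quality_mask, dtype=bool)
    if not quality_mask.any():
        raise ValueError("all map points masked")
    mean = X[quality_mask].mean(axis=0)
    n_used = int(np.count_nonzero(quality_mask))
    return Spectrum(axis, mean, {"map_points": n_used}), n_used
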