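"""Uncertainty calibration: coverage curves, miscalibration area, scaling.

A surrogate reporting ``(mu_i, sigma_i)`` for truths ``t_i`` is well
calibrated when, for every confidence level ``p``, a fraction ``p`` of
truths falls inside the central Gaussian interval
``mu_i +/- z_{(1+p)/2} * sigma_i``. The miscalibration area (MA) is the
area between the observed-coverage curve and the ideal diagonal; a
single multiplicative uncertainty scaling factor is fitted on a small
validation set by minimizing MA over a fixed log-spaced grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.stats import norm, pearsonr

from .errors import CalibrationInputError, FittingError

#: default confidence levels: 99 evenly spaced interior points
DEFAULT_LEVELS = np.arange(1, 100) / 100.0

#: default search grid for the uncertainty scaling factor
DEFAULT_SCALE_GRID = np.geomspace(0.25, 20.0, 101)


@dataclass(frozen=True)
class CalibrationReport:
    """Fitted calibration summary for one surrogate configuration."""

    expected_levels: tuple[float, ...]
    observed_proportions: tuple[float, ...]
    miscalibration_area: float
    fitted_scale: float
    n_validation: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _validate(mu, sigma, truth):
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if not (mu.shape == sigma.shape == truth.shape) or mu.ndim != 1:
        raise CalibrationInputError("mu, sigma, truth must be equal-length 1-D arrays")
    if mu.size < 2:
        raise CalibrationInputError("need at least 2 validation points")
    if np.any(sigma <= 0):
        raise CalibrationInputError("all sigma must be > 0 for coverage intervals")
    return mu, sigma, truth


def calibration_curve(
    mu, sigma, truth, levels: np.ndarray = DEFAULT_LEVELS
) -> tuple[np.ndarray, np.ndarray]:
    """Observed coverage of central Gaussian intervals at each level."""
    mu, sigma, truth = _validate(mu, sigma, truth)
    levels = np.asarray(levels, dtype=np.float64)
    z = np.abs(truth - mu) / sigma
    zcrit = norm.ppf((1.0 + levels) / 2.0)
    observed = (z[:, None] <= zcrit[None, :]).mean(axis=0)
    return levels, observed


def miscalibration_area(levels, observed) -> float:
    """Trapezoidal area between the coverage curve and the diagonal."""
    levels = np.asarray(levels, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if levels.ndim != 1 or levels.shape != observed.shape:
        raise CalibrationInputError("levels and observed must be equal-length 1-D")
    if np.any(np.diff(levels) <= 0):
        raise CalibrationInputError("levels must be strictly increasing")
    return float(np.trapezoid(np.abs(observed - levels), levels))


def fit_uncertainty_scale(
    mu,
    sigma,
    truth,
    candidate_scales: np.ndarray = DEFAULT_SCALE_GRID,
    levels: np.ndarray = DEFAULT_LEVELS,
) -> float:
    """Scale ``c`` minimizing the MA of ``c * sigma``; ties to smallest ``c``.

    A 1-D grid search over a fixed log-spaced grid keeps the fit
    reproducible and free of optimizer state.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if np.all(sigma == 0):
        raise FittingError("all sigma are zero; scaling factor is unidentifiable")
    mu, sigma, truth = _validate(mu, sigma, truth)
    scales = np.sort(np.asarray(candidate_scales, dtype=np.float64))
    if scales.size < 1 or np.any(scales <= 0):
        raise ValueError("candidate_scales must be positive")
    best_scale = None
    best_ma = np.inf
    for c in scales:
        _, observed = calibration_curve(mu, c * sigma, truth, levels)
        ma = miscalibration_area(levels, observed)
        if ma < best_ma - 1e-15:
            best_ma = ma
            best_scale = float(c)
    return best_scale


def calibrate(
    mu, sigma, truth,
    candidate_scales: np.ndarray = DEFAULT_SCALE_GRID,
    levels: np.ndarray = DEFAULT_LEVELS,
) -> CalibrationReport:
    """Fit the scaling factor and report the post-scaling coverage curve."""
    c = fit_uncertainty_scale(mu, sigma, truth, candidate_scales, levels)
    lv, observed = calibration_curve(mu, c * np.asarray(sigma, float), truth, levels)
    return CalibrationReport(
        expected_levels=tuple(float(x) for x in lv),
        observed_proportions=tuple(float(x) for x in observed),
        miscalibration_area=miscalibration_area(lv, observed),
        fitted_scale=c,
        n_validation=int(np.asarray(mu).size),
    )


@dataclass(frozen=True)
class RegressionMetrics:
    mae: float
    pearson_r: float
    nll: float | None


def regression_metrics(pred, truth, sigma=None) -> RegressionMetrics:
    """MAE, Pearson r, and (if sigma given) mean Gaussian negative
    log-likelihood of the truths under ``Normal(pred, sigma)``."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size < 2:
        raise CalibrationInputError("pred and truth must be equal-length 1-D, n >= 2")
    if np.std(truth) == 0 or np.std(pred) == 0:
        raise CalibrationInputError("Pearson r undefined for zero-variance input")
    mae = float(np.mean(np.abs(pred - truth)))
    r = float(pearsonr(pred, truth).statistic)
    nll = None
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=np.float64)
        if sigma.shape != pred.shape or np.any(sigma <= 0):
            raise CalibrationInputError("sigma must match pred and be > 0 for NLL")
        nll = float(np.mean(-norm.logpdf(truth, loc=pred, scale=sigma)))
    return RegressionMetrics(mae=mae, pearson_r=r, nll=nll)
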