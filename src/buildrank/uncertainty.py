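"""Kernel-estimator prediction intervals for forest predictions.

Uncertainty is quantified per (variant, measure) regressor from its
calibration residuals: for a bagged forest these are out-of-bag residuals
(observed minus the prediction of only those trees whose bootstrap sample
excluded the row), which estimate held-out error without a separate
calibration set.  A Gaussian kernel density with Silverman's rule-of-thumb
bandwidth is fitted to the residual distribution, and the interval around a
point prediction is given by the density's central quantiles:

    [point + q_{(1-c)/2},  point + q_{(1+c)/2}]

The interval width is the ranking currency: wide interval = uncertain
prediction.  One global residual distribution is used per regressor
(homoscedastic); intervals may therefore be asymmetric around the point
but have the same width for every input.
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import clone
from sklearn.model_selection import KFold, cross_val_predict

if TYPE_CHECKING:  # pragma: no cover
    from sklearn.ensemble import RandomForestRegressor

    from .training import TrainingTable

logger = logging.getLogger(__name__)

__all__ = [
    "BANDWIDTH_FLOOR",
    "silverman_bandwidth",
    "oob_predictions",
    "calibration_residuals",
    "kernel_interval",
]

#: Lower bound on the kernel bandwidth, so zero-spread residual sets still
#: produce a finite-width interval.
BANDWIDTH_FLOOR = 1e-6


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = float(np.std(values))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not spread_candidates:
        return BANDWIDTH_FLOOR
    h = 0.9 * min(spread_candidates) * n ** (-1 / 5)
    return max(h, BANDWIDTH_FLOOR)


def oob_predictions(
    forest: "RandomForestRegressor", X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag prediction per training row.

    Each tree's bootstrap sample is reconstructed from the tree's recorded
    random state, so a row is averaged only over trees that never saw it.
    Returns ``(predictions, has_oob)``; ``has_oob[i]`` is False for rows
    that appeared in every tree's bootstrap sample (prediction NaN there).
    """
    # sklearn keeps these helpers stable across minor versions; their output
    # matches forest.oob_prediction_ exactly (see the uncertainty tests).
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    total = np.zeros(n)
    count = np.zeros(n)
    n_bootstrap = _get_n_samples_bootstrap(n, forest.max_samples, None)
    for tree in forest.estimators_:
        oob_idx = _generate_unsampled_indices(tree.random_state, n, n_bootstrap, None)
        if len(oob_idx) == 0:
            continue
        total[oob_idx] += tree.predict(X[oob_idx])
        count[oob_idx] += 1
    has_oob = count > 0
    predictions = np.full(n, np.nan)
    predictions[has_oob] = total[has_oob] / count[has_oob]
    return predictions, has_oob


def calibration_residuals(
    forest: "RandomForestRegressor", train: "TrainingTable"
) -> np.ndarray:
    """Residuals (observed - held-out-style prediction) on the training rows.

    With bagging on, residuals are out-of-bag; rows that were in-bag for
    every tree are skipped.  With bagging off there is no out-of-bag sample,
    so 10-fold cross-validated residuals are used instead (logged).
    """
    X, y = train.X, train.y
    if getattr(forest, "bootstrap", True):
        pred, has_oob = oob_predictions(forest, X)
        n_skipped = int((~has_oob).sum())
        if n_skipped:
            logger.info("skipping %d rows with no out-of-bag prediction", n_skipped)
        return y[has_oob] - pred[has_oob]
    logger.info("bagging disabled: falling back to 10-fold cross-validated residuals")
    k = min(10, len(y))
    cv_pred = cross_val_predict(
        clone(forest), X, y, cv=KFold(n_splits=k, shuffle=True, random_state=0)
    )
    return y - cv_pred


def _kde_cdf(x: float, residuals: np.ndarray, bandwidth: float) -> float:
    return float(np.mean(norm.cdf((x - residuals) / bandwidth)))


def _kde_quantile(q: float, residuals: np.ndarray, bandwidth: float) -> float:
    lo = float(residuals.min()) - 12.0 * bandwidth
    hi = float(residuals.max()) + 12.0 * bandwidth
    return brentq(lambda x: _kde_cdf(x, residuals, bandwidth) - q, lo, hi, xtol=1e-12)


def kernel_interval(
    point: float, residuals: np.ndarray, confidence: float = 0.95
) -> tuple[float, float]:
    """Prediction interval from a Gaussian-kernel density over the residuals.

    Deterministic given its inputs.  Requires at least 10 residuals.  A
    zero-spread residual set yields the minimum-width interval
    ``point + mean(residuals) ± BANDWIDTH_FLOOR``.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 10:
        raise ValueError(f"need at least 10 residuals, got {residuals.size}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if float(np.ptp(residuals)) == 0.0:
        center = point + float(residuals[0])
        return (center - BANDWIDTH_FLOOR, center + BANDWIDTH_FLOOR)
    h = silverman_bandwidth(residuals)
    q_low = _kde_quantile((1.0 - confidence) / 2.0, residuals, h)
    q_high = _kde_quantile((1.0 + confidence) / 2.0, residuals, h)
    return (point + q_low, point + q_high)
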