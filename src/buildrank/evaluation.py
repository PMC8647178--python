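"""Evaluation protocol: error metrics, ablation, binned comparison, hit rates.

The predictive suite is judged the way a regression benchmark would be:

* MAE/RMSE per (variant, measure) cell against the Zero-R median baseline,
  on held-out data and (for the over-fit gap) on the training data;
* leave-one-feature-out ablation — retrain the suite without each feature
  in turn, same split and seeds, and report the error increase;
* per-resolution-bin mean/SD of predicted vs actual outcomes;
* group hit rate — how often the variant with the lowest prediction error
  lands in the first (most certain) uncertainty group;
* within-k analysis — how close the recommended variant's actual outcome
  comes to the best achievable outcome across all variants.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ranking import RankedReport
from .training import ForestConfig, SuiteMatrix, TrainingTable, train_suite
from .variants import PipelineVariant

logger = logging.getLogger(__name__)

__all__ = [
    "mae",
    "rmse",
    "compare_to_baseline",
    "ablation",
    "resolution_binned_stats",
    "group_hit_rate",
    "within_k_analysis",
]

_HIGHER_IS_BETTER = {"completeness"}


def _paired(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty vectors")
    if p.size != a.size:
        raise ValueError(f"length mismatch: {p.size} vs {a.size}")
    return p, a


def mae(predicted, actual) -> float:
    """Mean absolute error."""
    p, a = _paired(predicted, actual)
    return float(np.mean(np.abs(p - a)))


def rmse(predicted, actual) -> float:
    """Root-mean-square error."""
    p, a = _paired(predicted, actual)
    return float(np.sqrt(np.mean((p - a) ** 2)))


def _cell_errors(suite: SuiteMatrix, table: TrainingTable, variant_id: str, measure: str):
    frame = table.frame
    keep = frame["outcome"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "cell (%s, %s): excluding %d rows with missing outcomes",
            variant_id,
            measure,
            n_dropped,
        )
    frame = frame[keep]
    if frame.empty:
        raise ValueError(f"no usable rows for cell ({variant_id}, {measure})")
    X = frame[table.feature_columns].to_numpy(dtype=float)
    y = frame["outcome"].to_numpy(dtype=float)
    model_pred = suite.predict_point(variant_id, measure, X)
    base_pred = suite.cell(variant_id, measure).baseline.predict(X)
    return model_pred, base_pred, y


def compare_to_baseline(
    suite: SuiteMatrix,
    test_tables: Mapping[tuple[str, str], TrainingTable],
    train_tables: Optional[Mapping[tuple[str, str], TrainingTable]] = None,
) -> pd.DataFrame:
    """MAE/RMSE of the suite and the Zero-R baseline, cell by cell.

    Returns one row per (variant, measure) with ``mae_model, rmse_model,
    mae_baseline, rmse_baseline, n_test`` and, when ``train_tables`` is
    given, the corresponding ``*_train`` columns for the over-fit gap.
    """
    rows = []
    for (variant_id, measure), cell in suite.cells.items():
        if (variant_id, measure) not in test_tables:
            raise ValueError(f"no test table for cell ({variant_id}, {measure})")
        model_pred, base_pred, y = _cell_errors(
            suite, test_tables[(variant_id, measure)], variant_id, measure
        )
        row = {
            "variant_id": variant_id,
            "measure": measure,
            "mae_model": mae(model_pred, y),
            "rmse_model": rmse(model_pred, y),
            "mae_baseline": mae(base_pred, y),
            "rmse_baseline": rmse(base_pred, y),
            "n_test": len(y),
        }
        if train_tables is not None:
            tr_model, tr_base, tr_y = _cell_errors(
                suite, train_tables[(variant_id, measure)], variant_id, measure
            )
            row.update(
                {
                    "mae_model_train": mae(tr_model, tr_y),
                    "rmse_model_train": rmse(tr_model, tr_y),
                    "mae_baseline_train": mae(tr_base, tr_y),
                    "rmse_baseline_train": rmse(tr_base, tr_y),
                    "n_train": len(tr_y),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _drop_feature(table: TrainingTable, feature: str) -> TrainingTable:
    columns = [c for c in table.feature_columns if c != feature]
    return TrainingTable(
        frame=table.frame[["dataset_id", *columns, "outcome"]],
        feature_columns=columns,
    )


def ablation(
    train_tables: Mapping[tuple[str, str], TrainingTable],
    test_tables: Mapping[tuple[str, str], TrainingTable],
    registry: Sequence[PipelineVariant],
    config: ForestConfig,
    features: Optional[Sequence[str]] = None,
    phasing_mode: str = "experimental",
) -> pd.DataFrame:
    """Leave-one-feature-out retraining: error deltas per removed feature.

    For each feature the whole suite is retrained without it (same seeds
    and split) and evaluated on the test tables.  Returns one row per
    (feature, variant, measure) with ``delta_mae``/``delta_rmse`` = error
    without the feature minus error with all features; a positive delta
    means the feature was informative.
    """
    some_table = next(iter(train_tables.values()))
    features = list(features) if features is not None else list(some_table.feature_columns)
    if len(some_table.feature_columns) < 2:
        raise ValueError("ablation needs at least 2 features")
    full_suite = train_suite(
        train_tables, registry, config, phasing_mode=phasing_mode, compute_residuals=False
    )
    full_report = compare_to_baseline(full_suite, test_tables)
    full_report = full_report.set_index(["variant_id", "measure"])
    rows = []
    for feature in features:
        reduced_train = {k: _drop_feature(t, feature) for k, t in train_tables.items()}
        reduced_test = {k: _drop_feature(t, feature) for k, t in test_tables.items()}
        suite = train_suite(
            reduced_train, registry, config, phasing_mode=phasing_mode, compute_residuals=False
        )
        report = compare_to_baseline(suite, reduced_test).set_index(["variant_id", "measure"])
        for key in report.index:
            rows.append(
                {
                    "feature": feature,
                    "variant_id": key[0],
                    "measure": key[1],
                    "delta_mae": report.loc[key, "mae_model"] - full_report.loc[key, "mae_model"],
                    "delta_rmse": report.loc[key, "rmse_model"]
                    - full_report.loc[key, "rmse_model"],
                }
            )
    return pd.DataFrame(rows)


def resolution_binned_stats(
    frame: pd.DataFrame, bin_width: float = 0.1
) -> pd.DataFrame:
    """Per-resolution-bin mean/SD of predicted and actual outcomes.

    ``frame`` needs columns ``resolution, predicted, actual``.  Bins are of
    fixed width over the observed resolution range; empty bins are reported
    with ``n = 0`` and NaN statistics.  SD uses the sample convention
    (ddof=1; NaN when n < 2).
    """
    required = {"resolution", "predicted", "actual"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"frame missing columns {sorted(missing)}")
    if frame.empty:
        raise ValueError("no records to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    res = frame["resolution"].to_numpy(dtype=float)
    low = np.floor(res.min() / bin_width) * bin_width
    high = res.max()
    n_bins = max(1, int(np.ceil((high - low) / bin_width)))
    if low + n_bins * bin_width <= high:  # right edge inclusive for the max
        n_bins += 1
    edges = low + bin_width * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(res, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        row = {
            "bin_low": float(edges[b]),
            "bin_high": float(edges[b + 1]),
            "n": n,
            "pred_mean": np.nan,
            "pred_sd": np.nan,
            "actual_mean": np.nan,
            "actual_sd": np.nan,
        }
        if n > 0:
            pred = frame.loc[mask, "predicted"].to_numpy(dtype=float)
            act = frame.loc[mask, "actual"].to_numpy(dtype=float)
            row.update(
                pred_mean=float(pred.mean()),
                actual_mean=float(act.mean()),
                pred_sd=float(pred.std(ddof=1)) if n > 1 else np.nan,
                actual_sd=float(act.std(ddof=1)) if n > 1 else np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _actual_lookup(actuals: pd.DataFrame) -> pd.Series:
    required = {"dataset_id", "variant_id", "outcome"}
    missing = required - set(actuals.columns)
    if missing:
        raise ValueError(f"actual-outcome frame missing columns {sorted(missing)}")
    return actuals.set_index(["dataset_id", "variant_id"])["outcome"]


def group_hit_rate(
    reports: Mapping[str, RankedReport],
    actuals: pd.DataFrame,
    criterion: str = "error",
) -> float:
    """Fraction of datasets whose best variant sits in the first group.

    ``reports`` maps dataset_id to that dataset's :class:`RankedReport`
    (one measure).  ``actuals`` is a long frame with ``dataset_id,
    variant_id, outcome``.  With the default ``criterion="error"`` the best
    variant is the one with the smallest |predicted - actual|; with
    ``criterion="outcome"`` it is the one with the best actual outcome.
    Datasets with no actual outcomes are excluded (logged).
    """
    if criterion not in ("error", "outcome"):
        raise ValueError("criterion must be 'error' or 'outcome'")
    lookup = _actual_lookup(actuals)
    hits = 0
    n_used = 0
    n_excluded = 0
    for dataset_id, report in reports.items():
        records = pd.concat(report.groups, ignore_index=True)
        actual = []
        for vid in records["variant_id"]:
            key = (dataset_id, vid)
            actual.append(lookup[key] if key in lookup.index else np.nan)
        records = records.assign(actual=actual).dropna(subset=["actual"])
        if records.empty:
            n_excluded += 1
            continue
        if criterion == "error":
            scores = (records["point"] - records["actual"]).abs()
            best_variant = records.loc[scores.idxmin(), "variant_id"]
        else:
            best = (
                records["actual"].idxmax()
                if report.measure in _HIGHER_IS_BETTER
                else records["actual"].idxmin()
            )
            best_variant = records.loc[best, "variant_id"]
        n_used += 1
        if best_variant in report.first_group_ids():
            hits += 1
    if n_excluded:
        logger.info("group_hit_rate: excluded %d datasets without outcomes", n_excluded)
    if n_used == 0:
        raise ValueError("no datasets with actual outcomes")
    return hits / n_used


def within_k_analysis(
    recommended: Mapping[str, str],
    actuals: pd.DataFrame,
    measure: str,
    thresholds: Sequence[float] = (0.01, 0.05),
) -> dict[float, float]:
    """Fraction of datasets whose recommended variant is within k of the best.

    For each dataset the gap is |actual(recommended) - best actual over all
    variants| (best = max for completeness, min for R factors); the result
    maps each threshold k to the fraction of datasets with gap <= k.
    Fractions are cumulative, hence non-decreasing in k.
    """
    lookup = _actual_lookup(actuals)
    by_dataset = actuals.groupby("dataset_id")["outcome"]
    best = by_dataset.max() if measure in _HIGHER_IS_BETTER else by_dataset.min()
    gaps = []
    n_excluded = 0
    for dataset_id, variant_id in recommended.items():
        key = (dataset_id, variant_id)
        if key not in lookup.index or dataset_id not in best.index:
            n_excluded += 1
            continue
        gaps.append(abs(float(lookup[key]) - float(best[dataset_id])))
    if n_excluded:
        logger.info("within_k_analysis: excluded %d datasets without outcomes", n_excluded)
    if not gaps:
        raise ValueError("no datasets with actual outcomes")
    gaps_arr = np.asarray(gaps)
    return {float(k): float(np.mean(gaps_arr <= k)) for k in thresholds}
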