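"""Training of the per-(variant, measure) regression-forest suite.

One random-forest regressor is trained for every applicable
(pipeline variant, evaluation measure) cell, all cells sharing a single
random 80/20 split of the datasets.  The forest uses 1024 fully grown trees
with bootstrap aggregation; predictions are the mean over trees, so they
can never leave the range of the training outcomes.  A Zero-R baseline
(constant training-median predictor) accompanies every cell.

Out-of-bag calibration residuals are computed at training time and stored
with each cell so that prediction intervals can be attached without
touching held-out data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .uncertainty import calibration_residuals, kernel_interval
from .variants import (
    MEASURES,
    PipelineVariant,
    applicable_measures,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingTable",
    "ForestConfig",
    "SuiteCell",
    "SuiteMatrix",
    "split_dataset",
    "split_ids",
    "train_forest",
    "ZeroR",
    "zero_r",
    "train_suite",
    "EXPERIMENTAL_FEATURES",
    "MR_FEATURES",
]

EXPERIMENTAL_FEATURES = ["resolution", "rmsd", "skew", "max_density", "min_density"]
MR_FEATURES = EXPERIMENTAL_FEATURES + ["sequence_identity"]


@dataclass
class TrainingTable:
    """Feature/outcome rows for one (variant, measure) cell.

    ``frame`` holds one row per dataset with a ``dataset_id`` column, the
    feature columns, and an outcome column.
    """

    frame: pd.DataFrame
    feature_columns: list[str]
    outcome_column: str = "outcome"

    def __post_init__(self) -> None:
        required = ["dataset_id", *self.feature_columns, self.outcome_column]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"training table missing columns {missing}")
        if self.frame["dataset_id"].duplicated().any():
            raise ValueError("one row per dataset_id required")
        if self.frame[self.feature_columns].isna().any().any():
            raise ValueError("missing feature values are not allowed")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.outcome_column].to_numpy(dtype=float)

    def subset(self, dataset_ids: Sequence) -> "TrainingTable":
        mask = self.frame["dataset_id"].isin(set(dataset_ids))
        return TrainingTable(
            frame=self.frame[mask].reset_index(drop=True),
            feature_columns=list(self.feature_columns),
            outcome_column=self.outcome_column,
        )


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters: 1024 unlimited-depth bagged trees."""

    n_trees: int = 1024
    max_depth: Optional[int] = None
    bagging: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")


def split_ids(dataset_ids: Sequence, train_fraction: float = 0.8, seed: int = 0):
    """Random disjoint partition of dataset ids; train size = round(f*n)."""
    ids = list(dataset_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 datasets to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def split_dataset(
    table: TrainingTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[TrainingTable, TrainingTable]:
    """80/20-style random split of a table by dataset_id (reproducible)."""
    train_ids, test_ids = split_ids(table.frame["dataset_id"], train_fraction, seed)
    return table.subset(train_ids), table.subset(test_ids)


def train_forest(train: TrainingTable, config: ForestConfig) -> RandomForestRegressor:
    """Fit a bagged regression forest on a training table."""
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        bootstrap=config.bagging,
        random_state=config.seed % (2**31),
        n_jobs=1,
    )
    forest.fit(train.X, train.y)
    return forest


class ZeroR:
    """Baseline predictor: the training-outcome median, regardless of input.

    Even-count median is the mean of the two middle values.
    """

    def __init__(self, median: float):
        self.median = float(median)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X)
        n = X.shape[0] if X.ndim > 0 else 1
        return np.full(n, self.median)


def zero_r(train: TrainingTable) -> ZeroR:
    if len(train) < 1:
        raise ValueError("need at least 1 training row")
    return ZeroR(float(np.median(train.y)))


@dataclass
class SuiteCell:
    """One trained (variant, measure) regressor with its calibration data."""

    variant_id: str
    measure: str
    forest: RandomForestRegressor
    baseline: ZeroR
    residuals: np.ndarray
    feature_columns: list[str]
    n_train: int
    seed: int


@dataclass
class SuiteMatrix:
    """The trained collection of per-(variant, measure) regressors."""

    cells: dict[tuple[str, str], SuiteCell]
    registry: list[PipelineVariant]
    config: ForestConfig
    phasing_mode: str
    split_seed: int
    feature_columns: list[str]
    train_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, variant_id: str, measure: str) -> SuiteCell:
        key = (variant_id, measure)
        if key not in self.cells:
            if any(v.variant_id == variant_id for v in self.registry):
                raise KeyError(
                    f"measure {measure!r} is not applicable to variant {variant_id!r}"
                )
            raise KeyError(f"variant {variant_id!r} is not in the suite registry")
        return self.cells[key]

    def predict_point(self, variant_id: str, measure: str, X: np.ndarray) -> np.ndarray:
        """Point prediction, clamped to [0, 1] for completeness."""
        cell = self.cell(variant_id, measure)
        pred = cell.forest.predict(np.asarray(X, dtype=float))
        if measure == "completeness":
            pred = np.clip(pred, 0.0, 1.0)
        return pred

    def predict_records(
        self,
        features: pd.DataFrame,
        confidence: float = 0.95,
        variant_ids: Optional[Sequence[str]] = None,
        measures: Optional[Sequence[str]] = None,
    ) -> pd.DataFrame:
        """Point predictions plus kernel prediction intervals.

        ``features`` has one row per dataset with a ``dataset_id`` column and
        the suite's feature columns.  Returns a long-format frame with one
        row per (dataset, variant, measure): columns ``dataset_id,
        variant_id, measure, point, interval_low, interval_high, confidence,
        width``.
        """
        missing = [c for c in self.feature_columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature frame missing columns {missing}")
        X = features[self.feature_columns].to_numpy(dtype=float)
        ids = features["dataset_id"].to_numpy()
        rows = []
        for (variant_id, measure), cell in self.cells.items():
            if variant_ids is not None and variant_id not in variant_ids:
                continue
            if measures is not None and measure not in measures:
                continue
            points = self.predict_point(variant_id, measure, X)
            # intervals are translation-equivariant in the point, so the
            # residual quantiles are computed once per cell
            q_low, q_high = kernel_interval(0.0, cell.residuals, confidence)
            for dataset_id, point in zip(ids, points):
                low, high = float(point) + q_low, float(point) + q_high
                rows.append(
                    {
                        "dataset_id": dataset_id,
                        "variant_id": variant_id,
                        "measure": measure,
                        "point": float(point),
                        "interval_low": low,
                        "interval_high": high,
                        "confidence": confidence,
                        "width": high - low,
                    }
                )
        return pd.DataFrame(rows)

    # --- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist the suite as one joblib file per cell plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "phasing_mode": self.phasing_mode,
            "split_seed": self.split_seed,
            "feature_columns": self.feature_columns,
            "train_ids": [str(i) for i in self.train_ids],
            "test_ids": [str(i) for i in self.test_ids],
            "config": {
                "n_trees": self.config.n_trees,
                "max_depth": self.config.max_depth,
                "bagging": self.config.bagging,
                "seed": self.config.seed,
            },
            "registry": [
                {
                    "variant_id": v.variant_id,
                    "stages": list(v.stages),
                    "parrot_preconditioned": v.parrot_preconditioned,
                    "phasing_mode": v.phasing_mode,
                }
                for v in self.registry
            ],
            "cells": [],
        }
        for (variant_id, measure), cell in self.cells.items():
            fname = f"{variant_id}__{measure}.joblib".replace("/", "_")
            joblib.dump(
                {
                    "forest": cell.forest,
                    "baseline_median": cell.baseline.median,
                    "residuals": cell.residuals,
                    "n_train": cell.n_train,
                    "seed": cell.seed,
                },
                directory / fname,
            )
            manifest["cells"].append(
                {"variant_id": variant_id, "measure": measure, "file": fname}
            )
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "SuiteMatrix":
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.is_file():
            raise FileNotFoundError(f"no suite manifest at {manifest_path}")
        manifest = json.loads(manifest_path.read_text())
        config = ForestConfig(**manifest["config"])
        registry = [
            PipelineVariant(
                stages=tuple(v["stages"]),
                parrot_preconditioned=v["parrot_preconditioned"],
                phasing_mode=v["phasing_mode"],
                variant_id=v["variant_id"],
            )
            for v in manifest["registry"]
        ]
        cells = {}
        for entry in manifest["cells"]:
            payload = joblib.load(directory / entry["file"])
            cells[(entry["variant_id"], entry["measure"])] = SuiteCell(
                variant_id=entry["variant_id"],
                measure=entry["measure"],
                forest=payload["forest"],
                baseline=ZeroR(payload["baseline_median"]),
                residuals=np.asarray(payload["residuals"]),
                feature_columns=list(manifest["feature_columns"]),
                n_train=payload["n_train"],
                seed=payload["seed"],
            )
        return cls(
            cells=cells,
            registry=registry,
            config=config,
            phasing_mode=manifest["phasing_mode"],
            split_seed=manifest["split_seed"],
            feature_columns=list(manifest["feature_columns"]),
            train_ids=manifest["train_ids"],
            test_ids=manifest["test_ids"],
        )


def tables_from_long(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    registry: Sequence[PipelineVariant],
    feature_columns: Sequence[str],
    dataset_ids: Optional[Sequence] = None,
) -> dict[tuple[str, str], TrainingTable]:
    """Assemble per-cell tables from a feature frame and a long outcome frame.

    ``features`` has one row per dataset (``dataset_id`` + feature columns);
    ``outcomes`` is long format with ``dataset_id, variant_id, measure,
    outcome``.  Rows are restricted to ``dataset_ids`` when given (e.g. one
    side of a split).
    """
    required = {"dataset_id", "variant_id", "measure", "outcome"}
    missing = required - set(outcomes.columns)
    if missing:
        raise ValueError(f"outcome frame missing columns {sorted(missing)}")
    if dataset_ids is not None:
        keep = set(dataset_ids)
        features = features[features["dataset_id"].isin(keep)]
        outcomes = outcomes[outcomes["dataset_id"].isin(keep)]
    tables: dict[tuple[str, str], TrainingTable] = {}
    for variant in registry:
        for measure in applicable_measures(variant):
            cell = outcomes[
                (outcomes["variant_id"] == variant.variant_id)
                & (outcomes["measure"] == measure)
            ][["dataset_id", "outcome"]]
            frame = features.merge(cell, on="dataset_id", how="inner")
            tables[(variant.variant_id, measure)] = TrainingTable(
                frame=frame[["dataset_id", *feature_columns, "outcome"]].reset_index(drop=True),
                feature_columns=list(feature_columns),
            )
    return tables


def _cell_seed(base: int, index: int) -> int:
    return (base * 1000003 + index * 7919) % (2**31)


def train_suite(
    tables: Mapping[tuple[str, str], TrainingTable],
    registry: Sequence[PipelineVariant],
    config: ForestConfig,
    phasing_mode: str = "experimental",
    split_seed: int = 0,
    train_ids: Optional[Sequence] = None,
    test_ids: Optional[Sequence] = None,
    compute_residuals: bool = True,
) -> SuiteMatrix:
    """Train one forest per applicable (variant, measure) cell.

    ``tables`` maps ``(variant_id, measure)`` to a :class:`TrainingTable`
    restricted to the TRAINING rows; all tables must cover the same
    dataset ids so every cell sees the same split.  Requesting an
    inapplicable cell (a table supplied for an (variant, measure) pair the
    registry rules out) is an error.
    """
    registry = list(registry)
    known = {v.variant_id: v for v in registry}
    for variant_id, measure in tables:
        if variant_id in known and measure not in applicable_measures(known[variant_id]):
            raise ValueError(
                f"measure {measure!r} is not applicable to variant {variant_id!r}"
            )
    cells: dict[tuple[str, str], SuiteCell] = {}
    feature_columns: Optional[list[str]] = None
    shared_ids: Optional[frozenset] = None
    index = 0
    for variant in registry:
        for measure in applicable_measures(variant):
            key = (variant.variant_id, measure)
            if key not in tables:
                raise ValueError(f"no training table for cell {key}")
            table = tables[key]
            if feature_columns is None:
                feature_columns = list(table.feature_columns)
            elif list(table.feature_columns) != feature_columns:
                raise ValueError("all cells must share one feature schema")
            ids = frozenset(table.frame["dataset_id"])
            if shared_ids is None:
                shared_ids = ids
            elif ids != shared_ids:
                raise ValueError("all cells must be trained on the same dataset split")
            cell_config = replace(config, seed=_cell_seed(config.seed, index))
            forest = train_forest(table, cell_config)
            residuals = (
                calibration_residuals(forest, table)
                if compute_residuals
                else np.empty(0)
            )
            cells[key] = SuiteCell(
                variant_id=variant.variant_id,
                measure=measure,
                forest=forest,
                baseline=zero_r(table),
                residuals=residuals,
                feature_columns=feature_columns,
                n_train=len(table),
                seed=cell_config.seed,
            )
            index += 1
    logger.info("trained %d suite cells (%s mode)", len(cells), phasing_mode)
    return SuiteMatrix(
        cells=cells,
        registry=registry,
        config=config,
        phasing_mode=phasing_mode,
        split_seed=split_seed,
        feature_columns=feature_columns or [],
        train_ids=list(train_ids or []),
        test_ids=list(test_ids or []),
    )
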