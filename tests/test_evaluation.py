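"""Error metrics, baseline comparison, binned stats, hit rates, within-k."""

import numpy as np
import pandas as pd
import pytest

from buildrank.evaluation import (
    compare_to_baseline,
    group_hit_rate,
    mae,
    resolution_binned_stats,
    rmse,
    within_k_analysis,
)
from buildrank.ranking import RankedReport, ranked_report
from buildrank.training import ForestConfig, split_dataset, train_suite
from buildrank.variants import PipelineVariant

from conftest import linear_table


class TestErrorMetrics:
    def test_identical_vectors(self):
        assert mae([1, 2], [1, 2]) == 0.0
        assert rmse([1, 2], [1, 2]) == 0.0

    def test_hand_values(self):
        assert mae([0.1, 0.2], [0.2, 0.4]) == pytest.approx(0.15)
        assert rmse([0.1, 0.2], [0.2, 0.4]) == pytest.approx(np.sqrt(0.025))

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, a = rng.normal(size=50), rng.normal(size=50)
            assert rmse(p, a) >= mae(p, a) >= 0.0

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            mae([1], [1, 2])
        with pytest.raises(ValueError):
            rmse([], [])


class TestCompareToBaseline:
    def test_signal_beats_baseline_every_cell(self, small_synthetic, fast_config,
                                              single_variant_registry):
        _, train, test, _, _ = small_synthetic
        suite = train_suite(train, single_variant_registry, fast_config,
                            compute_residuals=False)
        report = compare_to_baseline(suite, test, train)
        assert len(report) == 3
        assert (report["mae_model"] < report["mae_baseline"]).all()
        assert (report["mae_model"] <= report["rmse_model"] + 1e-12).all()
        # forest fits training data better than held-out data
        assert (report["mae_model_train"] <= report["mae_model"]).all()

    def test_pure_noise_matches_baseline(self, single_variant_registry):
        table = linear_table(600, 0.05, seed=1, pure_noise=True)
        train, test = split_dataset(table, 0.8, seed=1)
        tables = {("buccaneer", m): train for m in ("completeness", "R_work", "R_free")}
        test_tables = {("buccaneer", m): test for m in ("completeness", "R_work", "R_free")}
        suite = train_suite(tables, single_variant_registry,
                            ForestConfig(n_trees=256, seed=1), compute_residuals=False)
        report = compare_to_baseline(suite, test_tables)
        ratio = report["mae_model"] / report["mae_baseline"]
        assert (abs(ratio - 1.0) <= 0.10).all()


class TestAblation:
    def test_removing_the_only_informative_feature_degrades_to_baseline(self):
        """Two-feature table where only resolution carries signal: ablating it
        leaves the forest no better than Zero-R; ablating the noise feature
        leaves the error essentially unchanged."""
        from buildrank.evaluation import ablation
        from buildrank.training import TrainingTable

        rng = np.random.default_rng(7)
        n = 400
        frame = pd.DataFrame(
            {
                "dataset_id": [f"d{i}" for i in range(n)],
                "resolution": rng.uniform(1, 4, n),
                "noise_feat": rng.normal(size=n),
            }
        )
        frame["outcome"] = np.clip(1.4 - 0.3 * frame["resolution"], 0, 1) + rng.normal(0, 0.05, n)
        table = TrainingTable(frame, ["resolution", "noise_feat"])
        train, test = split_dataset(table, 0.8, seed=7)
        registry = [PipelineVariant(stages=("Buccaneer",))]
        tables_tr = {("buccaneer", m): train for m in ("completeness", "R_work", "R_free")}
        tables_te = {("buccaneer", m): test for m in ("completeness", "R_work", "R_free")}
        deltas = ablation(tables_tr, tables_te, registry, ForestConfig(n_trees=128, seed=7))
        per_feature = deltas.groupby("feature")["delta_mae"].mean()
        assert per_feature["resolution"] > 5 * max(per_feature["noise_feat"], 1e-9)
        assert abs(per_feature["noise_feat"]) < 0.01
        # with resolution gone, only noise remains: forest ~ baseline
        from buildrank.training import train_forest, zero_r

        noise_only = TrainingTable(
            train.frame[["dataset_id", "noise_feat", "outcome"]], ["noise_feat"]
        )
        noise_test = TrainingTable(
            test.frame[["dataset_id", "noise_feat", "outcome"]], ["noise_feat"]
        )
        forest_mae = mae(
            train_forest(noise_only, ForestConfig(n_trees=128, seed=7)).predict(noise_test.X),
            noise_test.y,
        )
        baseline_mae = mae(zero_r(noise_only).predict(noise_test.X), noise_test.y)
        assert forest_mae == pytest.approx(baseline_mae, rel=0.15)


class TestResolutionBins:
    def test_single_resolution_single_bin(self):
        frame = pd.DataFrame({"resolution": [2.0] * 5,
                              "predicted": [0.5] * 5, "actual": [0.6] * 5})
        report = resolution_binned_stats(frame)
        populated = report[report["n"] > 0]
        assert len(populated) == 1
        assert populated["n"].iloc[0] == 5

    def test_perfect_predictions_identical_stats(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 1, 40)
        frame = pd.DataFrame({"resolution": rng.uniform(1, 4, 40),
                              "predicted": values, "actual": values})
        report = resolution_binned_stats(frame, bin_width=0.5)
        populated = report[report["n"] > 0]
        np.testing.assert_allclose(populated["pred_mean"], populated["actual_mean"])
        pd.testing.assert_series_equal(populated["pred_sd"], populated["actual_sd"],
                                       check_names=False)

    def test_bins_partition_and_counts_sum(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame({"resolution": rng.uniform(1.0, 4.0, 200),
                              "predicted": rng.uniform(0, 1, 200),
                              "actual": rng.uniform(0, 1, 200)})
        report = resolution_binned_stats(frame, bin_width=0.1)
        assert report["n"].sum() == 200
        np.testing.assert_allclose(report["bin_low"].iloc[1:].to_numpy(),
                                   report["bin_high"].iloc[:-1].to_numpy())

    def test_decaying_completeness_gives_decreasing_bin_means(self):
        rng = np.random.default_rng(4)
        resolution = rng.uniform(1.0, 4.0, 500)
        actual = np.clip(1.3 - 0.3 * resolution, 0, 1) + rng.normal(0, 0.01, 500)
        frame = pd.DataFrame({"resolution": resolution, "predicted": actual,
                              "actual": actual})
        report = resolution_binned_stats(frame, bin_width=0.5)
        means = report[report["n"] > 5]["actual_mean"].to_numpy()
        assert (np.diff(means) < 0.05).all()  # decreasing within sampling noise


def make_report(widths, points, ids, measure="completeness", tolerance=0.05):
    frame = pd.DataFrame({"variant_id": ids, "measure": [measure] * len(ids),
                          "point": points, "width": widths})
    return ranked_report(frame, tolerance=tolerance)


class TestGroupHitRate:
    def test_single_group_always_hits(self):
        reports = {
            f"d{i}": make_report([0.1, 0.1, 0.1], [0.5, 0.6, 0.7], ["A", "B", "C"])
            for i in range(4)
        }
        actuals = pd.DataFrame(
            [{"dataset_id": f"d{i}", "variant_id": v, "outcome": 0.5}
             for i in range(4) for v in "ABC"]
        )
        assert group_hit_rate(reports, actuals) == 1.0

    def test_best_always_last_never_hits(self):
        # singleton groups; the variant with zero error is ranked last
        reports = {}
        actual_rows = []
        for i in range(3):
            reports[f"d{i}"] = make_report([0.05, 0.2, 0.8], [0.9, 0.8, 0.5],
                                           ["A", "B", "C"], tolerance=0.0)
            actual_rows += [
                {"dataset_id": f"d{i}", "variant_id": "A", "outcome": 0.2},
                {"dataset_id": f"d{i}", "variant_id": "B", "outcome": 0.2},
                {"dataset_id": f"d{i}", "variant_id": "C", "outcome": 0.5},
            ]
        assert group_hit_rate(reports, pd.DataFrame(actual_rows)) == 0.0

    def test_datasets_without_outcomes_excluded(self):
        reports = {
            "good": make_report([0.1], [0.5], ["A"]),
            "orphan": make_report([0.1], [0.5], ["A"]),
        }
        actuals = pd.DataFrame([{"dataset_id": "good", "variant_id": "A", "outcome": 0.5}])
        assert group_hit_rate(reports, actuals) == 1.0


class TestWithinK:
    def test_perfect_recommender(self):
        actuals = pd.DataFrame(
            [{"dataset_id": f"d{i}", "variant_id": v, "outcome": o}
             for i in range(5) for v, o in (("A", 0.9), ("B", 0.5))]
        )
        fractions = within_k_analysis({f"d{i}": "A" for i in range(5)}, actuals,
                                      "completeness", thresholds=(0.0, 0.01, 0.05))
        assert fractions == {0.0: 1.0, 0.01: 1.0, 0.05: 1.0}

    def test_r_factor_best_is_minimum(self):
        actuals = pd.DataFrame(
            [{"dataset_id": "d0", "variant_id": "A", "outcome": 0.25},
             {"dataset_id": "d0", "variant_id": "B", "outcome": 0.31}]
        )
        assert within_k_analysis({"d0": "A"}, actuals, "R_free")[0.01] == 1.0
        assert within_k_analysis({"d0": "B"}, actuals, "R_free")[0.05] == 0.0

    def test_random_recommender_among_separated_variants(self):
        """Variants separated by > 0.05: a uniformly random pick lands within
        k=0.05 of the best with probability ~ 1/|variants|."""
        rng = np.random.default_rng(5)
        n, variants = 2000, ["A", "B", "C", "D"]
        rows, recommended = [], {}
        for i in range(n):
            base = rng.uniform(0.1, 0.5)
            outcomes = {v: base + j * 0.08 for j, v in enumerate(variants)}
            rows += [{"dataset_id": f"d{i}", "variant_id": v, "outcome": o}
                     for v, o in outcomes.items()]
            recommended[f"d{i}"] = rng.choice(variants)
        fractions = within_k_analysis(recommended, pd.DataFrame(rows), "completeness")
        assert fractions[0.05] == pytest.approx(1 / len(variants), abs=0.03)

    def test_fractions_cumulative_in_k(self):
        rng = np.random.default_rng(6)
        rows, recommended = [], {}
        for i in range(100):
            outcomes = rng.uniform(0, 1, 3)
            rows += [{"dataset_id": f"d{i}", "variant_id": v, "outcome": o}
                     for v, o in zip("ABC", outcomes)]
            recommended[f"d{i}"] = rng.choice(list("ABC"))
        fractions = within_k_analysis(recommended, pd.DataFrame(rows), "completeness",
                                      thresholds=(0.0, 0.01, 0.05, 0.1, 0.5, 1.0))
        values = [fractions[k] for k in sorted(fractions)]
        assert values == sorted(values)
        assert fractions[1.0] == 1.0
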