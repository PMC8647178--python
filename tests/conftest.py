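import numpy as np
import pandas as pd
import pytest

from buildrank.synthetic import OutcomeGeneratorSpec, make_outcome_table
from buildrank.training import ForestConfig, TrainingTable, split_ids
from buildrank.variants import PipelineVariant

FEATURES = ["resolution", "rmsd", "skew", "max_density", "min_density"]


def linear_table(n, sigma, seed, slope=-0.3, intercept=1.4, pure_noise=False):
    """Outcome = clamp(intercept + slope*resolution) + N(0, sigma) over random features."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "dataset_id": [f"d{i:05d}" for i in range(n)],
            "resolution": rng.uniform(1.0, 4.0, n),
            "rmsd": rng.uniform(0.1, 0.4, n),
            "skew": rng.uniform(0.0, 0.4, n),
            "max_density": rng.uniform(2.0, 10.0, n),
            "min_density": rng.uniform(-2.0, 0.0, n),
        }
    )
    if pure_noise:
        truth = np.full(n, 0.5)
    else:
        truth = np.clip(intercept + slope * frame["resolution"].to_numpy(), 0.0, 1.0)
    frame["outcome"] = truth + rng.normal(0.0, sigma, n)
    return TrainingTable(frame, list(FEATURES))


@pytest.fixture(scope="session")
def single_variant_registry():
    return [PipelineVariant(stages=("Buccaneer",))]


@pytest.fixture(scope="session")
def small_synthetic(single_variant_registry):
    """300 datasets, one variant, all three measures, split 80/20."""
    data = make_outcome_table(OutcomeGeneratorSpec(seed=11), 300, registry=single_variant_registry)
    train_ids, test_ids = split_ids(data.features["dataset_id"], 0.8, seed=11)
    train = {k: t.subset(train_ids) for k, t in data.tables.items()}
    test = {k: t.subset(test_ids) for k, t in data.tables.items()}
    return data, train, test, train_ids, test_ids


@pytest.fixture(scope="session")
def fast_config():
    return ForestConfig(n_trees=64, seed=5)
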