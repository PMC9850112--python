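import math

import pytest

from sgccanet.preprocess import (beta_to_mvalue, filter_missing_features, knn_impute,
                                 scale_block_by_first_eigenvalue)
from sgccanet.synthetic_data import SimConfig, generate_multiomics

OMICS = ("cpg", "transcript", "mirna")


def recovery_sparsity(config: SimConfig):
    """l1 budget 10% inside sqrt(planted size): absorbs estimation-noise leakage."""
    return [min(1.0, 0.9 * math.sqrt(k / p))
            for k, p in zip(config.planted_block_size, config.block_dims)]


def preprocess_blocks(dataset, k: int = 10):
    cpg = beta_to_mvalue(knn_impute(filter_missing_features(dataset.blocks["cpg"]), k))
    blocks = [cpg, dataset.blocks["transcript"], dataset.blocks["mirna"]]
    return [scale_block_by_first_eigenvalue(b) for b in blocks]


def planted_union(dataset):
    truth = dataset.truth["planted"]
    out = set()
    for o in OMICS:
        for feats in truth[o].values():
            out.update(feats)
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """Fast dataset for unit-level checks: 60 samples, blocks 60/50/20."""
    return generate_multiomics(SimConfig(
        seed=5, n_samples_per_group=30, block_dims=(60, 50, 20),
        planted_block_size=(6, 6, 4), n_prior_edges=6))


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard recovery conditions: n=100, blocks 200/150/50, planted
    10/10/5, signal ratio 3, fixed seed."""
    return generate_multiomics(SimConfig(seed=11))


@pytest.fixture(scope="session")
def standard_blocks(standard_dataset):
    return preprocess_blocks(standard_dataset)


@pytest.fixture(scope="session")
def mi_dataset():
    """Larger-n dataset (n=200) for MI threshold calibration checks."""
    return generate_multiomics(SimConfig(seed=23, n_samples_per_group=100))
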