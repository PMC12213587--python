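import numpy as np
import pytest

from bingogs.synthetic_fixtures import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def mini_dataset():
    """Small dataset reused across read-only tests."""
    cfg = SimConfig(n_samples=150, n_markers=1000, n_genes=20, n_terms=8,
                    qtn_count=15, h2=0.7, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def mini_geno(mini_dataset):
    return mini_dataset["geno"]


@pytest.fixture(scope="session")
def mini_y(mini_dataset):
    return mini_dataset["pheno"].values[:, 0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
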