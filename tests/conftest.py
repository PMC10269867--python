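import numpy as np
import pandas as pd
import pytest

from aviphylosym import synthetic_data
from aviphylosym.core_io import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def star_tree():
    """Eight tips radiating from the root with unit branches."""
    return parse_newick("(" + ",".join(f"t{i}:1" for i in range(8)) + ");")


@pytest.fixture
def random_tree_factory():
    def make(n_tips, seed, prefix="t"):
        return synthetic_data.simulate_host_tree(n_tips, seed=seed, prefix=prefix)

    return make


@pytest.fixture
def small_dataset():
    """A compact simulated survey shared by integration-style tests."""
    host = synthetic_data.simulate_host_tree(12, seed=7)
    config = synthetic_data.SimulationConfig(
        n_species=12,
        samples_per_species=3,
        n_asvs=80,
        body_sites=("blood", "cloaca"),
        phylosymbiosis_signal=0.8,
        seed=7,
    )
    table, meta, asv_tree = synthetic_data.simulate_feature_table(host, config)
    return host, table, meta, asv_tree, config


def random_table(rng, n_samples=6, n_asvs=10, max_count=50, prefix="asv"):
    counts = rng.integers(0, max_count, size=(n_samples, n_asvs))
    counts[:, 0] += 1  # no empty samples
    return pd.DataFrame(
        counts,
        index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id"),
        columns=[f"{prefix}{i + 1:04d}" for i in range(n_asvs)],
    )
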