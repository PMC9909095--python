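"""Shared fixtures: small trees, count tables and metadata frames.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

import microbiogeo as mb


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — 3 tips, total branch length 5."""
    return mb.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def quartet_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — balanced quartet, A-C distance 4."""
    return mb.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_counts():
    """Deterministic 6-taxon x 4-sample count table."""
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        rng.integers(0, 50, size=(6, 4)),
        index=[f"T{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(4)],
    )
    data.iloc[0] += 1  # guarantee nonzero columns
    return mb.CountTable(data.astype(np.int64))


@pytest.fixture
def metadata_frame():
    """8 stations x 6 depths metadata from the environment generator."""
    cfg = mb.ScenarioConfig(n_taxa=10, seed=5)
    return mb.simulate_environment(cfg)


def random_count_table(rng, n_taxa=12, n_samples=5, max_count=100):
    data = rng.integers(0, max_count, size=(n_taxa, n_samples))
    data[rng.integers(n_taxa), :] += 1
    return mb.CountTable(
        pd.DataFrame(
            data.astype(np.int64),
            index=[f"T{i:03d}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )
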