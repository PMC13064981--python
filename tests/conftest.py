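import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from grnas.experiments import prepare_graph
from grnas.graph_data import sample_negatives, split_edges
from grnas.io_preprocess import PreprocessConfig
from grnas.synthetic import SimulationConfig, simulate_bundle


@pytest.fixture
def preprocess_cfg():
    return PreprocessConfig()


@pytest.fixture(scope="session")
def small_bundle():
    """A small planted bundle: 12 TFs, 80 targets, 200 cells."""
    cfg = SimulationConfig(
        n_tfs=12, n_targets=80, n_cells=200, mean_out_degree=5, dropout_prob=0.3, seed=42
    )
    grn, x = simulate_bundle(cfg)
    return cfg, grn, x


@pytest.fixture(scope="session")
def small_graph(small_bundle):
    _, grn, x = small_bundle
    return prepare_graph(x, list(grn.edges), set(grn.tf_ids))


@pytest.fixture(scope="session")
def small_split(small_graph):
    split = split_edges(small_graph, mode="random", seed=0)
    return sample_negatives(small_graph, split, neg_ratio=1, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
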