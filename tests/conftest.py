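import networkx as nx
import numpy as np
import pytest

import netsig as ns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def hand_survival():
    """8 subjects, binary covariate, distinct times, mixed censoring."""
    time = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0])
    event = np.array([1, 0, 1, 1, 0, 1, 1, 0])
    x = np.array([1.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0])
    return x, time, event


@pytest.fixture
def small_synthetic():
    """Compact planted-module cohort for pipeline-level tests."""
    cfg = ns.SyntheticConfig(
        n_genes=120, n_samples=120,
        planted_modules=[ns.PlantedModule() for _ in range(4)],
        seed=42)
    net, expr, truth = ns.generate(cfg)
    return cfg, net, expr, truth


@pytest.fixture
def weighted_two_cliques():
    """Two disjoint 4-cliques with uniform weight 0.9."""
    net = nx.Graph()
    for grp in (["A1", "A2", "A3", "A4"], ["B1", "B2", "B3", "B4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                net.add_edge(grp[i], grp[j], weight=0.9, pcc=0.9)
    return net
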