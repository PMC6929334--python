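import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dnlc.io import ClinicalTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def path_graph():
    """a - b - c - d."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return g


@pytest.fixture
def star_tail_graph():
    """4-node star (hub h, leaves x/y/z) with a tail t hanging off x."""
    g = nx.Graph()
    g.add_edges_from([("h", "x"), ("h", "y"), ("h", "z"), ("x", "t")])
    return g


def random_connected_graph(rng, n_nodes, p=0.25):
    """Random connected simple graph with string node labels."""
    while True:
        seed = int(rng.integers(0, 2**31 - 1))
        g = nx.gnp_random_graph(n_nodes, p, seed=seed)
        if nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})


@pytest.fixture
def small_expression(rng):
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{j}" for j in range(10)]
    return pd.DataFrame(
        rng.normal(size=(20, 10)), index=genes, columns=samples
    )


def binary_clinical(outcome):
    outcome = np.asarray(outcome, dtype=float)
    return ClinicalTable(
        sample_ids=[f"s{i}" for i in range(len(outcome))],
        outcome_type="binary",
        outcome=outcome,
    )
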