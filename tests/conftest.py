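import networkx as nx
import numpy as np
import pytest

from netpharm.graph_io import GeneSet
from netpharm.synthetic_data import SimConfig, gen_interactome


@pytest.fixture
def path_graph():
    """a - b - c chain with unit weights."""
    g = nx.Graph()
    g.add_edge("a", "b", weight=1.0)
    g.add_edge("b", "c", weight=1.0)
    return g


@pytest.fixture
def triangle_graph():
    g = nx.Graph()
    for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
        g.add_edge(u, v, weight=1.0)
    return g


@pytest.fixture
def small_interactome():
    """120-node scale-free graph for association-scale tests."""
    return gen_interactome(SimConfig(n_nodes=120, edges_per_node=2, seed=7))


@pytest.fixture
def geneset():
    return lambda name, members: GeneSet(name, frozenset(members))


def pearson_oracle(x, y):
    """Independent Pearson correlation for cross-checks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(np.corrcoef(x, y)[0, 1])
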