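import networkx as nx
import numpy as np
import pytest

from pamod.graph import ScoredNetwork


def make_net(edges, scores=None, pvalues=None, extra_nodes=()):
    """Small ScoredNetwork from an edge list and optional per-gene scores."""
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    net = ScoredNetwork(g)
    if pvalues is not None:
        net.set_pvalues(pvalues)
    if scores is not None:
        arr = np.zeros(net.n_nodes)
        for gene, s in scores.items():
            arr[net.index_of(gene)] = s
        net.scores = arr
    return net


@pytest.fixture
def path5():
    """Path a-b-c-d-e."""
    return make_net([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


def sample_bum(n, a, lam, rng):
    """Draw n p-values from the beta-uniform mixture by inverse transform."""
    isnull = rng.random(n) < lam
    p = np.where(isnull, rng.random(n), rng.random(n) ** (1.0 / a))
    return np.clip(p, 1e-300, 1.0)
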