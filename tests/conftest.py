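import networkx as nx
import numpy as np
import pytest

from lccd.graph_core import karate_fixture, two_cliques_bridge


@pytest.fixture(scope="session")
def karate():
    return karate_fixture()


@pytest.fixture
def two_cliques():
    return two_cliques_bridge(4)


def random_graph(seed: int, n: int = 20, p: float = 0.2) -> nx.Graph:
    """Seeded Erdos-Renyi graph with string labels, for oracle tests."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(str(i) for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(str(i), str(j))
    return g


def all_pairs_oracle(g: nx.Graph):
    """All-pairs hop distances via scipy's Floyd-Warshall (independent of BFS)."""
    from scipy.sparse.csgraph import floyd_warshall

    nodes = sorted(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in g.edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
    d = floyd_warshall(a, unweighted=True)
    return nodes, idx, d
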