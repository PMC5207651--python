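import networkx as nx
import numpy as np
import pytest

from lccd.centrality import node_density, structural_centrality
from lccd.expansion import (
    Community,
    ExpansionOptions,
    Partition,
    density_gain,
    detect_communities,
    expand_community,
    subgraph_density,
)
from lccd.graph_core import two_cliques_bridge

from conftest import random_graph


def _community(g, members, rho, cid=0, center=None):
    members = frozenset(members)
    m = g.subgraph(members).number_of_edges()
    return Community(cid, center, members, m, float(sum(rho[v] for v in members)))


class TestSubgraphDensity:
    def test_single_node_is_zero(self, karate):
        rho = node_density(karate, 1)
        assert subgraph_density(karate, {"1"}, rho) == 0.0

    def test_whole_graph_is_half(self, karate):
        rho = node_density(karate, 1)
        assert subgraph_density(karate, set(karate.nodes), rho) == 0.5

    def test_embedded_clique(self):
        # 3-clique a-b-c with pendant edges bringing total degree to 10
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("a", "x"), ("a", "y"), ("b", "z"), ("c", "w")])
        rho = node_density(g, 1)
        assert subgraph_density(g, {"a", "b", "c"}, rho) == pytest.approx(3 / 10)


class TestDensityGain:
    def test_member_rejected(self, karate):
        rho = node_density(karate, 1)
        c = _community(karate, {"1", "2"}, rho)
        with pytest.raises(ValueError):
            density_gain(karate, c, "2", rho)

    def test_no_edges_into_community_negative(self):
        g = two_cliques_bridge(4)
        rho = node_density(g, 1)
        c = _community(g, {"a1", "a2", "a3"}, rho)
        # b2 has no edge into the community: denominator grows, numerator fixed
        assert density_gain(g, c, "b2", rho) < 0

    def test_zero_density_isolated_node_gain_is_zero(self):
        g = two_cliques_bridge(4)
        g.add_node("iso")
        rho = node_density(g, 1)
        c = _community(g, {"a1", "a2", "a3"}, rho)
        assert density_gain(g, c, "iso", rho) == 0.0

    def test_second_endpoint_positive_from_singleton(self):
        g = nx.Graph([("a", "b")])
        rho = node_density(g, 1)
        c = _community(g, {"a"}, rho)
        assert density_gain(g, c, "b", rho) > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_incremental_equals_from_scratch(self, seed):
        g = random_graph(seed, n=20, p=0.2)
        rng = np.random.default_rng(seed)
        rho = node_density(g, 1)
        nodes = sorted(g.nodes)
        members = set(rng.choice(nodes, size=rng.integers(1, 10), replace=False))
        c = _community(g, members, rho)
        for v in nodes:
            if v in members:
                continue
            expected = subgraph_density(g, members | {v}, rho) - subgraph_density(
                g, members, rho
            )
            assert density_gain(g, c, v, rho) == pytest.approx(expected, abs=1e-12)


class TestExpandCommunity:
    def test_bridged_cliques_stop_at_bridge(self):
        g = two_cliques_bridge(4)
        rho = node_density(g, 1)
        comm = expand_community(g, "a2", set(g.nodes), rho)
        assert comm.members == {"a1", "a2", "a3", "a4"}

    def test_whole_clique_absorbed(self):
        g = nx.relabel_nodes(nx.complete_graph(5), str)
        rho = node_density(g, 1)
        comm = expand_community(g, "0", set(g.nodes), rho)
        assert comm.members == set(g.nodes)
        assert comm.density == 0.5

    def test_center_must_be_unclassified(self, karate):
        rho = node_density(karate, 1)
        with pytest.raises(ValueError):
            expand_community(karate, "1", set(karate.nodes) - {"1"}, rho)

    def test_termination_is_local_maximum(self, karate):
        rho = node_density(karate, 1)
        unclassified = set(karate.nodes)
        comm = expand_community(karate, "34", unclassified, rho)
        outside = unclassified - comm.members
        for v in outside:
            if any(w in comm.members for w in karate.neighbors(v)):
                assert density_gain(karate, comm, v, rho) <= 0


class TestDetectCommunities:
    def test_two_triangles(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
        p = detect_communities(g)
        assert sorted(map(sorted, p.as_sets())) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_partition_covers_graph_disjointly(self, karate):
        p = detect_communities(karate)
        assert set(p.assignment) == set(karate.nodes)
        sets = p.as_sets()
        assert sum(len(s) for s in sets) == 34
        for c in p.communities:
            assert nx.is_connected(karate.subgraph(c.members))
            if c.center is not None:
                assert c.center in c.members
            assert 0.0 <= c.density <= 0.5

    def test_karate_centers_present(self, karate):
        p = detect_communities(karate)
        centers = {c.center for c in p.communities}
        assert {"34", "1"} <= centers

    @pytest.mark.parametrize("seed", range(3))
    def test_deterministic_under_node_permutation(self, seed):
        g = random_graph(seed, n=30, p=0.15)
        rng = np.random.default_rng(seed + 100)
        shuffled = nx.Graph()
        nodes, edges = list(g.nodes), list(g.edges)
        rng.shuffle(nodes)
        rng.shuffle(edges)
        shuffled.add_nodes_from(nodes)
        shuffled.add_edges_from(edges)
        p1 = detect_communities(g, epsilon=1.0)
        p2 = detect_communities(shuffled, epsilon=1.0)
        assert sorted(map(sorted, p1.as_sets())) == sorted(map(sorted, p2.as_sets()))

    def test_zero_centers_is_an_error(self, karate):
        with pytest.warns(UserWarning):
            with pytest.raises(RuntimeError, match="epsilon"):
                detect_communities(karate, epsilon=1000.0)

    def test_recheck_and_zero_gain_options_run(self, karate):
        for opts in (
            ExpansionOptions(accept_zero_gain=True),
            ExpansionOptions(recheck_members=True),
        ):
            p = detect_communities(karate, options=opts)
            assert set(p.assignment) == set(karate.nodes)


class TestPartitionFromAssignment:
    def test_counts(self, two_cliques):
        assignment = {v: v[0] for v in two_cliques.nodes}
        p = Partition.from_assignment(two_cliques, assignment)
        assert len(p) == 2
        for c in p.communities:
            assert c.internal_edges == 6
            assert c.rho_sum == 13  # 4-clique degrees 3+3+3+4 (bridge endpoint)
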