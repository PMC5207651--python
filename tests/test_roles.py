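import networkx as nx
import numpy as np
import pytest

from lccd.centrality import node_density
from lccd.expansion import Partition
from lccd.graph_core import two_cliques_bridge
from lccd.roles import assign_roles, border_density, border_region

from conftest import random_graph


def three_cliques_bridge():
    """Two 3-cliques joined by one bridge; densities 2 except endpoints 3."""
    g = nx.Graph([("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                  ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                  ("a1", "b1")])
    part = Partition.from_assignment(g, {v: v[0] for v in g.nodes})
    return g, part


class TestBorderRegion:
    def test_whole_graph_has_empty_border(self, karate):
        part = Partition.from_assignment(karate, {v: 0 for v in karate.nodes})
        assert border_region(karate, part, 0, d_c=1) == set()

    def test_bridge_endpoints_only_at_dc1(self, two_cliques):
        part = Partition.from_assignment(two_cliques, {v: v[0] for v in two_cliques.nodes})
        cid_a = part.assignment["a1"]
        assert border_region(two_cliques, part, cid_a, d_c=1) == {"a1"}

    def test_dc2_extends_to_in_clique_neighbours(self, two_cliques):
        part = Partition.from_assignment(two_cliques, {v: v[0] for v in two_cliques.nodes})
        cid_a = part.assignment["a1"]
        assert border_region(two_cliques, part, cid_a, d_c=2) == {"a1", "a2", "a3", "a4"}

    def test_unknown_community_rejected(self, two_cliques):
        part = Partition.from_assignment(two_cliques, {v: v[0] for v in two_cliques.nodes})
        with pytest.raises(KeyError):
            border_region(two_cliques, part, 99)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_cutoff(self, seed):
        g = random_graph(seed, n=20, p=0.15)
        part = Partition.from_assignment(g, {v: int(v) % 3 for v in g.nodes})
        for cid in range(3):
            prev = set()
            for d_c in (1, 2, 3):
                cur = border_region(g, part, cid, d_c)
                assert prev <= cur
                prev = cur


class TestBorderDensity:
    def test_empty_border_is_zero(self, karate):
        part = Partition.from_assignment(karate, {v: 0 for v in karate.nodes})
        rho = node_density(karate, 1)
        assert border_density(karate, part, 0, rho) == 0.0

    def test_pair_average_on_bridged_triangles(self):
        g, part = three_cliques_bridge()
        rho = node_density(g, 1)
        cid = part.assignment["a1"]
        assert border_density(g, part, cid, rho, variant="pair_average") == 3.0

    def test_region_max_on_bridged_triangles(self):
        g, part = three_cliques_bridge()
        rho = node_density(g, 1)
        cid = part.assignment["a1"]
        assert border_density(g, part, cid, rho, variant="region_max") == 3.0

    @pytest.mark.parametrize("seed", range(4))
    def test_region_max_matches_brute_force(self, seed):
        g = random_graph(seed, n=20, p=0.15)
        part = Partition.from_assignment(g, {v: int(v) % 3 for v in g.nodes})
        rho = node_density(g, 1)
        import networkx as nx

        spl = dict(nx.all_pairs_shortest_path_length(g))
        for cid in range(3):
            members = {v for v, c in part.assignment.items() if c == cid}
            region = {
                v
                for v in members
                for w in g.nodes
                if w not in members and spl[v].get(w, 99) <= 1
            }
            expected = max((rho[v] for v in region), default=0)
            assert border_density(g, part, cid, rho, variant="region_max") == expected


class TestAssignRoles:
    def test_single_community_all_cores(self, karate):
        part = Partition.from_assignment(karate, {v: 0 for v in karate.nodes})
        rho = node_density(karate, 1)
        labels = assign_roles(karate, part, rho)
        assert all(r == "core" for r in labels.role.values())

    def test_two_community_graph_with_hub_border_and_outlier(self):
        # a community whose densest member sits on the border: the border
        # density equals that hub's density, members at least as dense are
        # cores, a pendant straggler is an outlier
        g = nx.Graph([
            ("1", "3"), ("1", "4"), ("1", "5"), ("1", "8"), ("3", "4"),
            ("3", "5"), ("4", "5"), ("3", "8"), ("4", "8"),
            ("2", "6"), ("2", "7"), ("6", "7"), ("5", "2"),
        ])
        part = Partition.from_assignment(
            g, {"1": 0, "3": 0, "4": 0, "5": 0, "8": 0, "2": 1, "6": 1, "7": 1}
        )
        rho = node_density(g, 1)
        labels = assign_roles(g, part, rho, variant="region_max")
        # node 5 bridges to the other community and is the densest border node
        assert labels.border_density[0] == rho["5"]
        assert labels.role["3"] == "core" and labels.role["4"] == "core"
        assert labels.role["8"] == "outlier"

    def test_bridged_cliques_pair_average(self, two_cliques):
        part = Partition.from_assignment(two_cliques, {v: v[0] for v in two_cliques.nodes})
        rho = node_density(two_cliques, 1)
        labels = assign_roles(two_cliques, part, rho, variant="pair_average")
        # bridge endpoints have the maximal density (4) and set rho_b = 4
        assert labels.role["a1"] == "core" and labels.role["b1"] == "core"
        # inner clique nodes have density 3 < rho_b
        assert labels.role["a2"] == "outlier"

    @pytest.mark.parametrize("variant", ["pair_average", "region_max"])
    @pytest.mark.parametrize("seed", range(3))
    def test_cores_and_outliers_partition_each_community(self, seed, variant):
        g = random_graph(seed, n=25, p=0.15)
        part = Partition.from_assignment(g, {v: int(v) % 4 for v in g.nodes})
        rho = node_density(g, 1)
        labels = assign_roles(g, part, rho, variant=variant)
        assert set(labels.role) == set(g.nodes)
        for c in part.communities:
            cores = {v for v in c.members if labels.role[v] == "core"}
            outliers = {v for v in c.members if labels.role[v] == "outlier"}
            assert cores | outliers == set(c.members)
            assert not cores & outliers
            rb = labels.border_density[c.id]
            for v in c.members:
                assert (rho[v] >= rb) == (labels.role[v] == "core")
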