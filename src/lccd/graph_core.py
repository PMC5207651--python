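"""Graph representation, file I/O, geodesic distances, and test fixtures.

All algorithms in this package operate on simple, undirected, unweighted
graphs with string node labels, carried as :class:`networkx.Graph`
instances. Readers clean dirty input (self-loops, duplicate edges) rather
than rejecting it, and disconnected graphs are accepted — cross-component
distances are reported as unreachable.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from ._order import natural_key, sorted_nodes

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceTable",
    "read_graph",
    "write_edgelist",
    "read_partition_file",
    "write_partition_file",
    "geodesic_distances",
    "bounded_distances",
    "karate_fixture",
]


class GraphFormatError(ValueError):
    """A graph file did not parse in the requested format."""


def _clean(g: nx.Graph) -> nx.Graph:
    """Coerce to a simple undirected graph with string labels.

    Self-loops and duplicate edges are dropped silently (with a logged
    count); node labels are preserved as strings.
    """
    out = nx.Graph()
    out.add_nodes_from(str(v) for v in g.nodes)
    loops = 0
    dupes = 0
    for u, v in g.edges():
        u, v = str(u), str(v)
        if u == v:
            loops += 1
            continue
        if out.has_edge(u, v):
            dupes += 1
            continue
        out.add_edge(u, v)
    if loops or dupes:
        logger.info("dropped %d self-loop(s) and %d duplicate edge(s)", loops, dupes)
    return out


def _parse_edgelist(path: Path) -> nx.Graph:
    g = nx.MultiGraph()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two whitespace-separated "
                    f"node labels, got {raw.strip()!r}"
                )
            g.add_edge(parts[0], parts[1])
    return g


def read_graph(path, format: str = "edgelist") -> nx.Graph:
    """Read a simple undirected graph from ``edgelist``, ``gml`` or ``graphml``.

    Self-loops and duplicate edges in the source are dropped (count
    logged); node labels are preserved as strings. '#' comments are
    allowed in edge lists.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"graph file not found: {path}")
    if format == "edgelist":
        raw = _parse_edgelist(path)
    elif format == "gml":
        try:
            raw = nx.read_gml(path, label="label")
        except Exception as exc:  # nx raises several parser error types
            raise GraphFormatError(f"{path}: not valid GML ({exc})") from exc
    elif format == "graphml":
        try:
            raw = nx.read_graphml(path)
        except Exception as exc:
            raise GraphFormatError(f"{path}: not valid GraphML ({exc})") from exc
    else:
        raise ValueError(f"unknown graph format: {format!r}")
    return _clean(raw)


def write_edgelist(g: nx.Graph, path) -> None:
    """Write one ``u v`` pair per line, in deterministic label order."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u in sorted_nodes(g.nodes):
            for v in sorted_nodes(g.neighbors(u)):
                if natural_key(u) < natural_key(v):
                    fh.write(f"{u} {v}\n")


def read_partition_file(path) -> dict[str, str]:
    """Read a two-column TSV ``node <TAB-or-space> community_id`` table."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"partition file not found: {path}")
    assignment: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line or line.lower().startswith("node"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 'node community_id', got {raw.strip()!r}"
                )
            assignment[parts[0]] = parts[1]
    return assignment


def write_partition_file(assignment: Mapping[str, object], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node\tcommunity_id\n")
        for v in sorted_nodes(assignment):
            fh.write(f"{v}\t{assignment[v]}\n")


@dataclass(frozen=True)
class DistanceTable:
    """Geodesic (hop-count) distances from one source node.

    ``distances`` maps each *reachable* node to its distance in hops;
    nodes absent from the map are unreachable, which every consumer in
    this package treats as larger than any finite distance.
    """

    source: str
    distances: dict[str, int] = field(repr=False)

    def __getitem__(self, node: str) -> int:
        return self.distances[node]

    def get(self, node: str, default=None):
        return self.distances.get(node, default)

    def reachable(self) -> set[str]:
        return set(self.distances)

    def eccentricity(self) -> int:
        """Largest finite distance from the source (0 for isolated nodes)."""
        return max(self.distances.values())


def geodesic_distances(g: nx.Graph, source: str) -> DistanceTable:
    """Breadth-first shortest-path hop counts from ``source``."""
    if source not in g:
        raise KeyError(f"source node {source!r} not in graph")
    return DistanceTable(source, dict(nx.single_source_shortest_path_length(g, source)))


def bounded_distances(adj: Mapping[str, set], source: str, cutoff: int) -> dict[str, int]:
    """BFS distances from ``source`` truncated at ``cutoff`` hops.

    ``adj`` is an adjacency mapping node -> set of neighbours; used in the
    hot loops where building nx views per call would dominate.
    """
    dist = {source: 0}
    if cutoff <= 0:
        return dist
    frontier = deque([source])
    d = 0
    while frontier and d < cutoff:
        d += 1
        for _ in range(len(frontier)):
            u = frontier.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = d
                    frontier.append(w)
    return dist


# Zachary's karate club: 34 members of a university karate club observed
# 1970-72; the club split into two factions around the administrator
# (node 1) and the instructor (node 34). The canonical 78-edge version,
# 1-based numbering.
_KARATE_EDGES = (
    "2 1;3 1;3 2;4 1;4 2;4 3;5 1;6 1;7 1;7 5;7 6;8 1;8 2;8 3;8 4;9 1;9 3;"
    "10 3;11 1;11 5;11 6;12 1;13 1;13 4;14 1;14 2;14 3;14 4;17 6;17 7;18 1;"
    "18 2;20 1;20 2;22 1;22 2;26 24;26 25;28 3;28 24;28 25;29 3;30 24;30 27;"
    "31 2;31 9;32 1;32 25;32 26;32 29;33 3;33 9;33 15;33 16;33 19;33 21;"
    "33 23;33 24;33 30;33 31;33 32;34 9;34 10;34 14;34 15;34 16;34 19;34 20;"
    "34 21;34 23;34 24;34 27;34 28;34 29;34 30;34 31;34 32;34 33"
)


def karate_fixture() -> nx.Graph:
    """The Zachary karate club graph: 34 nodes "1".."34", 78 edges.

    Node 1 is the club administrator and node 34 the instructor — the two
    poles of the split the network famously documents.
    """
    g = nx.Graph()
    g.add_nodes_from(str(i) for i in range(1, 35))
    for pair in _KARATE_EDGES.split(";"):
        u, v = pair.split()
        g.add_edge(u, v)
    return g


def two_cliques_bridge(k: int = 4) -> nx.Graph:
    """Two k-cliques joined by a single bridge edge — a toy fixture.

    Nodes ``a1..ak`` and ``b1..bk``; the bridge joins ``a1`` and ``b1``.
    """
    g = nx.Graph()
    a = [f"a{i}" for i in range(1, k + 1)]
    b = [f"b{i}" for i in range(1, k + 1)]
    for grp in (a, b):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(grp[i], grp[j])
    g.add_edge("a1", "b1")
    return g
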