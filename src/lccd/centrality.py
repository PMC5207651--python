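"""Node density, relative distance, and structural centrality.

The structural centrality of a node combines two quantities computed from
hop distances on the graph:

* density ``rho(i)``: the number of nodes within the cutoff distance
  ``d_c`` of ``i`` (with the default ``d_c = 1`` this is the degree);
* relative distance ``delta(i)``: the hop distance from ``i`` to the
  nearest strictly denser node; the densest node of a component instead
  takes its largest finite distance (its eccentricity).

Their product ``sc = rho * delta`` is large only for nodes that are both
locally dense and far from anything denser — the "structural centers"
that seed communities.

Density ties are resolved by a deterministic total order (density, then
numeric-aware label order), so "strictly denser" is a strict total order
and each connected component has exactly one density maximum.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx
import pandas as pd

from ._order import natural_key, sorted_nodes
from .graph_core import bounded_distances

__all__ = [
    "CutoffPolicy",
    "CentralityTable",
    "node_density",
    "auto_cutoff",
    "relative_distance",
    "structural_centrality",
    "decision_graph_export",
]


@dataclass(frozen=True)
class CutoffPolicy:
    """How the cutoff distance ``d_c`` is chosen.

    ``fixed`` uses ``value`` (default 1, the rule of thumb under which
    density reduces to degree). ``auto`` picks the smallest hop radius at
    which the mean neighbourhood size reaches 1% of the network.
    """

    mode: Literal["fixed", "auto"] = "fixed"
    value: int = 1

    def __post_init__(self):
        if self.mode not in ("fixed", "auto"):
            raise ValueError(f"unknown cutoff mode {self.mode!r}")
        if self.mode == "fixed" and self.value < 1:
            raise ValueError("fixed cutoff distance must be >= 1")

    def resolve(self, g: nx.Graph) -> int:
        return self.value if self.mode == "fixed" else auto_cutoff(g)


def node_density(g: nx.Graph, d_c: int = 1) -> dict[str, int]:
    """Number of nodes within ``d_c`` hops of each node (excluding itself).

    With ``d_c = 1`` this is exactly the degree. Unreachable nodes never
    contribute.
    """
    if d_c < 1:
        raise ValueError("cutoff distance d_c must be >= 1")
    if d_c == 1:
        return {v: g.degree(v) for v in g.nodes}
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    return {v: len(bounded_distances(adj, v, d_c)) - 1 for v in g.nodes}


def auto_cutoff(g: nx.Graph) -> int:
    """Smallest ``d_c`` at which mean neighbourhood size reaches 1% of n.

    The scan is capped at the largest finite eccentricity, beyond which
    neighbourhoods stop growing; ``d_c = 1`` is returned whenever the mean
    degree already satisfies the rule.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("auto cutoff needs a graph with at least 2 nodes")
    target = 0.01 * n
    cap = 1
    for comp in nx.connected_components(g):
        if len(comp) > 1:
            cap = max(cap, nx.diameter(g.subgraph(comp)))
    for d in range(1, cap + 1):
        rho = node_density(g, d)
        if sum(rho.values()) / n >= target:
            return d
    return cap


def relative_distance(
    g: nx.Graph, rho: Mapping[str, int]
) -> dict[str, tuple[int, str | None]]:
    """Hop distance from each node to its nearest strictly denser node.

    Returns ``node -> (delta, nearest_higher)``. "Strictly denser" uses
    the tie-broken total order (rho, then label), so exactly one node per
    connected component — its density maximum — has no denser node; it
    takes ``delta`` equal to its eccentricity within the component and
    ``nearest_higher = None``. An isolated node takes ``delta = 1`` by
    convention (its ``sc`` is 0 regardless, since ``rho = 0``).
    """
    missing = [v for v in g.nodes if v not in rho]
    if missing:
        raise KeyError(f"density missing for node(s): {missing[:5]}")
    # rank in the strict density order: lower rank = denser
    by_order = sorted(g.nodes, key=lambda v: (-rho[v], natural_key(v)))
    rank = {v: i for i, v in enumerate(by_order)}
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    out: dict[str, tuple[int, str | None]] = {}
    for v in g.nodes:
        rv = rank[v]
        # layered BFS with early stop at the first layer containing a
        # denser node; most nodes stop at depth 1
        seen = {v}
        frontier = [v]
        depth = 0
        found: str | None = None
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        nxt.append(w)
            if not nxt:
                depth -= 1  # last non-empty layer = eccentricity
                break
            denser = [w for w in nxt if rank[w] < rv]
            if denser:
                found = min(denser, key=lambda w: rank[w])
                break
            frontier = nxt
        if found is not None:
            out[v] = (depth, found)
        else:
            # component density maximum (or isolated node: depth 0 -> 1)
            out[v] = (max(depth, 1), None)
    return out


@dataclass(frozen=True)
class CentralityTable:
    """Per-node density, relative distance, structural centrality.

    ``sc[v] == rho[v] * delta[v]`` for every node; ``nearest_higher[v]``
    is the denser node realising ``delta[v]`` (None for each component's
    density maximum).
    """

    d_c: int
    rho: dict[str, int] = field(repr=False)
    delta: dict[str, int] = field(repr=False)
    sc: dict[str, float] = field(repr=False)
    nearest_higher: dict[str, str | None] = field(repr=False)

    def __len__(self) -> int:
        return len(self.rho)

    def nodes_by_sc(self) -> list[str]:
        """Nodes in descending (sc, rho, label) order — the decision ranking."""
        return sorted(
            self.rho, key=lambda v: (-self.sc[v], -self.rho[v], natural_key(v))
        )

    def to_frame(self) -> pd.DataFrame:
        order = self.nodes_by_sc()
        return pd.DataFrame(
            {
                "node": order,
                "rho": [self.rho[v] for v in order],
                "delta": [self.delta[v] for v in order],
                "sc": [self.sc[v] for v in order],
                "rank_by_sc": range(1, len(order) + 1),
            }
        )


def structural_centrality(
    g: nx.Graph, policy: CutoffPolicy | int = CutoffPolicy()
) -> CentralityTable:
    """Compute the full per-node centrality table for a graph."""
    if isinstance(policy, int):
        policy = CutoffPolicy("fixed", policy)
    d_c = policy.resolve(g)
    rho = node_density(g, d_c)
    rel = relative_distance(g, rho)
    delta = {v: rel[v][0] for v in g.nodes}
    nearest = {v: rel[v][1] for v in g.nodes}
    sc = {v: float(rho[v] * delta[v]) for v in g.nodes}
    return CentralityTable(d_c=d_c, rho=rho, delta=delta, sc=sc, nearest_higher=nearest)


def decision_graph_export(table: CentralityTable, path) -> None:
    """Write the decision-graph data (node, rho, delta, sc, rank) as CSV."""
    table.to_frame().to_csv(path, index=False)
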