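"""Core / outlier classification via community border regions.

A member of a community is a *border node* if some node of another
community lies within ``d_c`` hops of it. The border region fixes a
density level ``rho_b`` for the community; members at least that dense
are *cores*, the rest *outliers*. Two variants of ``rho_b`` are offered:

* ``pair_average`` (default): the maximum over cross-boundary pairs
  ``(v in C, w not in C, dist <= d_c)`` of ``(rho(v) + rho(w)) / 2``;
* ``region_max``: the maximum density within the border region itself.

The two disagree in general; both are exposed rather than silently
picking one. A community with an empty border region (e.g. a whole
connected component) has ``rho_b = 0`` and every member is a core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx
import pandas as pd

from ._order import sorted_nodes
from .expansion import Partition
from .graph_core import bounded_distances

__all__ = ["RoleLabels", "border_region", "border_density", "assign_roles"]

BorderVariant = Literal["pair_average", "region_max"]


@dataclass(frozen=True)
class RoleLabels:
    """Per-node core/outlier role plus per-community border summaries."""

    role: dict[str, str] = field(repr=False)
    border_density: dict[int, float] = field(repr=False)
    border_region: dict[int, set[str]] = field(repr=False)

    def cores(self, cid: int | None = None, partition: Partition | None = None) -> set[str]:
        if cid is None:
            return {v for v, r in self.role.items() if r == "core"}
        assert partition is not None
        return {v for v in partition.communities[cid].members if self.role[v] == "core"}

    def to_frame(self, partition: Partition, rho: Mapping[str, float]) -> pd.DataFrame:
        rows = [
            (v, partition.assignment[v], self.role[v], rho[v])
            for v in sorted_nodes(self.role)
        ]
        return pd.DataFrame(rows, columns=["node", "community_id", "role", "rho"])


def _cross_pairs(g, members: frozenset, d_c: int):
    """Yield (v, w, dist) with v in the community, w outside, dist <= d_c."""
    adj = {u: set(g.neighbors(u)) for u in g.nodes}
    for v in members:
        for w, d in bounded_distances(adj, v, d_c).items():
            if w not in members and d >= 1:
                yield v, w, d


def border_region(g: nx.Graph, partition: Partition, cid: int, d_c: int = 1) -> set[str]:
    """Members of community ``cid`` within ``d_c`` of another community."""
    comm = _get(partition, cid)
    return {v for v, _, _ in _cross_pairs(g, comm.members, d_c)}


def border_density(
    g: nx.Graph,
    partition: Partition,
    cid: int,
    rho: Mapping[str, float],
    d_c: int = 1,
    variant: BorderVariant = "pair_average",
) -> float:
    """The density level rho_b of community ``cid`` (0 for empty borders)."""
    comm = _get(partition, cid)
    if variant == "pair_average":
        best = 0.0
        for v, w, _ in _cross_pairs(g, comm.members, d_c):
            pair = (rho[v] + rho[w]) / 2.0
            if pair > best:
                best = pair
        return best
    if variant == "region_max":
        region = border_region(g, partition, cid, d_c)
        return max((float(rho[v]) for v in region), default=0.0)
    raise ValueError(f"unknown border-density variant {variant!r}")


def assign_roles(
    g: nx.Graph,
    partition: Partition,
    rho: Mapping[str, float],
    d_c: int = 1,
    variant: BorderVariant = "pair_average",
) -> RoleLabels:
    """Label every assigned node core (rho >= rho_b) or outlier (rho < rho_b)."""
    role: dict[str, str] = {}
    rb: dict[int, float] = {}
    regions: dict[int, set[str]] = {}
    for comm in partition.communities:
        cid = comm.id
        rb[cid] = border_density(g, partition, cid, rho, d_c, variant)
        regions[cid] = border_region(g, partition, cid, d_c)
        for v in comm.members:
            role[v] = "core" if rho[v] >= rb[cid] else "outlier"
    return RoleLabels(role=role, border_density=rb, border_region=regions)


def _get(partition: Partition, cid: int):
    for comm in partition.communities:
        if comm.id == cid:
            return comm
    raise KeyError(f"no community with id {cid!r}")
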