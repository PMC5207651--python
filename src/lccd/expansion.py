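"""Greedy community expansion around structural centers.

Each community starts as its center and grows by repeatedly adding the
neighbouring node whose inclusion most increases the sub-graph density

    D_C = m_C / sum_{i in C} rho(i)

(the number of internal edges over the summed densities of the members;
with d_c = 1 the denominator is the total degree, so D_C is at most 1/2
and reaches it only when the community has no outgoing edge). Expansion
stops when no neighbour passes the acceptance rule, yielding a local
maximum of D_C. Centers are processed in descending structural
centrality, each expansion claiming only still-unclassified nodes; a
completion pass then assigns any leftovers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import networkx as nx

from ._order import natural_key, sorted_nodes
from .centrality import CentralityTable, CutoffPolicy, structural_centrality
from .centers import CenterSet, MergeRule, locate_centers, select_threshold

__all__ = [
    "Community",
    "refine_partition",
    "Partition",
    "ExpansionOptions",
    "subgraph_density",
    "density_gain",
    "expand_community",
    "grow_partition",
    "detect_communities",
]


@dataclass(frozen=True)
class Community:
    """One detected community: its seed center and member set."""

    id: int
    center: str | None
    members: frozenset[str]
    internal_edges: int
    rho_sum: float

    @property
    def density(self) -> float:
        """Sub-graph density D_C = internal edges / summed member density."""
        return self.internal_edges / self.rho_sum if self.rho_sum > 0 else 0.0

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Partition:
    """Disjoint communities covering (after completion) the whole graph."""

    communities: tuple[Community, ...]
    assignment: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.communities)

    def community_of(self, node: str) -> int:
        return self.assignment[node]

    def as_sets(self) -> list[set[str]]:
        return [set(c.members) for c in self.communities]

    @classmethod
    def from_assignment(cls, g: nx.Graph, assignment: Mapping[str, object]) -> "Partition":
        """Build a partition (with edge counts) from a node -> label map."""
        labels = sorted({str(c) for c in assignment.values()}, key=natural_key)
        index = {lab: i for i, lab in enumerate(labels)}
        groups: dict[int, set[str]] = {i: set() for i in index.values()}
        for v, lab in assignment.items():
            groups[index[str(lab)]].add(v)
        comms = []
        for cid in sorted(groups):
            members = groups[cid]
            m = sum(1 for u, v in g.edges(members) if u in members and v in members)
            rho_sum = sum(g.degree(v) for v in members)
            comms.append(Community(cid, None, frozenset(members), m, float(rho_sum)))
        return cls(tuple(comms), {v: index[str(lab)] for v, lab in assignment.items()})


def subgraph_density(g: nx.Graph, members: Iterable[str], rho: Mapping[str, float]) -> float:
    """D_C of a member set: internal edge count over summed densities."""
    members = set(members)
    m = g.subgraph(members).number_of_edges()
    denom = sum(rho[v] for v in members)
    return m / denom if denom > 0 else 0.0


def density_gain(
    g: nx.Graph, community: Community, v: str, rho: Mapping[str, float]
) -> float:
    """Change in D_C from adding ``v``, computed incrementally."""
    if v in community.members:
        raise ValueError(f"node {v!r} is already a member")
    e = sum(1 for w in g.neighbors(v) if w in community.members)
    m, s = community.internal_edges, community.rho_sum
    before = m / s if s > 0 else 0.0
    after_denom = s + rho[v]
    after = (m + e) / after_denom if after_denom > 0 else 0.0
    return after - before


@dataclass(frozen=True)
class ExpansionOptions:
    """Knobs of the greedy expansion.

    ``accept_zero_gain`` also admits zero-gain additions (the literal
    break-on-negative reading of the expansion loop); the default demands
    strictly positive gain so D_C increases monotonically.
    ``recheck_members`` re-tests members after every addition and ejects
    any whose removal would raise D_C (never the center, and never when
    ejection would disconnect the community).
    """

    accept_zero_gain: bool = False
    recheck_members: bool = False


def expand_community(
    g: nx.Graph,
    center: str,
    unclassified: set[str],
    rho: Mapping[str, float],
    options: ExpansionOptions = ExpansionOptions(),
    community_id: int = 0,
) -> Community:
    """Grow one community greedily from ``center`` over unclassified nodes."""
    if center not in unclassified:
        raise ValueError(f"center {center!r} is not unclassified")
    members: set[str] = {center}
    m = 0
    s = float(rho[center])
    # frontier: unclassified non-member -> number of edges into the community
    frontier: dict[str, int] = {}
    for w in g.neighbors(center):
        if w in unclassified:
            frontier[w] = 1

    def gain_of(v: str, e: int) -> float:
        before = m / s if s > 0 else 0.0
        denom = s + rho[v]
        after = (m + e) / denom if denom > 0 else 0.0
        return after - before

    while frontier:
        best_v, best_gain, best_e = None, None, -1
        for v, e in frontier.items():
            gv = gain_of(v, e)
            if (
                best_v is None
                or gv > best_gain
                or (gv == best_gain and (e > best_e or (e == best_e and natural_key(v) < natural_key(best_v))))
            ):
                best_v, best_gain, best_e = v, gv, e
        accept = best_gain > 0 or (options.accept_zero_gain and best_gain == 0)
        if not accept:
            break
        v = best_v
        members.add(v)
        m += frontier.pop(v)
        s += rho[v]
        for w in g.neighbors(v):
            if w in members:
                continue
            if w in unclassified:
                frontier[w] = frontier.get(w, 0) + 1
        if options.recheck_members and len(members) > 2:
            if _recheck(g, center, members, rho):
                # ejections invalidate all cached edge counts: rebuild
                m = g.subgraph(members).number_of_edges()
                s = float(sum(rho[u] for u in members))
                frontier = {}
                for u in members:
                    for w in g.neighbors(u):
                        if w not in members and w in unclassified:
                            frontier[w] = frontier.get(w, 0) + 1
    return Community(community_id, center, frozenset(members), m, s)


def _recheck(g, center, members, rho) -> bool:
    """Eject members whose removal raises D_C (connectivity-preserving)."""
    ejected = False
    changed = True
    while changed:
        changed = False
        m = g.subgraph(members).number_of_edges()
        s = sum(rho[u] for u in members)
        d_now = m / s if s > 0 else 0.0
        for u in sorted_nodes(members):
            if u == center or len(members) <= 2:
                continue
            e_u = sum(1 for w in g.neighbors(u) if w in members)
            s_wo = s - rho[u]
            d_wo = (m - e_u) / s_wo if s_wo > 0 else 0.0
            if d_wo > d_now:
                trial = members - {u}
                if nx.is_connected(g.subgraph(trial)):
                    members.discard(u)
                    ejected = True
                    changed = True
                    break
    return ejected


CompletionRule = Literal["reseed", "density_chain", "none"]


def refine_partition(
    g: nx.Graph,
    assignment: dict[str, int],
    rho: Mapping[str, float],
    max_sweeps: int = 20,
) -> dict[str, int]:
    """Fixpoint cleanup of a complete partition under the D_C objective.

    A node mis-captured during greedy growth (typically in the early
    steps of an expansion, when D_C is still near zero and barely
    discriminates) is detectable afterwards: removing it raises its own
    community's density. Each sweep moves every such node to the
    neighbouring community for which its addition gain is largest, if
    that gain is positive and the move neither empties nor disconnects
    the donor community. Every move raises the density of both
    communities involved, so the procedure terminates; sweeps repeat
    until no move fires (bounded by ``max_sweeps``).
    """
    assignment = dict(assignment)
    m_c: dict[int, int] = {}
    s_c: dict[int, float] = {}
    members: dict[int, set[str]] = {}
    for v, c in assignment.items():
        s_c[c] = s_c.get(c, 0.0) + rho[v]
        members.setdefault(c, set()).add(v)
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            m_c[assignment[u]] = m_c.get(assignment[u], 0) + 1
    for c in s_c:
        m_c.setdefault(c, 0)

    order = sorted(assignment, key=lambda v: (-rho[v], natural_key(v)))
    for _ in range(max_sweeps):
        moved = False
        for v in order:
            a = assignment[v]
            if len(members[a]) <= 1:
                continue
            e_to: dict[int, int] = {}
            for w in g.neighbors(v):
                e_to[assignment[w]] = e_to.get(assignment[w], 0) + 1
            e_a = e_to.get(a, 0)
            d_a = m_c[a] / s_c[a] if s_c[a] > 0 else 0.0
            s_wo = s_c[a] - rho[v]
            d_wo = (m_c[a] - e_a) / s_wo if s_wo > 0 else 0.0
            if d_wo <= d_a:
                continue
            best_b, best_gain, best_e = None, 0.0, -1
            for b, e_b in e_to.items():
                if b == a:
                    continue
                d_b = m_c[b] / s_c[b] if s_c[b] > 0 else 0.0
                denom = s_c[b] + rho[v]
                gain = (m_c[b] + e_b) / denom - d_b if denom > 0 else 0.0
                if gain > best_gain or (gain == best_gain and e_b > best_e):
                    best_b, best_gain, best_e = b, gain, e_b
            if best_b is None or best_gain <= 0:
                continue
            rest = members[a] - {v}
            if e_a > 0 and not nx.is_connected(g.subgraph(rest)):
                continue
            members[a].discard(v)
            members[best_b].add(v)
            assignment[v] = best_b
            m_c[a] -= e_a
            s_c[a] -= rho[v]
            m_c[best_b] += e_to[best_b]
            s_c[best_b] += rho[v]
            moved = True
        if not moved:
            break
    return assignment


def grow_partition(
    g: nx.Graph,
    table: CentralityTable,
    centers: CenterSet,
    options: ExpansionOptions = ExpansionOptions(),
    completion: CompletionRule = "reseed",
    refine: bool = True,
) -> Partition:
    """Expand every center in descending sc order, then complete the cover.

    Each expansion sees only still-unclassified nodes, so communities are
    disjoint by construction. A center swallowed by an earlier expansion
    no longer seeds a community of its own.

    Unclassified leftovers are then handled by the completion rule. The
    default ``reseed`` repeats the locate-and-expand cycle on the
    subgraph induced by the leftovers — communities whose centers were
    hidden in the full decision graph (their peaks sit next to denser
    nodes of other communities) become separable once the already-claimed
    nodes are removed — until no further centers can be located. Any
    stragglers, and everything under ``density_chain``, are assigned in
    descending density: each joins the community of its nearest denser
    node (the ``nearest_higher`` chain), falling back to the majority
    community among its neighbours, and finally to a fresh singleton.
    """
    rho = table.rho
    unclassified = set(g.nodes)
    communities: list[Community] = []
    for c in centers:
        if c not in unclassified:
            continue
        comm = expand_community(
            g, c, unclassified, rho, options, community_id=len(communities)
        )
        communities.append(comm)
        unclassified -= comm.members

    if completion == "reseed":
        while unclassified:
            sub = g.subgraph(unclassified)
            sub_table = structural_centrality(sub, CutoffPolicy("fixed", table.d_c))
            if all(s == 0 for s in sub_table.sc.values()):
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                eps = select_threshold(sub_table, method="gap")
                sub_centers = locate_centers(sub, sub_table, eps, d_c=table.d_c)
            if sub_centers.k == 0:
                break
            claimed = 0
            for c in sub_centers:
                if c not in unclassified:
                    continue
                comm = expand_community(
                    sub, c, unclassified, sub_table.rho, options,
                    community_id=len(communities),
                )
                communities.append(comm)
                unclassified -= comm.members
                claimed += len(comm.members)
            if claimed == 0:
                break

    assignment: dict[str, int] = {}
    for comm in communities:
        for v in comm.members:
            assignment[v] = comm.id

    if completion in ("reseed", "density_chain") and unclassified:
        extra: dict[int, set[str]] = {}
        order = sorted(unclassified, key=lambda v: (-rho[v], natural_key(v)))
        for v in order:
            cid: int | None = None
            nh = table.nearest_higher[v]
            if nh is not None and nh in assignment:
                cid = assignment[nh]
            else:
                votes: dict[int, int] = {}
                for w in g.neighbors(v):
                    if w in assignment:
                        votes[assignment[w]] = votes.get(assignment[w], 0) + 1
                if votes:
                    cid = min(votes, key=lambda c: (-votes[c], c))
            if cid is None:
                cid = len(communities) + len(extra)
                extra[cid] = set()
            assignment[v] = cid
            if cid in extra:
                extra[cid].add(v)
            # membership of pre-existing communities is rebuilt below

    if refine:
        assignment = refine_partition(g, assignment, rho)

    # (re)build communities from the final assignment
    groups: dict[int, set[str]] = {}
    for v, cid in assignment.items():
        groups.setdefault(cid, set()).add(v)
    center_of = {c.id: c.center for c in communities}
    rebuilt = []
    renumber: dict[int, int] = {}
    for cid in sorted(groups):
        members = groups[cid]
        m = g.subgraph(members).number_of_edges()
        s = float(sum(rho[v] for v in members))
        center = center_of.get(cid)
        if center is not None and center not in members:
            center = None  # the seed itself was moved during refinement
        renumber[cid] = len(rebuilt)
        rebuilt.append(
            Community(renumber[cid], center, frozenset(members), m, s)
        )
    return Partition(
        tuple(rebuilt), {v: renumber[cid] for v, cid in assignment.items()}
    )


def detect_communities(
    g: nx.Graph,
    cutoff: CutoffPolicy | int = CutoffPolicy(),
    epsilon: float | None = None,
    epsilon_method: Literal["gap", "quantile", "manual"] = "gap",
    merge_rule: MergeRule = "leq",
    options: ExpansionOptions = ExpansionOptions(),
    completion: CompletionRule = "reseed",
    refine: bool = True,
) -> Partition:
    """Full pipeline: centrality -> centers -> expansion -> completion."""
    table = structural_centrality(g, cutoff)
    auto_epsilon = epsilon is None
    if auto_epsilon:
        epsilon = select_threshold(table, method=epsilon_method)
    centers = locate_centers(g, table, epsilon, d_c=table.d_c, merge_rule=merge_rule)
    if centers.k == 0 and auto_epsilon:
        # degenerate decision graph (e.g. every sc equal, as in a vertex-
        # transitive graph): fall back to a threshold just below the
        # maximum, letting the merge step pick one center per region
        max_sc = max(table.sc.values(), default=0.0)
        if max_sc > 0:
            warnings.warn(
                "threshold selection found no separable centers; falling "
                "back to the maximum-centrality nodes",
                stacklevel=2,
            )
            centers = locate_centers(
                g, table, max_sc * (1 - 1e-9), d_c=table.d_c, merge_rule=merge_rule
            )
    if centers.k == 0:
        raise RuntimeError(
            "no structural centers located; lower epsilon or use a different "
            "threshold method"
        )
    return grow_partition(g, table, centers, options=options,
                          completion=completion, refine=refine)
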