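"""Locating community structural centers.

Centers are selected in two steps: a threshold ``epsilon`` separates
candidate centers from the bulk of the sorted structural-centrality
sequence, then a descending scan keeps each candidate in turn as a center
and prunes remaining candidates too close to it, so that each community
contributes exactly one center.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx

from .centrality import CentralityTable
from .graph_core import bounded_distances

__all__ = ["CenterSet", "select_threshold", "locate_centers"]

MergeRule = Literal["leq", "strict_lt"]


@dataclass(frozen=True)
class CenterSet:
    """Ordered structural centers (descending sc) with the parameters used."""

    centers: list[str] = field(repr=True)
    epsilon_used: float = 0.0
    merge_rule: MergeRule = "leq"

    @property
    def k(self) -> int:
        return len(self.centers)

    def __iter__(self):
        return iter(self.centers)

    def __len__(self) -> int:
        return len(self.centers)


def select_threshold(
    table: CentralityTable,
    method: Literal["gap", "quantile", "manual"] = "gap",
    manual_value: float | None = None,
    quantile: float = 0.95,
) -> float:
    """Choose the center-selection threshold from the sc distribution.

    ``gap`` scans the descending positive-sc sequence for the largest
    multiplicative drop ``sc[r]/sc[r+1]`` among the head ranks
    ``r = 1..ceil(sqrt(n))`` and returns the midpoint of that gap —
    centers sit in the extreme head of the distribution, so searching
    deeper would only find drops in the noise tail. ``quantile`` returns
    the stated upper quantile of sc; ``manual`` echoes ``manual_value``.
    """
    if len(table) == 0:
        raise ValueError("cannot select a threshold from an empty centrality table")
    order = table.nodes_by_sc()
    sc = [table.sc[v] for v in order]
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual threshold selection requires a value")
        return float(manual_value)
    if method == "quantile":
        import numpy as np

        return float(np.quantile(sc, quantile))
    if method != "gap":
        raise ValueError(f"unknown threshold method {method!r}")

    positive = [s for s in sc if s > 0]
    if len(positive) < 2 or positive[0] == positive[-1]:
        warnings.warn(
            "all structural centralities are equal; no centers are separable",
            stacklevel=2,
        )
        return (positive[0] if positive else 0.0) + 1.0
    rmax = min(math.ceil(math.sqrt(len(table))), len(positive) - 1)
    best_r, best_ratio = 1, 0.0
    for r in range(1, rmax + 1):
        ratio = positive[r - 1] / positive[r]
        if ratio > best_ratio:
            best_r, best_ratio = r, ratio
    return (positive[best_r - 1] + positive[best_r]) / 2.0


def locate_centers(
    g: nx.Graph,
    table: CentralityTable,
    epsilon: float,
    d_c: int | None = None,
    merge_rule: MergeRule = "leq",
) -> CenterSet:
    """Scan candidates above ``epsilon`` in descending sc order.

    Each popped candidate becomes the next center; remaining candidates
    within the merge radius of it are discarded, so nodes clustered
    around an already-chosen center cannot spawn a second one. Under the
    default ``leq`` rule the radius is ``d_c`` inclusive (a center's
    ``d_c``-neighbourhood is pruned); ``strict_lt`` keeps candidates at
    distance exactly ``d_c``, which with ``d_c = 1`` prunes nothing.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if d_c is None:
        d_c = table.d_c
    if merge_rule not in ("leq", "strict_lt"):
        raise ValueError(f"unknown merge rule {merge_rule!r}")
    candidates = [
        v for v in table.nodes_by_sc() if table.sc[v] > epsilon
    ]  # already (sc desc, rho desc, label asc)
    if not candidates:
        warnings.warn("no candidate exceeds the threshold; zero centers located",
                      stacklevel=2)
        return CenterSet([], epsilon_used=float(epsilon), merge_rule=merge_rule)
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    radius = d_c if merge_rule == "leq" else d_c - 1
    centers: list[str] = []
    pool = list(candidates)
    while pool:
        c = pool.pop(0)
        centers.append(c)
        if radius >= 0:
            near = bounded_distances(adj, c, radius)
            pool = [v for v in pool if v not in near]
    return CenterSet(centers, epsilon_used=float(epsilon), merge_rule=merge_rule)
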