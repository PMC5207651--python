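"""Partition quality metrics: modularity and normalized mutual information.

Modularity compares the internal edge fraction of each community against
the degree-preserving random null model:

    Q = sum_c [ m_c / M - (d_c / 2M)^2 ]

with ``m_c`` the internal edge count and ``d_c`` the total degree of
community ``c`` — algebraically identical to the usual double sum over
ordered node pairs (diagonal included, ``P_ij = k_i k_j / 2M``).

NMI between two partitions is computed from their confusion matrix and
normalised by the arithmetic mean of the two partition entropies; it is
1 for identical partitions and 0 for independent ones.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .expansion import Partition

__all__ = ["modularity", "nmi", "confusion_matrix"]


def _as_assignment(p) -> dict[str, object]:
    if isinstance(p, Partition):
        return dict(p.assignment)
    if isinstance(p, Mapping):
        return dict(p)
    if isinstance(p, Sequence):  # list of node sets
        return {v: i for i, members in enumerate(p) for v in members}
    raise TypeError(f"cannot interpret {type(p).__name__} as a partition")


def modularity(g: nx.Graph, partition) -> float:
    """Newman modularity Q of a node partition of ``g``.

    ``partition`` may be a :class:`Partition`, a node -> label mapping, or
    a list of node sets covering the graph.
    """
    M = g.number_of_edges()
    if M < 1:
        raise ValueError("modularity is undefined for an edgeless graph")
    assignment = _as_assignment(partition)
    missing = [v for v in g.nodes if v not in assignment]
    if missing:
        raise ValueError(f"partition does not cover node(s): {missing[:5]}")
    m_c: dict[object, int] = {}
    deg_c: dict[object, float] = {}
    for v in g.nodes:
        deg_c[assignment[v]] = deg_c.get(assignment[v], 0.0) + g.degree(v)
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            m_c[assignment[u]] = m_c.get(assignment[u], 0) + 1
    return sum(
        m_c.get(c, 0) / M - (deg_c[c] / (2.0 * M)) ** 2 for c in deg_c
    )


def confusion_matrix(a, b) -> tuple[np.ndarray, list, list]:
    """Community-overlap counts N_ij between two partitions of one node set."""
    aa, bb = _as_assignment(a), _as_assignment(b)
    if set(aa) != set(bb):
        raise ValueError("partitions cover different node sets")
    rows = sorted({str(c) for c in aa.values()})
    cols = sorted({str(c) for c in bb.values()})
    ri = {c: i for i, c in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    N = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for v in aa:
        N[ri[str(aa[v])], ci[str(bb[v])]] += 1
    return N, rows, cols


def nmi(a, b) -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Symmetric and invariant under community relabeling; ``0 log 0`` terms
    are taken as 0. When both partitions are the trivial single cluster
    (both entropies zero) the partitions are identical and 1 is returned
    by convention.
    """
    N, _, _ = confusion_matrix(a, b)
    total = N.sum()
    ni = N.sum(axis=1)
    nj = N.sum(axis=0)
    num = 0.0
    for i in range(N.shape[0]):
        for j in range(N.shape[1]):
            if N[i, j] > 0:
                num += N[i, j] * math.log(N[i, j] * total / (ni[i] * nj[j]))
    num *= -2.0
    den = sum(x * math.log(x / total) for x in ni if x > 0) + sum(
        x * math.log(x / total) for x in nj if x > 0
    )
    if den == 0.0:
        # both partitions are a single all-in-one cluster: identical
        return 1.0
    return num / den
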