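"""Seeded synthetic benchmark graphs with planted community structure.

Two families are provided:

* **GN (planted partition)**: 128 nodes in four groups of 32, independent
  Bernoulli edges with within-group probability ``P_in`` and
  between-group probability ``P_out`` calibrated so the expected degree
  is ``z = 16`` and the mixing parameter ``mu = z_out / z`` is the
  expected fraction of a node's edges leaving its group.

* **LFR-style**: heterogeneous benchmarks with power-law degree
  distribution (exponent ``t1``, mean ``<k>``, cap ``maxk``) and
  power-law community sizes (exponent ``t2`` in ``[minc, maxc]``). Each
  node spends the fraction ``1 - mu`` of its degree inside its community;
  internal and external edge sets are realised by configuration-model
  stub matching with reshuffle/edge-swap repair to keep the graph simple.

Instances are fully reproducible from their integer seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from .expansion import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "GNParams",
    "LFRParams",
    "BenchmarkInstance",
    "GenerationError",
    "generate_gn",
    "generate_lfr",
    "realized_mixing",
    "sweep",
]


class GenerationError(RuntimeError):
    """The requested benchmark parameters could not be realised."""


@dataclass(frozen=True)
class BenchmarkInstance:
    """A synthetic graph together with its planted ground truth."""

    graph: nx.Graph
    planted: Partition
    realized_mixing: float


def realized_mixing(g: nx.Graph, assignment) -> float:
    """Fraction of edges joining different planted communities."""
    if isinstance(assignment, Partition):
        assignment = assignment.assignment
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    ext = sum(1 for u, v in g.edges if assignment[u] != assignment[v])
    return ext / m


# ---------------------------------------------------------------------------
# GN planted-partition benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GNParams:
    """Planted-partition parameters: 4 groups of 32, expected degree 16."""

    n: int = 128
    groups: int = 4
    mean_degree: float = 16.0
    mu: float = 0.1
    seed: int = 0

    @property
    def group_size(self) -> int:
        if self.n % self.groups:
            raise GenerationError("n must be divisible by the number of groups")
        return self.n // self.groups

    @property
    def p_in(self) -> float:
        return (1.0 - self.mu) * self.mean_degree / (self.group_size - 1)

    @property
    def p_out(self) -> float:
        return self.mu * self.mean_degree / (self.n - self.group_size)


def generate_gn(params: GNParams) -> BenchmarkInstance:
    """Sample one GN graph: Bernoulli edges at P_in within / P_out between."""
    if not 0.0 <= params.mu <= 1.0:
        raise GenerationError("mixing parameter mu must lie in [0, 1]")
    p_in, p_out = params.p_in, params.p_out
    if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
        raise GenerationError(
            f"edge probabilities outside [0,1]: P_in={p_in:.3f}, P_out={p_out:.3f}"
        )
    rng = np.random.default_rng(params.seed)
    n = params.n
    group = np.arange(n) // params.group_size
    u = rng.random((n, n))
    prob = np.where(group[:, None] == group[None, :], p_in, p_out)
    iu, ju = np.triu_indices(n, k=1)
    hit = u[iu, ju] < prob[iu, ju]
    g = nx.Graph()
    g.add_nodes_from(str(i + 1) for i in range(n))
    g.add_edges_from(
        (str(i + 1), str(j + 1)) for i, j in zip(iu[hit], ju[hit])
    )
    assignment = {str(i + 1): int(group[i]) for i in range(n)}
    planted = Partition.from_assignment(g, assignment)
    return BenchmarkInstance(g, planted, realized_mixing(g, assignment))


# ---------------------------------------------------------------------------
# LFR-style benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LFRParams:
    """Heterogeneous benchmark parameters (defaults: the 1000-node,
    small-community configuration: <k>=20, maxk=50, sizes in [10, 50])."""

    n: int = 1000
    mean_degree: float = 20.0
    maxk: int = 50
    minc: int = 10
    maxc: int = 50
    mu: float = 0.1
    t1: float = 2.0
    t2: float = 1.0
    seed: int = 0
    mixing_tol: float = 0.05
    max_retries: int = 100

    def __post_init__(self):
        if not (1 <= self.minc <= self.maxc <= self.n):
            raise GenerationError("community size bounds must satisfy 1 <= minc <= maxc <= n")
        if self.mean_degree > self.maxk:
            raise GenerationError("mean degree cannot exceed the maximum degree")
        if not 0.0 <= self.mu <= 1.0:
            raise GenerationError("mixing parameter mu must lie in [0, 1]")


def _powerlaw_mean(a: float, b: float, t: float) -> float:
    """Mean of the continuous power law x^-t truncated to [a, b]."""
    if abs(t - 1.0) < 1e-12:
        return (b - a) / math.log(b / a)
    if abs(t - 2.0) < 1e-12:
        return math.log(b / a) / (1.0 / a - 1.0 / b)
    c1, c2 = 1.0 - t, 2.0 - t
    return (c1 / c2) * (b**c2 - a**c2) / (b**c1 - a**c1)


def _powerlaw_sample(rng, size: int, a: float, b: float, t: float) -> np.ndarray:
    """Inverse-CDF samples of the truncated power law x^-t on [a, b]."""
    u = rng.random(size)
    if abs(t - 1.0) < 1e-12:
        return a * (b / a) ** u
    c1 = 1.0 - t
    return (a**c1 + u * (b**c1 - a**c1)) ** (1.0 / c1)


def _degree_sequence(rng, p: LFRParams) -> np.ndarray:
    """Power-law degrees calibrated to the requested mean, even total."""
    lo, hi = 1.0, float(p.maxk) - 1e-9
    if _powerlaw_mean(lo, p.maxk, p.t1) >= p.mean_degree:
        a = lo
    else:
        # bisection for the lower truncation point giving the target mean
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _powerlaw_mean(mid, p.maxk, p.t1) < p.mean_degree:
                lo = mid
            else:
                hi = mid
        a = 0.5 * (lo + hi)
    deg = np.clip(np.rint(_powerlaw_sample(rng, p.n, a, p.maxk, p.t1)), 1, p.maxk)
    deg = deg.astype(np.int64)
    if deg.sum() % 2:
        cand = np.flatnonzero(deg < p.maxk)
        deg[rng.choice(cand)] += 1
    return deg


def _community_sizes(rng, p: LFRParams) -> list[int]:
    """Power-law community sizes in [minc, maxc] summing exactly to n."""
    for _ in range(p.max_retries):
        sizes: list[int] = []
        while sum(sizes) < p.n:
            s = int(np.clip(np.rint(
                _powerlaw_sample(rng, 1, p.minc, p.maxc, p.t2)[0]), p.minc, p.maxc))
            sizes.append(s)
        excess = sum(sizes) - p.n
        shrinkable = [i for i, s in enumerate(sizes) if s > p.minc]
        for _ in range(excess):
            shrinkable = [i for i, s in enumerate(sizes) if s > p.minc]
            if not shrinkable:
                break
            sizes[int(rng.choice(shrinkable))] -= 1
        if sum(sizes) == p.n:
            return sizes
    raise GenerationError("could not realise community sizes summing to n")


def _assign_nodes(rng, deg_int: np.ndarray, sizes: list[int], retries: int) -> np.ndarray:
    """Place each node in a community large enough for its internal degree."""
    n = len(deg_int)
    order = np.argsort(-deg_int, kind="stable")
    for _ in range(retries):
        slots = np.array(sizes, dtype=np.int64)
        comm = np.full(n, -1, dtype=np.int64)
        ok = True
        for v in order:
            feasible = np.flatnonzero((slots > 0) & (np.array(sizes) - 1 >= deg_int[v]))
            if len(feasible) == 0:
                ok = False
                break
            weights = slots[feasible].astype(float)
            comm[v] = rng.choice(feasible, p=weights / weights.sum())
            slots[comm[v]] -= 1
        if ok:
            return comm
    raise GenerationError("could not fit internal degrees into community sizes")


def _match_stubs(stubs: list[int], rng, edges: set, same_forbidden=None,
                 max_sweeps: int = 80) -> list[int]:
    """Pair stubs into simple edges; returns the stubs it had to drop.

    Repeatedly shuffles the unpaired stubs, accepting pairs that create
    neither self-loops, duplicate edges, nor (when ``same_forbidden`` is
    given) intra-forbidden pairs; stubborn leftovers are resolved by
    double-edge swaps against edges placed by this same call, so a
    phase can never rewire edges laid down by another phase (which would
    silently shift the internal/external split).
    """
    leftover = list(stubs)
    new_edges: set[tuple[int, int]] = set()
    for _ in range(max_sweeps):
        if not leftover:
            break
        rng.shuffle(leftover)
        bad: list[int] = []
        for i in range(0, len(leftover) - 1, 2):
            u, v = leftover[i], leftover[i + 1]
            key = (u, v) if u < v else (v, u)
            if u == v or key in edges or (same_forbidden and same_forbidden(u, v)):
                bad.append(u)
                bad.append(v)
            else:
                edges.add(key)
                new_edges.add(key)
        if len(leftover) % 2:
            bad.append(leftover[-1])
        if len(bad) == len(leftover):
            break  # no progress: go to swap repair
        leftover = bad
    # targeted repair: consume leftover stubs two at a time via edge swaps
    dropped: list[int] = []
    pool = list(new_edges)
    leftover_iter = list(leftover)
    while len(leftover_iter) >= 2:
        u = leftover_iter.pop()
        v = leftover_iter.pop()
        done = False
        for _ in range(200):
            if not pool:
                break
            x, y = pool[int(rng.integers(len(pool)))]
            kxy = (x, y) if x < y else (y, x)
            if kxy not in edges:
                continue
            for a, b in ((x, y), (y, x)):
                ku = (u, a) if u < a else (a, u)
                kv = (v, b) if v < b else (b, v)
                if (
                    u != a and v != b and ku not in edges and kv not in edges
                    and not (same_forbidden and (same_forbidden(u, a) or same_forbidden(v, b)))
                ):
                    edges.discard(kxy)
                    new_edges.discard(kxy)
                    edges.add(ku)
                    edges.add(kv)
                    new_edges.add(ku)
                    new_edges.add(kv)
                    pool = list(new_edges)
                    done = True
                    break
            if done:
                break
        if not done:
            dropped.extend([u, v])
    dropped.extend(leftover_iter)
    return dropped


def generate_lfr(params: LFRParams) -> BenchmarkInstance:
    """Sample one LFR-style benchmark instance (seeded, reproducible)."""
    root = np.random.SeedSequence(params.seed)
    last_err: Exception | None = None
    for attempt, ss in enumerate(root.spawn(max(params.max_retries // 10, 3))):
        rng = np.random.default_rng(ss)
        try:
            inst = _generate_lfr_once(rng, params)
        except GenerationError as exc:
            last_err = exc
            continue
        if abs(inst.realized_mixing - params.mu) <= params.mixing_tol:
            return inst
        last_err = GenerationError(
            f"realized mixing {inst.realized_mixing:.3f} outside "
            f"{params.mu} +/- {params.mixing_tol}"
        )
    raise GenerationError(f"LFR generation failed after retries: {last_err}")


def _generate_lfr_once(rng, p: LFRParams) -> BenchmarkInstance:
    deg = _degree_sequence(rng, p)
    sizes = _community_sizes(rng, p)
    deg_int = np.floor((1.0 - p.mu) * deg).astype(np.int64)
    # a node's internal degree cannot exceed the largest community minus
    # itself; the excess becomes external (matters only near mu = 0 when
    # maxk approaches maxc)
    deg_int = np.minimum(deg_int, max(sizes) - 1)
    comm = _assign_nodes(rng, deg_int, sizes, retries=10)

    members: dict[int, list[int]] = {}
    for v, c in enumerate(comm):
        members.setdefault(int(c), []).append(v)

    # per-community parity fix on internal stubs (keeps total degree fixed)
    for c, mem in members.items():
        if deg_int[mem].sum() % 2:
            size = len(mem)
            up = [v for v in mem if deg_int[v] < min(deg[v], size - 1)]
            if up:
                deg_int[up[int(rng.integers(len(up)))]] += 1
            else:
                down = [v for v in mem if deg_int[v] > 0]
                deg_int[down[int(rng.integers(len(down)))]] -= 1

    edges: set[tuple[int, int]] = set()
    dropped = 0
    for c, mem in members.items():
        stubs = [v for v in mem for _ in range(int(deg_int[v]))]
        dropped += len(_match_stubs(stubs, rng, edges))

    deg_ext = deg - deg_int
    if deg_ext.sum() % 2:
        cand = np.flatnonzero(deg_ext > 0)
        deg_ext[cand[int(rng.integers(len(cand)))]] -= 1
    ext_stubs = [v for v in range(p.n) for _ in range(int(deg_ext[v]))]
    dropped += len(
        _match_stubs(ext_stubs, rng, edges, same_forbidden=lambda u, v: comm[u] == comm[v])
    )
    if dropped:
        logger.debug("LFR generation dropped %d stub(s)", dropped)

    g = nx.Graph()
    g.add_nodes_from(str(v + 1) for v in range(p.n))
    g.add_edges_from((str(u + 1), str(v + 1)) for u, v in edges)
    assignment = {str(v + 1): int(comm[v]) for v in range(p.n)}
    planted = Partition.from_assignment(g, assignment)
    return BenchmarkInstance(g, planted, realized_mixing(g, assignment))


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------


def sweep(
    generator: Callable[[float, int], BenchmarkInstance],
    mu_grid,
    reps: int,
    detector: Callable[[nx.Graph], Partition],
    metric: Callable[[Partition, Partition], float],
    seed: int = 0,
) -> pd.DataFrame:
    """Average a detection metric over replicate benchmark instances.

    For each ``mu`` in the grid, ``reps`` instances are generated from
    seeds derived deterministically from ``seed``; the detector runs on
    each and the metric compares its partition with the planted one.
    Detector failures are recorded as missing rather than aborting the
    sweep.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    ss = np.random.SeedSequence(seed)
    for mu in mu_grid:
        values = []
        failures = 0
        for child in ss.spawn(reps):
            inst_seed = int(child.generate_state(1)[0] % (2**31))
            try:
                inst = generator(float(mu), inst_seed)
                part = detector(inst.graph)
                values.append(metric(part, inst.planted))
            except Exception as exc:  # recorded, not fatal
                logger.warning("detector failed at mu=%s: %s", mu, exc)
                failures += 1
        arr = np.asarray(values, dtype=float)
        rows.append(
            {
                "mu": float(mu),
                "mean": float(arr.mean()) if len(arr) else float("nan"),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "n_ok": len(arr),
                "n_failed": failures,
            }
        )
    return pd.DataFrame(rows)
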