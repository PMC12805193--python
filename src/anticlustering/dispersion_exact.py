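"""Exact maximum dispersion via cannot-link graphs and bounded K-coloring.

The dispersion objective acts like a family of cannot-link constraints: two
objects whose dissimilarity is at or below a threshold theta must not share
a group. Maximizing the dispersion therefore amounts to finding the largest
theta whose cannot-link graph can still be colored with K colors under the
cardinality constraints; the optimal dispersion is the next larger distance
in the matrix. Feasibility of a threshold is decided by

* an exact polynomial routine for K = 2 (bipartiteness plus a subset-sum
  DP over the two sides of each connected component), and
* a cardinality-bounded graph-coloring ILP (HiGHS via scipy) for K >= 3,
  preceded by a greedy capacity-respecting coloring that can certify
  feasibility cheaply, and by pigeonhole checks that can certify
  infeasibility cheaply.

Only vertices incident to a cannot-link edge are colored; the remaining
objects can be filled into groups arbitrarily without changing the
dispersion, which :func:`complete_partition` does uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from ._solver import quiet_solver
from .criteria import DISPERSION_SENTINEL
from .distances import as_dissimilarity_values
from .partition import Partition

__all__ = [
    "CannotLinkGraph",
    "OptimalDispersionResult",
    "SolverError",
    "InfeasibleConstraintsError",
    "build_cannot_link_graph",
    "k_color_with_cardinalities",
    "optimal_dispersion",
    "complete_partition",
    "satisfy_cannot_link",
]

UNASSIGNED = -1


class SolverError(RuntimeError):
    """ILP backend failed or hit its time limit (never an infeasibility verdict)."""


class InfeasibleConstraintsError(ValueError):
    """The requested cannot-link constraints admit no feasible partition."""


@dataclass(frozen=True)
class CannotLinkGraph:
    """Pairs of objects forbidden from sharing a group."""

    n_vertices: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError("cannot-link graph has a self-loop")
            if not (0 <= u < self.n_vertices and 0 <= v < self.n_vertices):
                raise ValueError("edge endpoint out of range")

    @staticmethod
    def from_pairs(pairs, n_vertices: int) -> "CannotLinkGraph":
        edges = frozenset((min(u, v), max(u, v)) for u, v in pairs)
        return CannotLinkGraph(n_vertices, edges)

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj


def build_cannot_link_graph(D, threshold: float) -> CannotLinkGraph:
    """Edges for every pair with ``d_ij <= threshold``."""
    D = as_dissimilarity_values(D)
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = D[iu, ju] <= threshold
    edges = frozenset(zip(iu[mask].tolist(), ju[mask].tolist()))
    return CannotLinkGraph(n, edges)


# ---------------------------------------------------------------------------
# Feasibility of bounded coloring


def _components(vertices: list[int], adj: list[set[int]]) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for s in vertices:
        if s in seen:
            continue
        comp = []
        stack = [s]
        seen.add(s)
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        comps.append(sorted(comp))
    return comps


def _two_color_component(comp: list[int], adj: list[set[int]]):
    """BFS 2-coloring; returns (sideA, sideB) or None on an odd cycle."""
    color = {comp[0]: 0}
    queue = [comp[0]]
    while queue:
        v = queue.pop()
        for u in adj[v]:
            if u not in color:
                color[u] = 1 - color[v]
                queue.append(u)
            elif color[u] == color[v]:
                return None
    a = [v for v in comp if color[v] == 0]
    b = [v for v in comp if color[v] == 1]
    return a, b


def _color_k2(constrained, adj, caps):
    """Exact polynomial feasibility for two groups.

    Each bipartite component contributes a split (|A_c|, |B_c|); an
    orientation choice per component must pack the totals within the two
    capacities, a subset-sum problem solved by bitset DP.
    """
    comps = _components(constrained, adj)
    sides = []
    for comp in comps:
        two = _two_color_component(comp, adj)
        if two is None:
            return None
        sides.append(two)
    if caps is None:
        coloring = {}
        for a, b in sides:
            for v in a:
                coloring[v] = 0
            for v in b:
                coloring[v] = 1
        return coloring
    total = sum(len(a) + len(b) for a, b in sides)
    lo = total - caps[1]
    hi = caps[0]
    if lo > hi:
        return None
    # prefix[i] = bitset of achievable color-0 totals using components < i
    prefix = [1]
    for a, b in sides:
        bits = prefix[-1]
        prefix.append((bits << len(a)) | (bits << len(b)))
    target = -1
    for t in range(max(lo, 0), hi + 1):
        if (prefix[-1] >> t) & 1:
            target = t
            break
    if target < 0:
        return None
    coloring = {}
    for i in range(len(sides) - 1, -1, -1):
        a, b = sides[i]
        if len(a) <= target and (prefix[i] >> (target - len(a))) & 1:
            first, second = a, b
            target -= len(a)
        else:
            first, second = b, a
            target -= len(first)
            assert target >= 0 and (prefix[i] >> target) & 1
        for v in first:
            coloring[v] = 0
        for v in second:
            coloring[v] = 1
    return coloring


def _greedy_color(constrained, adj, K, caps):
    """Capacity-respecting greedy coloring; success certifies feasibility."""
    remaining = list(caps) if caps is not None else [len(constrained)] * K
    order = sorted(constrained, key=lambda v: -len(adj[v]))
    coloring: dict[int, int] = {}
    for v in order:
        used = {coloring[u] for u in adj[v] if u in coloring}
        best_k, best_cap = -1, 0
        for k in range(K):
            if k not in used and remaining[k] > best_cap:
                best_k, best_cap = k, remaining[k]
        if best_k < 0:
            return None
        coloring[v] = best_k
        remaining[best_k] -= 1
    return coloring


def _pigeonhole_infeasible(constrained, adj, K, caps) -> bool:
    """Cheap certificates of infeasibility on dense graphs."""
    n_total = None
    if caps is not None:
        n_total = sum(caps)
        min_size = min(caps)
        n_constr = len(constrained)
        for v in constrained:
            # v needs (size-1) non-neighbors in its group; count available ones
            non_neighbors = n_total - 1 - len(adj[v])
            if non_neighbors < min_size - 1:
                return True
    # greedy clique of size K+1 proves uncolorability
    order = sorted(constrained, key=lambda v: -len(adj[v]))[: 4 * K + 8]
    clique: list[int] = []
    for v in order:
        if all(v in adj[u] for u in clique):
            clique.append(v)
            if len(clique) > K:
                return True
    return False


def _color_ilp(constrained, edges, K, caps, time_limit):
    """Bounded-coloring assignment ILP; returns coloring, None, or raises."""
    if not constrained:
        return {}
    idx = {v: i for i, v in enumerate(constrained)}
    nv = len(constrained)
    nvar = nv * K
    rows, cols, vals = [], [], []
    lb_con, ub_con = [], []
    r = 0
    for i in range(nv):  # exactly one color each
        for k in range(K):
            rows.append(r)
            cols.append(i * K + k)
            vals.append(1.0)
        lb_con.append(1.0)
        ub_con.append(1.0)
        r += 1
    for u, v in edges:
        if u in idx and v in idx:
            for k in range(K):
                rows.extend([r, r])
                cols.extend([idx[u] * K + k, idx[v] * K + k])
                vals.extend([1.0, 1.0])
                lb_con.append(-np.inf)
                ub_con.append(1.0)
                r += 1
    if caps is not None:
        for k in range(K):
            for i in range(nv):
                rows.append(r)
                cols.append(i * K + k)
                vals.append(1.0)
            lb_con.append(-np.inf)
            ub_con.append(float(caps[k]))
            r += 1
    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    # symmetry breaking: with interchangeable colors, constrained vertex at
    # position p (p < K) may only use colors 0..p
    if caps is None or len(set(caps)) == 1:
        for p in range(min(K, nv)):
            for k in range(p + 1, K):
                ub[p * K + k] = 0.0
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    with quiet_solver():
        res = milp(
            c=np.zeros(nvar),
            constraints=LinearConstraint(A, lb_con, ub_con),
            integrality=np.ones(nvar),
            bounds=Bounds(lb, ub),
            options={"time_limit": time_limit} if time_limit else None,
        )
    if res.status == 2:
        return None
    if res.status != 0 or res.x is None:
        raise SolverError(f"MILP solver failed: {res.message}")
    x = np.round(res.x).astype(int)
    coloring = {}
    for v, i in idx.items():
        coloring[v] = int(np.argmax(x[i * K : (i + 1) * K]))
    return coloring


def _feasible_coloring(G: CannotLinkGraph, K: int, caps, time_limit=None):
    """Coloring of the edge-incident vertices, or None if infeasible.

    ``caps`` bounds how often each color may be used among the constrained
    vertices (isolated vertices absorb the remaining capacity).
    """
    if K < 1:
        raise ValueError("K must be positive")
    adj = G.adjacency()
    constrained = [v for v in range(G.n_vertices) if adj[v]]
    if not constrained:
        return {}
    if caps is not None and max(len(adj[v]) for v in constrained) >= G.n_vertices:
        return None
    if K == 1:
        return None  # any edge forbids a single group
    if K == 2:
        return _color_k2(constrained, adj, caps)
    if _pigeonhole_infeasible(constrained, adj, K, caps):
        return None
    greedy = _greedy_color(constrained, adj, K, caps)
    if greedy is not None:
        return greedy
    return _color_ilp(constrained, G.edges, K, caps, time_limit)


def k_color_with_cardinalities(G: CannotLinkGraph, K: int, sizes):
    """Full coloring using color k exactly ``sizes[k]`` times, or None.

    Adjacent vertices receive different colors. Isolated vertices are
    filled deterministically (index order) into remaining capacity.
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.sum() != G.n_vertices:
        raise ValueError("sizes must sum to the number of vertices")
    coloring = _feasible_coloring(G, K, list(sizes))
    if coloring is None:
        return None
    remaining = list(sizes)
    for v, k in coloring.items():
        remaining[k] -= 1
        if remaining[k] < 0:  # defensive; solver respects capacities
            raise SolverError("capacity violated by coloring backend")
    out = np.full(G.n_vertices, UNASSIGNED, dtype=np.int64)
    for v, k in coloring.items():
        out[v] = k
    k = 0
    for v in range(G.n_vertices):
        if out[v] == UNASSIGNED:
            while remaining[k] == 0:
                k += 1
            out[v] = k
            remaining[k] -= 1
    return out


# ---------------------------------------------------------------------------
# Threshold sweep


@dataclass(frozen=True)
class OptimalDispersionResult:
    """Certificate of the optimal dispersion.

    ``theta_star`` is the largest threshold whose cannot-link graph is
    feasibly colorable; the optimal ``dispersion`` is the next larger
    distance in the matrix (+inf when no within-group pair is forced).
    ``partial_assignment`` colors exactly the vertices incident to a
    cannot-link edge at ``theta_star`` (-1 elsewhere).
    """

    theta_star: float
    dispersion: float
    partial_assignment: np.ndarray
    K: int
    sizes: np.ndarray | None = field(default=None)

    @property
    def N(self) -> int:
        return len(self.partial_assignment)


def optimal_dispersion(
    D,
    K: int,
    sizes=None,
    *,
    strategy: str = "binary",
    time_limit: float | None = None,
) -> OptimalDispersionResult:
    """Exact maximum dispersion for K groups with optional fixed sizes.

    ``sizes=None`` drops the cardinality constraints (groups need only be
    separable). ``strategy`` selects the sweep over the ascending grid of
    unique dissimilarities: ``"linear"`` walks upward from the minimum,
    ``"binary"`` (default) exploits that feasibility is monotone
    non-increasing in the threshold; both yield identical results.
    """
    D = as_dissimilarity_values(D)
    N = D.shape[0]
    if sizes is not None:
        sizes = np.asarray(sizes, dtype=int)
        if sizes.sum() != N:
            raise ValueError("group sizes must sum to N")
        if len(sizes) != K:
            raise ValueError("len(sizes) must equal K")
    iu, ju = np.triu_indices(N, k=1)
    grid = np.unique(D[iu, ju])
    caps = list(sizes) if sizes is not None else None

    def feasible(idx: int):
        G = build_cannot_link_graph(D, grid[idx])
        return _feasible_coloring(G, K, caps, time_limit)

    last = len(grid) - 1
    top = feasible(last)
    if top is not None:
        partial = _coloring_to_array(top, N)
        return OptimalDispersionResult(
            float(grid[last]), DISPERSION_SENTINEL, partial, K, sizes
        )

    if strategy == "linear":
        lo, lo_col = -1, {}
        for idx in range(len(grid)):
            col = feasible(idx)
            if col is None:
                hi = idx
                break
            lo, lo_col = idx, col
        else:  # pragma: no cover - top already tested infeasible
            raise AssertionError("sweep found no infeasible threshold")
    elif strategy == "binary":
        lo, hi = -1, last
        lo_col: dict[int, int] = {}
        while hi - lo > 1:
            mid = (lo + hi) // 2
            col = feasible(mid)
            if col is None:
                hi = mid
            else:
                lo, lo_col = mid, col
    else:
        raise ValueError(f"unknown sweep strategy {strategy!r}")

    theta_star = float(grid[lo]) if lo >= 0 else -np.inf
    return OptimalDispersionResult(
        theta_star, float(grid[hi]), _coloring_to_array(lo_col, N), K, sizes
    )


def _coloring_to_array(coloring: dict[int, int], N: int) -> np.ndarray:
    out = np.full(N, UNASSIGNED, dtype=np.int64)
    for v, k in coloring.items():
        out[v] = k
    return out


def complete_partition(
    res: OptimalDispersionResult, rng: np.random.Generator
) -> Partition:
    """Fill unassigned vertices uniformly at random into remaining capacity.

    The result is a full partition whose dispersion equals the optimal
    value certified by ``res``; different random streams may produce
    different completions.
    """
    if res.sizes is None:
        raise ValueError("completion requires fixed group sizes")
    assign = res.partial_assignment.copy()
    remaining = np.asarray(res.sizes, dtype=int).copy()
    for k in assign[assign != UNASSIGNED]:
        remaining[k] -= 1
    if (remaining < 0).any():
        raise RuntimeError("partial assignment exceeds group capacities")
    free = np.flatnonzero(assign == UNASSIGNED)
    slots = np.repeat(np.arange(res.K), remaining)
    if len(slots) != len(free):
        raise RuntimeError("capacity bookkeeping is inconsistent")
    rng.shuffle(slots)
    assign[free] = slots
    return Partition(assign, K=res.K)


def satisfy_cannot_link(
    pairs,
    N: int,
    K: int,
    sizes,
    rng: np.random.Generator,
    *,
    time_limit: float | None = None,
) -> Partition:
    """Partition separating every listed pair, cardinalities respected.

    Raises :class:`InfeasibleConstraintsError` when no partition can
    separate all pairs; free objects are completed uniformly at random.
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.sum() != N:
        raise ValueError("group sizes must sum to N")
    G = CannotLinkGraph.from_pairs(pairs, N)
    coloring = _feasible_coloring(G, K, list(sizes), time_limit)
    if coloring is None:
        raise InfeasibleConstraintsError(
            "the cannot-link constraint set cannot be satisfied"
        )
    res = OptimalDispersionResult(
        np.nan, np.nan, _coloring_to_array(coloring, N), K, sizes
    )
    return complete_partition(res, rng)
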