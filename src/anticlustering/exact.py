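"""Exact bicriterion anticlustering: constraint method and full Pareto set.

The constraint method first certifies the optimal dispersion, then
maximizes diversity among all partitions preserving it. The restriction is
encoded in the dissimilarity matrix itself: every pair closer than the
dispersion threshold gets a penalty entry -M, with M exceeding the total
sum of dissimilarities, so a single forbidden within-group pair outweighs
any attainable diversity. Maximum diversity on the adjusted matrix is then
an unconstrained clique-partitioning ILP.

Sweeping the threshold downward over the distance grid and re-solving
yields the entire Pareto frontier of (diversity, dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from ._solver import quiet_solver
from .criteria import diversity, dispersion
from .dispersion_exact import OptimalDispersionResult, SolverError, optimal_dispersion
from .distances import as_dissimilarity_values
from .pareto import ParetoEntry, ParetoSet
from .partition import Partition

__all__ = [
    "AdjustedDissimilarityMatrix",
    "adjust_dissimilarities",
    "max_diversity_exact",
    "optimal_bicriterion",
    "exact_pareto_set",
]


@dataclass
class AdjustedDissimilarityMatrix:
    """Raw matrix with forbidden pairs replaced by a large negative penalty."""

    base: np.ndarray
    threshold: float
    penalty: float
    forbidden_pairs: frozenset[tuple[int, int]]
    values: np.ndarray

    @property
    def flavor(self) -> str:
        return "adjusted"


def adjust_dissimilarities(D, threshold: float, reference=None) -> AdjustedDissimilarityMatrix:
    """Set entries with reference distance strictly below ``threshold`` to -M.

    ``reference`` defaults to ``D`` itself; passing a second matrix forbids
    pairs by one measure (e.g. orthographic dissimilarity) while the
    retained entries still score diversity by the other. The penalty is
    M = sum of off-diagonal entries of ``D`` (each pair once) + 1, so any
    partition containing a forbidden pair scores below every partition
    without one. Pairs exactly at the threshold stay allowed, matching the
    dispersion's definition as an attained minimum.
    """
    D = as_dissimilarity_values(D)
    R = D if reference is None else as_dissimilarity_values(reference)
    if R.shape != D.shape:
        raise ValueError("reference matrix must match D in shape")
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    M = float(D[iu, ju].sum()) + 1.0
    mask = R < threshold
    np.fill_diagonal(mask, False)
    adjusted = D.copy()
    adjusted[mask] = -M
    forb = frozenset(
        (int(i), int(j)) for i, j in zip(iu[mask[iu, ju]], ju[mask[iu, ju]])
    )
    return AdjustedDissimilarityMatrix(D, float(threshold), M, forb, adjusted)


def _solve(c, A, lb, ub, integrality, bounds, time_limit):
    with quiet_solver():
        res = milp(
            c=c,
            constraints=LinearConstraint(A, lb, ub),
            integrality=integrality,
            bounds=bounds,
            options={"time_limit": time_limit} if time_limit else None,
        )
    if res.status == 1:
        raise SolverError("MILP solver hit its time limit")
    if res.status != 0 or res.x is None:
        raise SolverError(f"MILP solver failed: {res.message}")
    return res


def _max_diversity_equal(D: np.ndarray, K: int, n: int, time_limit):
    """Clique-partitioning model with degree constraints (equal group sizes).

    Binary co-membership variables y_ij with the three transitivity
    inequalities per triple; each object has exactly n-1 within-group
    partners, which forces K cliques of size n.
    """
    N = D.shape[0]
    pair_idx = {}
    c = []
    for i in range(N):
        for j in range(i + 1, N):
            pair_idx[(i, j)] = len(c)
            c.append(-D[i, j])
    nvar = len(c)
    rows, cols, vals, lb, ub = [], [], [], [], []
    r = 0
    for i in range(N):
        for j in range(i + 1, N):
            for k in range(j + 1, N):
                ij, ik, jk = pair_idx[(i, j)], pair_idx[(i, k)], pair_idx[(j, k)]
                for a, b, d in ((ij, jk, ik), (ij, ik, jk), (ik, jk, ij)):
                    rows += [r, r, r]
                    cols += [a, b, d]
                    vals += [1.0, 1.0, -1.0]
                    lb.append(-np.inf)
                    ub.append(1.0)
                    r += 1
    for i in range(N):
        for j in range(N):
            if j == i:
                continue
            rows.append(r)
            cols.append(pair_idx[(min(i, j), max(i, j))])
            vals.append(1.0)
        lb.append(float(n - 1))
        ub.append(float(n - 1))
        r += 1
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    res = _solve(
        np.asarray(c), A, lb, ub, np.ones(nvar), Bounds(0, 1), time_limit
    )
    y = np.round(res.x).astype(int)
    # recover groups as connected components of the co-membership graph
    assign = np.full(N, -1, dtype=np.int64)
    label = 0
    for i in range(N):
        if assign[i] >= 0:
            continue
        assign[i] = label
        stack = [i]
        while stack:
            u = stack.pop()
            for v in range(N):
                if v != u and assign[v] < 0:
                    a, b = min(u, v), max(u, v)
                    if y[pair_idx[(a, b)]]:
                        assign[v] = label
                        stack.append(v)
        label += 1
    return Partition(assign, K=label)


def _max_diversity_assignment(D: np.ndarray, K: int, sizes, time_limit):
    """Assignment model with linearized co-membership (unequal group sizes)."""
    N = D.shape[0]
    pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]
    nx = N * K
    nz = len(pairs) * K
    nvar = nx + nz

    def xv(i, k):
        return i * K + k

    def zv(p, k):
        return nx + p * K + k

    c = np.zeros(nvar)
    for p, (i, j) in enumerate(pairs):
        for k in range(K):
            c[zv(p, k)] = -D[i, j]
    rows, cols, vals, lb, ub = [], [], [], [], []
    r = 0
    for i in range(N):  # one group per object
        for k in range(K):
            rows.append(r)
            cols.append(xv(i, k))
            vals.append(1.0)
        lb.append(1.0)
        ub.append(1.0)
        r += 1
    for k in range(K):  # cardinalities
        for i in range(N):
            rows.append(r)
            cols.append(xv(i, k))
            vals.append(1.0)
        lb.append(float(sizes[k]))
        ub.append(float(sizes[k]))
        r += 1
    for p, (i, j) in enumerate(pairs):  # z = x_i AND x_j, tight both ways
        for k in range(K):
            rows += [r, r]
            cols += [zv(p, k), xv(i, k)]
            vals += [1.0, -1.0]
            lb.append(-np.inf)
            ub.append(0.0)
            r += 1
            rows += [r, r]
            cols += [zv(p, k), xv(j, k)]
            vals += [1.0, -1.0]
            lb.append(-np.inf)
            ub.append(0.0)
            r += 1
            rows += [r, r, r]
            cols += [zv(p, k), xv(i, k), xv(j, k)]
            vals += [1.0, -1.0, -1.0]
            lb.append(-1.0)
            ub.append(np.inf)
            r += 1
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, nvar))
    res = _solve(c, A, lb, ub, np.ones(nvar), Bounds(0, 1), time_limit)
    x = np.round(res.x[:nx]).astype(int).reshape(N, K)
    return Partition(np.argmax(x, axis=1), K=K)


def max_diversity_exact(D, K: int, sizes, *, time_limit: float | None = None) -> Partition:
    """Globally diversity-maximal partition with fixed group sizes.

    Accepts a raw or penalty-adjusted matrix. Equal-sized instances use the
    clique-partitioning model with per-object degree constraints; unequal
    sizes fall back to an assignment formulation.
    """
    vals = D.values if hasattr(D, "values") else np.asarray(D, dtype=float)
    N = vals.shape[0]
    sizes = np.asarray(sizes, dtype=int)
    if sizes.sum() != N or len(sizes) != K:
        raise ValueError("sizes must have length K and sum to N")
    if len(set(sizes.tolist())) == 1:
        return _max_diversity_equal(vals, K, int(sizes[0]), time_limit)
    return _max_diversity_assignment(vals, K, sizes, time_limit)


def _entry(D_div, D_disp, part: Partition) -> ParetoEntry:
    return ParetoEntry(part, diversity(D_div, part), dispersion(D_disp, part))


def optimal_bicriterion(
    D,
    K: int,
    sizes,
    *,
    D_disp=None,
    disp_result: OptimalDispersionResult | None = None,
    time_limit: float | None = None,
) -> ParetoEntry:
    """Maximum diversity subject to preserved optimal dispersion.

    Scores of the returned entry are recomputed on the raw matrices; the
    penalty entries never leak into output.
    """
    D = as_dissimilarity_values(D)
    Dd = D if D_disp is None else as_dissimilarity_values(D_disp)
    if disp_result is None:
        disp_result = optimal_dispersion(Dd, K, sizes, time_limit=time_limit)
    t = disp_result.dispersion
    if not np.isfinite(t):
        part = max_diversity_exact(D, K, sizes, time_limit=time_limit)
        return _entry(D, Dd, part)
    adjusted = adjust_dissimilarities(D, t, reference=Dd)
    part = max_diversity_exact(adjusted, K, sizes, time_limit=time_limit)
    entry = _entry(D, Dd, part)
    if entry.dispersion < t:  # pragma: no cover - would indicate a defect
        raise RuntimeError("bicriterion solution violated the dispersion bound")
    return entry


def exact_pareto_set(
    D, K: int, sizes, *, time_limit: float | None = None
) -> ParetoSet:
    """The exact Pareto frontier of (diversity, dispersion).

    Solves a maximum-diversity ILP for every dispersion level: thresholds
    sweep the unique distance values downward from the optimal dispersion,
    forbidding pairs strictly below each level. The sweep stops early once
    the unconstrained diversity optimum is reached, since weaker
    constraints can only produce dominated partitions after that.
    """
    D = as_dissimilarity_values(D)
    N = D.shape[0]
    sizes = np.asarray(sizes, dtype=int)
    disp_result = optimal_dispersion(D, K, sizes, time_limit=time_limit)
    S = ParetoSet()
    if not np.isfinite(disp_result.dispersion):
        part = max_diversity_exact(D, K, sizes, time_limit=time_limit)
        S.add(_entry(D, D, part))
        return S
    unconstrained = max_diversity_exact(D, K, sizes, time_limit=time_limit)
    e0 = _entry(D, D, unconstrained)
    div_max = e0.diversity
    S.add(e0)
    iu, ju = np.triu_indices(N, k=1)
    grid = np.unique(D[iu, ju])
    levels = grid[grid <= disp_result.dispersion][::-1]
    tol = 1e-9 * (1.0 + abs(div_max))
    for t in levels:
        if t <= grid[0]:
            break  # no pair strictly below the minimum distance
        adjusted = adjust_dissimilarities(D, float(t))
        part = max_diversity_exact(adjusted, K, sizes, time_limit=time_limit)
        entry = _entry(D, D, part)
        S.add(entry)
        if entry.diversity >= div_max - tol:
            break
    return S
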