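"""Synthetic benchmark harness and brute-force oracles.

The generator emulates a covariate-balancing scenario: feature tables of
i.i.d. normal measurements (mean 0, common SD per dataset) with the sample
size a uniform multiple of K in [20, 120], 2-5 features, SD in {1, 2, 3}.
Diversity is scored on squared Euclidean distances of the raw features.

The harness compares hybrid methods that all guarantee optimal dispersion
and differ in how they maximize diversity on top of it. A method's solution
counts as "good" when its diversity is within 0.1% of the best diversity
attained on that dataset. Datasets are additionally labeled by how strongly
the optimal-dispersion certificate restricts the search: the label counts
duplicates among the random completions used as initializations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import dispersion, diversity
from .dispersion_exact import complete_partition, optimal_dispersion
from .distances import as_dissimilarity_values, squared_euclidean_matrix
from .pareto import ParetoEntry, ParetoSet
from .partition import Partition, canonical_assignment, partition_count
from .search import BilsConfig, bils, restricted_lcw, select_entry

__all__ = [
    "Sim2Config",
    "RestrictionLabel",
    "generate_dataset",
    "good_solution_flags",
    "label_restriction",
    "run_simulation",
    "brute_force_oracle",
    "enumerate_partitions",
    "DEFAULT_METHODS",
]


def generate_dataset(N: int, P: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """N x P i.i.d. normal features, mean 0, common standard deviation."""
    if N < 2 or P < 1 or sd <= 0:
        raise ValueError("need N >= 2, P >= 1, sd > 0")
    return rng.normal(0.0, sd, size=(N, P))


def good_solution_flags(diversities) -> np.ndarray:
    """True where a diversity is within 0.1% of the best one attained."""
    div = np.asarray(list(diversities), dtype=float)
    if div.size == 0:
        raise ValueError("need at least one diversity value")
    return div >= 0.999 * div.max()


@dataclass(frozen=True)
class RestrictionLabel:
    """How much the optimal-dispersion certificate pins down the partition."""

    label: str  # none | some | maximum
    duplicate_count: int


def label_restriction(inits: list[Partition]) -> RestrictionLabel:
    """Duplicate-based restriction label of a list of initializations."""
    if len(inits) < 2:
        raise ValueError("need at least two initializations")
    canon = {tuple(canonical_assignment(p.assignment)) for p in inits}
    dup = len(inits) - len(canon)
    if dup == 0:
        return RestrictionLabel("none", 0)
    if len(canon) == 1:
        return RestrictionLabel("maximum", dup)
    return RestrictionLabel("some", dup)


@dataclass
class Sim2Config:
    """Design of the synthetic comparison of hybrid methods."""

    reps_per_K: int = 50
    K_set: tuple[int, ...] = (2, 3, 4, 5)
    N_range: tuple[int, int] = (20, 120)
    P_range: tuple[int, int] = (2, 5)
    sd_choices: tuple[float, ...] = (1.0, 2.0, 3.0)
    restarts: int = 100
    seed: int = 0

    def sample_instance(self, K: int, rng: np.random.Generator):
        lo, hi = self.N_range
        multiples = np.arange(lo, hi + 1)
        multiples = multiples[multiples % K == 0]
        N = int(rng.choice(multiples))
        P = int(rng.integers(self.P_range[0], self.P_range[1] + 1))
        sd = float(rng.choice(np.asarray(self.sd_choices)))
        return N, P, sd


def _method_lcw_single(D, K, sizes, res, inits, restarts, rng):
    return restricted_lcw(D, D, res, rng)


def _method_lcw_multi(D, K, sizes, res, inits, restarts, rng):
    best = None
    for _ in range(restarts):
        entry = restricted_lcw(D, D, res, rng)
        if best is None or entry.diversity > best.diversity:
            best = entry
    return best


def _bils_method(init_mode, use_ils):
    def run(D, K, sizes, res, inits, restarts, rng):
        cfg = BilsConfig(
            restarts_total=restarts,
            restarts_ils=restarts // 2 if use_ils else 0,
            init_mode=init_mode,
        )
        S = bils(D, K=K, sizes=sizes, cfg=cfg, rng=rng, disp_result=res)
        return select_entry(S, "max-dispersion")

    return run


#: The six-method roster: restricted LCW with one or many optimal
#: initializations, and the BILS hybrids with and without the ILS phase.
DEFAULT_METHODS = {
    "lcw_restricted": _method_lcw_single,
    "lcw_restricted_multi": _method_lcw_multi,
    "bils_hybrid_1": _bils_method("hybrid-1", False),
    "bils_hybrid_1_ils": _bils_method("hybrid-1", True),
    "bils_hybrid_all": _bils_method("hybrid-all", False),
    "bils_hybrid_all_ils": _bils_method("hybrid-all", True),
}


def run_simulation(
    cfg: Sim2Config,
    methods: dict | None = None,
    *,
    K_only: int | None = None,
    restriction_filter: str | None = None,
    max_datasets: int | None = None,
) -> pd.DataFrame:
    """Apply every method to each synthetic dataset; tidy results table.

    One row per dataset x method with the diversity and dispersion of the
    max-dispersion Pareto entry, its good-solution flag, and the dataset's
    restriction label. ``K_only`` restricts the design to one K;
    ``restriction_filter`` keeps generating datasets (up to
    ``max_datasets``) until ``reps_per_K`` datasets carrying that label
    have been scored, which supports studying heavily restricted instances.
    """
    if methods is None:
        methods = DEFAULT_METHODS
    rng = np.random.default_rng(cfg.seed)
    K_values = (K_only,) if K_only is not None else cfg.K_set
    rows = []
    for K in K_values:
        kept = 0
        attempts = 0
        while kept < cfg.reps_per_K:
            attempts += 1
            if max_datasets is not None and attempts > max_datasets:
                break
            N, P, sd = cfg.sample_instance(K, rng)
            X = generate_dataset(N, P, sd, rng)
            D = squared_euclidean_matrix(X).values
            sizes = np.full(K, N // K)
            res = optimal_dispersion(D, K, sizes)
            inits = [complete_partition(res, rng) for _ in range(cfg.restarts)]
            restriction = label_restriction(inits)
            if restriction_filter is not None and restriction.label != restriction_filter:
                continue
            kept += 1
            divs = {}
            for name, run in methods.items():
                entry = run(D, K, sizes, res, inits, cfg.restarts, rng)
                divs[name] = entry
            flags = good_solution_flags([e.diversity for e in divs.values()])
            for flag, (name, entry) in zip(flags, divs.items()):
                rows.append(
                    {
                        "K": K,
                        "N": N,
                        "P": P,
                        "sd": sd,
                        "restriction": restriction.label,
                        "duplicates": restriction.duplicate_count,
                        "optimal_dispersion": res.dispersion,
                        "method": name,
                        "diversity": entry.diversity,
                        "dispersion": entry.dispersion,
                        "good": bool(flag),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle


def enumerate_partitions(N: int, sizes):
    """Yield every distinct partition (canonical labels) with the given sizes.

    Object 0 always opens cluster 0; each later object joins a non-full
    open cluster or opens the next cluster, where among clusters of equal
    target size only the first unopened one may be opened (clusters are
    unlabeled). Yields assignment arrays.
    """
    pool = sorted(sizes)  # multiset of target sizes not yet attached to a cluster
    K = len(pool)
    assign = np.full(N, -1, dtype=np.int64)
    targets: list[int] = []  # target size of each opened cluster
    fill: list[int] = []

    def rec(i):
        if i == N:
            yield assign.copy()
            return
        for k in range(len(targets)):
            if fill[k] < targets[k]:
                assign[i] = k
                fill[k] += 1
                yield from rec(i + 1)
                fill[k] -= 1
        for s in sorted(set(pool)):
            pool.remove(s)
            targets.append(s)
            fill.append(1)
            assign[i] = len(targets) - 1
            yield from rec(i + 1)
            fill.pop()
            targets.pop()
            pool.append(s)
        assign[i] = -1

    yield from rec(0)


def brute_force_oracle(D, K: int, sizes, *, max_partitions: int = 10**6):
    """Exact maxima and Pareto frontier by exhaustive enumeration.

    Returns ``(max_diversity, max_dispersion, ParetoSet)``. Refuses
    instances whose partition space exceeds ``max_partitions``.
    """
    D = as_dissimilarity_values(D)
    N = D.shape[0]
    sizes = np.asarray(sizes, dtype=int)
    if sizes.sum() != N or len(sizes) != K:
        raise ValueError("sizes must have length K and sum to N")
    if len(set(sizes.tolist())) == 1 and partition_count(N, K) > max_partitions:
        raise ValueError("partition space too large for enumeration")
    best_div = -np.inf
    best_disp = -np.inf
    S = ParetoSet()
    for assign in enumerate_partitions(N, sizes):
        part = Partition(assign, K=K)
        dv = diversity(D, part)
        dp = dispersion(D, part)
        best_div = max(best_div, dv)
        best_disp = max(best_disp, dp)
        S.add(ParetoEntry(part, dv, dp))
    return best_div, best_disp, S
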