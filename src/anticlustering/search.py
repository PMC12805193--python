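"""Heuristic bicriterion search: LCW, BPI/MBPI, ILS and BILS.

BPI is a best-improvement pairwise-interchange local search guided by the
weighted sum ``w * diversity + (1 - w) * dispersion``; after every realized
exchange the current partition is offered to a shared Pareto set. MBPI
restarts BPI from random partitions with weights drawn from a fixed
ten-value catalog spanning extreme trade-offs. BILS adds an iterated-local-
search phase: a random Pareto entry is perturbed by random pair swaps
(swap probability drawn from [0.05, 0.10]) and re-optimized.

The hybrid variants seed restarts with partitions completed from the exact
maximum-dispersion certificate, which guarantees the returned Pareto set
contains an entry with globally optimal dispersion: such an entry can only
ever be displaced by one that is equally dispersion-optimal and more
diverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .criteria import average_diversity, dispersion, diversity
from .dispersion_exact import (
    OptimalDispersionResult,
    complete_partition,
    optimal_dispersion,
)
from .distances import as_dissimilarity_values
from .exact import adjust_dissimilarities
from .pareto import ParetoEntry, ParetoSet
from .partition import Partition, random_partition

__all__ = [
    "WEIGHT_CATALOG",
    "BilsConfig",
    "lcw",
    "restricted_lcw",
    "bpi",
    "mbpi",
    "ils_perturb",
    "bils",
    "select_entry",
]

#: The ten admissible diversity weights for MBPI restarts.
WEIGHT_CATALOG = (
    0.000001,
    0.00001,
    0.0001,
    0.001,
    0.01,
    0.1,
    0.5,
    0.99,
    0.999,
    0.999999,
)


@dataclass
class BilsConfig:
    """Knobs of the BILS algorithm.

    ``restarts_total`` counts all restarts; ``restarts_ils`` of them (by
    default half) run the ILS improvement phase after the MBPI phase.
    ``init_mode`` chooses how MBPI restarts are initialized: ``vanilla``
    (random), ``hybrid-1`` (first restart from an optimal-dispersion
    completion, rest random) or ``hybrid-all`` (every restart a fresh
    optimal-dispersion completion). ``criterion`` selects the diversity
    flavor being optimized and recorded.
    """

    restarts_total: int = 100
    restarts_ils: int | None = None
    swap_prob_range: tuple[float, float] = (0.05, 0.10)
    init_mode: str = "vanilla"
    criterion: str = "diversity"

    def __post_init__(self) -> None:
        if self.restarts_ils is None:
            self.restarts_ils = self.restarts_total // 2
        if not 0 <= self.restarts_ils <= self.restarts_total:
            raise ValueError("restarts_ils must lie in [0, restarts_total]")
        lo, hi = self.swap_prob_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("swap_prob_range must lie inside (0, 1)")
        if self.init_mode not in ("vanilla", "hybrid-1", "hybrid-all"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.criterion not in ("diversity", "average-diversity"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


def _criterion_value(D, part, criterion):
    if criterion == "average-diversity":
        return average_diversity(D, part)
    return diversity(D, part)


def _finalize(pareto: ParetoSet, D_div_raw, D_disp_raw, criterion) -> ParetoSet:
    """Re-score surviving entries exactly on the raw matrices and re-filter.

    During search the Pareto set is maintained with the kernel's
    incrementally updated criterion values; the survivors (few) get their
    scores recomputed from scratch so that every reported entry satisfies
    score == recomputation, and dominance is re-applied on exact scores.
    """
    out = ParetoSet()
    for e in pareto:
        out.add(
            ParetoEntry(
                e.partition,
                _criterion_value(D_div_raw, e.partition, criterion),
                dispersion(D_disp_raw, e.partition),
            )
        )
    return out


def bpi(
    D_div,
    D_disp,
    w: float,
    init: Partition,
    pareto: ParetoSet | None = None,
    *,
    criterion: str = "diversity",
    score_div=None,
    score_disp=None,
    finalize: bool = True,
) -> tuple[Partition, ParetoSet]:
    """One bicriterion pairwise-interchange descent from ``init``.

    ``score_div``/``score_disp`` override the matrices used for Pareto
    scoring (the search itself runs on ``D_div``/``D_disp``); restricted
    LCW searches on a penalty-adjusted matrix but reports raw scores.
    Multistart drivers pass ``finalize=False`` and re-score the shared set
    once at the end.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    Dv = np.ascontiguousarray(as_dissimilarity_values(D_div))
    Dp = np.ascontiguousarray(as_dissimilarity_values(D_disp))
    if Dv.shape != Dp.shape or Dv.shape[0] != init.N:
        raise ValueError("matrices and initial partition disagree on N")
    raw_div = Dv if score_div is None else as_dissimilarity_values(score_div)
    raw_disp = Dp if score_disp is None else as_dissimilarity_values(score_disp)
    if pareto is None:
        pareto = ParetoSet()
    N = init.N
    assign = init.assignment.copy()
    use_avg = criterion == "average-diversity"

    init_part = Partition(assign.copy(), K=init.K)
    pareto.add(
        ParetoEntry(
            init_part,
            _criterion_value(raw_div, init_part, criterion),
            dispersion(raw_disp, init_part),
        )
    )

    max_rec = 64 + 64 * N
    rec_i = np.empty(max_rec, dtype=np.int64)
    rec_j = np.empty(max_rec, dtype=np.int64)
    rec_div = np.empty(max_rec)
    rec_disp = np.empty(max_rec)
    nrec = _kernels.bpi_kernel(
        Dv, Dp, assign, init.K, float(w), use_avg, rec_i, rec_j, rec_div, rec_disp
    )
    if nrec == _kernels.OVERFLOW:  # pragma: no cover - generous buffer
        raise RuntimeError("exchange-record buffer overflow")

    replay = init.assignment.copy()
    for t in range(nrec):
        i, j = rec_i[t], rec_j[t]
        replay[i], replay[j] = replay[j], replay[i]
        div_t, disp_t = float(rec_div[t]), float(rec_disp[t])
        if not pareto.would_reject(div_t, disp_t):
            pareto.add(
                ParetoEntry(Partition(replay.copy(), K=init.K), div_t, disp_t)
            )
    final = Partition(assign, K=init.K)
    if finalize:
        new = _finalize(pareto, raw_div, raw_disp, criterion)
        pareto.entries = new.entries
        pareto._keys = new._keys
    return final, pareto


def lcw(
    D,
    init: Partition,
    *,
    objective: str = "diversity",
    score_div=None,
    score_disp=None,
) -> Partition:
    """Pairwise-interchange local search on a single (diversity) criterion."""
    final, _ = bpi(
        D,
        D,
        1.0,
        init,
        criterion=objective,
        score_div=score_div,
        score_disp=score_disp,
    )
    return final


def restricted_lcw(
    D_div,
    D_disp,
    res: OptimalDispersionResult,
    rng: np.random.Generator,
    *,
    criterion: str = "diversity",
) -> ParetoEntry:
    """LCW restricted to partitions preserving the optimal dispersion.

    The search starts from a random completion of the maximum-dispersion
    certificate and runs on the penalty-adjusted diversity matrix, so any
    exchange breaking a forbidden pair would lower the (adjusted) diversity
    and is never accepted. Scores are reported on the raw matrices.
    """
    Dv = as_dissimilarity_values(D_div)
    Dp = as_dissimilarity_values(D_disp)
    init = complete_partition(res, rng)
    if np.isfinite(res.dispersion):
        adjusted = adjust_dissimilarities(Dv, res.dispersion, reference=Dp).values
    else:
        adjusted = Dv
    final = lcw(adjusted, init, objective=criterion, score_div=Dv, score_disp=Dp)
    return ParetoEntry(
        final, _criterion_value(Dv, final, criterion), dispersion(Dp, final)
    )


def mbpi(
    D_div,
    D_disp,
    K: int,
    sizes,
    restarts: int,
    rng: np.random.Generator,
    *,
    init_source=None,
    criterion: str = "diversity",
    pareto: ParetoSet | None = None,
) -> ParetoSet:
    """Multistart BPI: random catalog weight and fresh initialization per restart."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    Dv = as_dissimilarity_values(D_div)
    N = Dv.shape[0]
    if pareto is None:
        pareto = ParetoSet()
    Dp = as_dissimilarity_values(D_disp)
    for r in range(restarts):
        w = float(rng.choice(WEIGHT_CATALOG))
        if init_source is not None:
            init = init_source(r, rng)
        else:
            init = random_partition(N, sizes, rng)
        bpi(D_div, D_disp, w, init, pareto, criterion=criterion, finalize=False)
    final = _finalize(pareto, Dv, Dp, criterion)
    pareto.entries = final.entries
    pareto._keys = final._keys
    return pareto


def ils_perturb(C: Partition, p: float, rng: np.random.Generator) -> Partition:
    """Random pairwise exchanges: every unordered pair, in index order,
    is swapped with probability ``p`` when currently in different groups."""
    if not 0.0 < p < 1.0:
        raise ValueError("swap probability must lie in (0, 1)")
    N = C.N
    assign = C.assignment.copy()
    uniforms = rng.random(N * (N - 1) // 2)
    _kernels.perturb_kernel(assign, uniforms, float(p))
    return Partition(assign, K=C.K)


def bils(
    D_div,
    D_disp=None,
    *,
    K: int,
    sizes,
    cfg: BilsConfig | None = None,
    rng: np.random.Generator,
    disp_result: OptimalDispersionResult | None = None,
    time_limit: float | None = None,
) -> ParetoSet:
    """Bicriterion iterated local search (MBPI phase + ILS phase).

    With a hybrid ``init_mode`` the exact maximum-dispersion certificate is
    computed (or passed via ``disp_result``) and used to seed restarts.
    """
    if cfg is None:
        cfg = BilsConfig()
    Dv = as_dissimilarity_values(D_div)
    Dp = Dv if D_disp is None else as_dissimilarity_values(D_disp)
    N = Dv.shape[0]
    sizes = np.asarray(sizes, dtype=int)
    if sizes.sum() != N or len(sizes) != K:
        raise ValueError("sizes must have length K and sum to N")

    if cfg.init_mode in ("hybrid-1", "hybrid-all") and disp_result is None:
        disp_result = optimal_dispersion(Dp, K, sizes, time_limit=time_limit)

    def init_source(r, rr):
        if cfg.init_mode == "hybrid-all":
            return complete_partition(disp_result, rr)
        if cfg.init_mode == "hybrid-1" and r == 0:
            return complete_partition(disp_result, rr)
        return random_partition(N, sizes, rr)

    pareto = ParetoSet()
    n_mbpi = cfg.restarts_total - cfg.restarts_ils
    if n_mbpi > 0:
        mbpi(
            Dv,
            Dp,
            K,
            sizes,
            n_mbpi,
            rng,
            init_source=init_source if cfg.init_mode != "vanilla" else None,
            criterion=cfg.criterion,
            pareto=pareto,
        )
    lo, hi = cfg.swap_prob_range
    for _ in range(cfg.restarts_ils):
        if not pareto.entries:
            base = init_source(0, rng)
        else:
            base = pareto.entries[rng.integers(len(pareto.entries))].partition
        p = float(rng.uniform(lo, hi))
        perturbed = ils_perturb(base, p, rng)
        w = float(rng.choice(WEIGHT_CATALOG))
        bpi(Dv, Dp, w, perturbed, pareto, criterion=cfg.criterion, finalize=False)
    final = _finalize(pareto, Dv, Dp, cfg.criterion)
    pareto.entries = final.entries
    pareto._keys = final._keys
    return pareto


def select_entry(S: ParetoSet, rule: str = "max-dispersion") -> ParetoEntry:
    """Pick one partition from a Pareto set (ties favor the other criterion)."""
    return S.best(rule)
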