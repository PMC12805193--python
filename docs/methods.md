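# Methods

## Problem and criteria

Objects `1..N` are partitioned into `K` exhaustive, mutually exclusive
groups with fixed cardinalities `n_k` (the common case is the equal split
`n_k = N/K`). All criteria are computed from a symmetric dissimilarity
matrix `D = (d_ij)` with zero diagonal, or from a feature table `X` via a
distance; pairs are unordered and counted once.

* **diversity** `Σ_k Σ_{i<j∈C_k} d_ij` — between-group balance via a sum.
* **average diversity** `Σ_k (1/n_k) Σ_{i<j∈C_k} d_ij` — the per-size
  normalization is chosen so that on squared Euclidean distances it equals
  the k-means (within-centroid sum of squares) criterion *exactly, for any
  group sizes*; this identity is property-tested at 1e-9 relative
  tolerance. With equal sizes `n`, average diversity is `diversity / n`,
  so both criteria have identical argmaxes there.
* **k-plus** — appending per-feature squared-deviation columns
  `(x_ij − mean_j)^2` (and optionally higher central powers) to `X` before
  taking squared Euclidean distances makes mean-balancing also balance
  variances (and higher moments).
* **dispersion** `min_k min_{i<j∈C_k} d_ij` — worst-case within-group
  similarity. For an all-singleton partition the minimum is vacuous and we
  return `+inf` rather than an error so Pareto bookkeeping degrades
  gracefully.
* **normalized Levenshtein** `2L/(|s|+|t|+L)` with unit-cost edit distance
  `L` (edlib), a [0,1]-valued orthographic dissimilarity for word stimuli.

Two matrices may be used at once: diversity scored on one, dispersion on
the other (e.g. covariate balance vs. orthographic confusability).

## Exact maximum dispersion

Dispersion maximization is equivalent to satisfying cannot-link
constraints: demanding dispersion above θ forbids every pair with
`d_ij ≤ θ` from sharing a group. The solver sweeps the ascending grid of
unique off-diagonal distances, at each threshold asking whether the
cannot-link graph admits a K-coloring using color `k` at most `n_k` times
among the edge-incident vertices (isolated vertices soak up remaining
capacity). The optimal dispersion is the grid value right above the
largest feasible threshold θ*, which is also the first infeasible
threshold; the last feasible coloring is returned as a certificate, and
any capacity-respecting random completion of it attains the optimum.

Feasibility testing is layered:

1. **K = 2** — exact polynomial route: the graph must be bipartite, and an
   orientation of each connected component's two sides must pack into the
   two capacities; the packing is a subset-sum problem solved by bitset
   dynamic programming with reconstruction. This route is exact in both
   directions and is cross-checked against the ILP in the tests.
2. **K ≥ 3** — cheap certificates first: a pigeonhole test (a vertex with
   fewer non-neighbors than its group needs cannot be placed) and a greedy
   clique probe (any clique of size K+1 is uncolorable) can prove
   infeasibility; a capacity-respecting greedy coloring can prove
   feasibility. Only undecided cases reach the assignment ILP
   (`x_{v,k} ∈ {0,1}`, one color per vertex, `x_{u,k}+x_{v,k} ≤ 1` per
   edge and color, `Σ_v x_{v,k} ≤ n_k`), solved by HiGHS through scipy.
   With interchangeable colors (equal capacities) the p-th constrained
   vertex is restricted to colors `0..p` as symmetry breaking, which
   cannot change feasibility. A greedy or DP success never substitutes for
   an infeasibility proof and vice versa; solver failures and timeouts
   raise a distinct error and are never reported as infeasibility.

The sweep itself defaults to binary search over the grid — feasibility is
monotone non-increasing in θ — and a linear ascending sweep is available;
both are tested to return identical (θ*, dispersion) pairs. Tied distances
collapse into a single grid value, so results do not depend on the input
order of tied pairs. Grid values are compared exactly; noisy matrices
should be rounded by the caller if tie grouping is intended.

`sizes=None` drops the cardinality constraints (plain K-colorability),
reproducing the polynomial special case for K = 2. When no within-group
pair is forced at any threshold (N ≤ K), the dispersion is the `+inf`
sentinel.

The same feasibility core powers arbitrary user cannot-link constraints
(`satisfy_cannot_link`), with an explicit infeasibility exception distinct
from I/O and solver errors (separate CLI exit codes).

## Exact bicriterion constraint method

To maximize diversity subject to preserving a dispersion level `t`, every
pair with reference distance *strictly below* `t` has its diversity-matrix
entry replaced by `−M`, with `M = Σ_{i<j} d_ij + 1`. Any partition
containing one forbidden pair then scores below every partition without
one, while the strict inequality keeps the pair *attaining* `t` allowed —
matching dispersion's definition as an attained minimum. Maximum diversity
on the adjusted matrix is solved as a clique-partitioning ILP with binary
co-membership variables `y_ij`, the three transitivity inequalities per
triple, and degree constraints `Σ_j y_ij = n − 1` (valid for equal sizes);
unequal sizes use an assignment formulation with linearized co-membership
(`z_ijk = x_ik ∧ x_jk`, tight in both directions because adjusted entries
can be negative). Reported scores are always recomputed on the raw
matrices; the penalty never appears in output.

The full Pareto frontier comes from sweeping `t` downward over the grid
values at or below the optimal dispersion, collecting each constrained
optimum, deduplicating canonically and filtering dominated entries. The
sweep stops once a constrained optimum reaches the unconstrained maximum
diversity (solved once up front): weaker constraints can then only produce
dominated partitions. Exactness of the frontier, of the constraint method
and of the dispersion solver is asserted against brute-force enumeration
of the entire partition space on hundreds of random small instances.

## Heuristic family

**BPI** is a best-improvement pairwise-interchange descent on
`w·diversity + (1−w)·dispersion`: for each focal object in turn, the best
strictly improving exchange partner in another group is realized (ties to
the lowest partner index), and passes repeat until no exchange improves.
After every realized exchange the partition is offered to the Pareto set.
The weighted form attaches `w` to diversity with no scale normalization —
the ten-value weight catalog (1e-6 … 1−1e-6) exists precisely to span
scale mismatch between the criteria. **MBPI** restarts BPI with weights
drawn uniformly from the catalog and fresh initial partitions. **ILS**
perturbs a uniformly chosen Pareto entry by iterating over all object
pairs in index order and swapping cross-group pairs with probability `p`
drawn once per iteration from [0.05, 0.10], then restores local optimality
with BPI. **BILS** = an MBPI phase plus an ILS phase (default split:
half/half of `restarts_total`, default 100).

Initialization modes: *vanilla* (all random), *hybrid-1* (first restart
from a random completion of the optimal-dispersion certificate, rest
random), *hybrid-all* (every restart a fresh completion; duplicate
completions are permitted and are what the restriction label counts).
Because Pareto bookkeeping never discards a partition unless something
dominates it, seeding with a dispersion-optimal partition guarantees the
final set contains an entry with exactly optimal dispersion.

**Restricted LCW** is single-criterion LCW (BPI at `w = 1`) started from an
optimal-dispersion completion and run on the penalty-adjusted diversity
matrix, so any exchange breaking a forbidden pair would lower the adjusted
diversity by more than any gain and is never accepted; its output
dispersion equals the exact optimum by construction (property-tested).

Numerics: the inner loops are numba kernels that maintain per-group
diversity sums and each object's nearest/second-nearest within-group
neighbor, making one candidate exchange O(n_a + n_b). Acceptance requires
a gain above `1e-9·(1+|objective|)` to guarantee termination under
floating-point arithmetic. During search the Pareto set is screened with
the kernel's incrementally updated scores; surviving entries are re-scored
from scratch on the raw matrices at the end, so every reported entry
satisfies score == recomputation. Duplicates are detected by the canonical
assignment (clusters relabeled in order of smallest member); clusters are
0-based internally and 1-based in files. A pure-Python from-scratch
reference search in the test suite pins the kernel's full trajectory. All
randomness flows from one caller-supplied generator, so a single seed
reproduces a run bit for bit.

## Synthetic benchmark

The generator draws i.i.d. Gaussian features: mean 0, one common SD per
dataset from {1, 2, 3}, `P` uniform in 2–5, `N` uniform over the multiples
of `K` in [20, 120] (the uniform-over-feasible-values law is our choice;
only the divisibility requirement is inherent), `K ∈ {2,3,4,5}`. Diversity
is scored on squared Euclidean distances of the raw features (a switchable
default). The roster has six methods: restricted LCW with a single or with
100 optimal initializations, and BILS-Hybrid-1/Hybrid-All each with and
without the ILS phase, all at 100 restarts and scored at the Pareto entry
with maximum dispersion. A method's solution is *good* when its diversity
is within 0.1% of the best attained on that dataset (scale-invariant by
construction). Each dataset is labeled by duplicates among the 100
hybrid-all initializations: none / some / maximum restriction.

What the generator does *not* emulate: correlated or non-Gaussian
covariates, categorical features (users pre-code them numerically),
outliers, and missing data. Passing benchmarks therefore demonstrate
algorithmic correctness and relative method behavior under the stated
design, not performance guarantees on arbitrary real data.

Problem sizes in the shipped acceptance runs are desk-scale choices: 200
benchmark datasets (50 per K), a K=5-only rerun that collects up to 100
maximum-restriction datasets (capped at 1400 attempts), 120–500 random
instances for the enumeration cross-checks, and 100 instances (N ≤ 40, 10
restarts) for the hybrid dispersion guarantee — enough for sampling errors
of a few percentage points on the reported rates.

## Known limitations

* The exact diversity ILPs scale to a few dozen objects; beyond that the
  hybrids are the intended tool (the dispersion solver alone scales much
  further). Timeouts raise errors rather than returning silently
  heuristic results.
* Whether cardinality-constrained maximum dispersion is NP-hard at K = 2
  is open; the subset-sum DP here is exact and polynomial for K = 2, and
  no polynomial guarantee is claimed for K ≥ 3.
* Only cannot-link constraints are supported (no must-link).
* The weighted-sum scalarization can in principle miss unsupported Pareto
  points during search; bookkeeping mitigates but does not eliminate this,
  which is why the exact sweep exists for small instances.
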