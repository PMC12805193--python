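"""Anticlustering objective criteria.

Four criteria are supported:

* diversity            -- within-group sum of pairwise dissimilarities
* average diversity    -- per-group sums divided by the group size n_k
* k-means criterion    -- sum of squared distances to cluster centroids
* dispersion           -- minimum dissimilarity within any group

With squared Euclidean distances the k-means criterion equals the average
diversity exactly, which is why the same search machinery can optimize
k-means and k-plus objectives through a distance matrix.
"""

from __future__ import annotations

import numpy as np

from .distances import as_dissimilarity_values
from .partition import Partition

__all__ = [
    "diversity",
    "average_diversity",
    "kmeans_criterion",
    "dispersion",
    "weighted_bicriterion",
    "DISPERSION_SENTINEL",
]

#: Dispersion of an all-singleton partition (vacuous minimum).
DISPERSION_SENTINEL = np.inf


def _check(D: np.ndarray, C: Partition) -> None:
    if D.shape[0] != C.N:
        raise ValueError(
            f"matrix is {D.shape[0]}x{D.shape[0]} but partition has {C.N} objects"
        )


def diversity(D, C: Partition) -> float:
    """Sum of d_ij over all unordered within-group pairs."""
    D = as_dissimilarity_values(D)
    _check(D, C)
    total = 0.0
    for k in range(C.K):
        idx = C.members(k)
        if len(idx) > 1:
            total += D[np.ix_(idx, idx)].sum() / 2.0
    return float(total)


def average_diversity(D, C: Partition) -> float:
    """Per-group pair sums, each divided by the group size n_k."""
    D = as_dissimilarity_values(D)
    _check(D, C)
    total = 0.0
    for k in range(C.K):
        idx = C.members(k)
        if len(idx) > 1:
            total += D[np.ix_(idx, idx)].sum() / 2.0 / len(idx)
    return float(total)


def kmeans_criterion(X, C: Partition) -> float:
    """Sum of squared Euclidean distances of objects to their group centroid."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != C.N:
        raise ValueError("feature matrix and partition disagree on N")
    total = 0.0
    for k in range(C.K):
        rows = X[C.members(k)]
        total += ((rows - rows.mean(axis=0)) ** 2).sum()
    return float(total)


def dispersion(D, C: Partition) -> float:
    """Minimum d_ij over within-group pairs; +inf if all groups are singletons."""
    D = as_dissimilarity_values(D)
    _check(D, C)
    best = DISPERSION_SENTINEL
    for k in range(C.K):
        idx = C.members(k)
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            m = sub[np.triu_indices(len(idx), k=1)].min()
            best = min(best, float(m))
    return best


def weighted_bicriterion(div: float, disp: float, w: float) -> float:
    """Weighted-sum scalarization ``w * diversity + (1 - w) * dispersion``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    return w * div + (1.0 - w) * disp
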