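"""Dissimilarity-matrix construction and feature-matrix augmentation.

Diversity and dispersion both operate on a symmetric matrix of pairwise
dissimilarities d_ij. The constructors here cover the standard choices:
(squared) Euclidean and Manhattan distances from a numeric feature table,
and the normalized Levenshtein distance of Yujian & Bo for word stimuli,

    d(s, t) = 2 L(s, t) / (|s| + |t| + L(s, t)),

with L the unit-cost edit distance, so that d lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

import edlib

__all__ = [
    "DissimilarityMatrix",
    "as_dissimilarity_values",
    "squared_euclidean_matrix",
    "euclidean_matrix",
    "manhattan_matrix",
    "pairwise_dissimilarities",
    "normalized_levenshtein",
    "normalized_levenshtein_matrix",
    "kplus_augment",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric N x N dissimilarities with object labels.

    ``flavor`` is ``"raw"`` for ordinary non-negative dissimilarities and
    ``"adjusted"`` for penalty-adjusted matrices whose forbidden pairs carry
    a large negative entry (used by the exact bicriterion method).
    """

    values: np.ndarray
    object_ids: list[str] = field(default_factory=list)
    flavor: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, rtol=0, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        if self.flavor == "raw":
            if not np.isfinite(v).all():
                raise ValueError("dissimilarities must be finite")
            if (v < 0).any():
                raise ValueError("raw dissimilarities must be non-negative")
        self.values = v
        if not self.object_ids:
            self.object_ids = [str(i + 1) for i in range(v.shape[0])]
        elif len(self.object_ids) != v.shape[0]:
            raise ValueError("object_ids length must match matrix size")

    @property
    def N(self) -> int:
        return self.values.shape[0]


def as_dissimilarity_values(D) -> np.ndarray:
    """Accept a DissimilarityMatrix or a plain symmetric ndarray."""
    if isinstance(D, DissimilarityMatrix):
        return D.values
    return np.asarray(D, dtype=float)


def _check_features(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite entries")
    if X.shape[0] < 2:
        raise ValueError("need at least two objects")
    return X


def squared_euclidean_matrix(X) -> DissimilarityMatrix:
    """d_ij = sum_p (x_ip - x_jp)^2."""
    X = _check_features(X)
    return DissimilarityMatrix(squareform(pdist(X, metric="sqeuclidean")))


def euclidean_matrix(X) -> DissimilarityMatrix:
    X = _check_features(X)
    return DissimilarityMatrix(squareform(pdist(X, metric="euclidean")))


def manhattan_matrix(X) -> DissimilarityMatrix:
    X = _check_features(X)
    return DissimilarityMatrix(squareform(pdist(X, metric="cityblock")))


_METRICS = {
    "squared-euclidean": squared_euclidean_matrix,
    "euclidean": euclidean_matrix,
    "manhattan": manhattan_matrix,
}


def pairwise_dissimilarities(X, metric: str = "squared-euclidean") -> DissimilarityMatrix:
    try:
        builder = _METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(_METRICS)}"
        ) from None
    return builder(X)


def normalized_levenshtein(a: str, b: str) -> float:
    """Normalized edit distance in [0, 1] (0 = identical strings)."""
    if not a or not b:
        raise ValueError("words must be non-empty strings")
    if a == b:
        return 0.0
    L = edlib.align(a, b)["editDistance"]
    return 2.0 * L / (len(a) + len(b) + L)


def normalized_levenshtein_matrix(words: Sequence[str]) -> DissimilarityMatrix:
    """Pairwise normalized Levenshtein distances for a list of words."""
    words = list(words)
    if any((not isinstance(w, str)) or (not w) for w in words):
        raise ValueError("words must be non-empty strings")
    n = len(words)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = normalized_levenshtein(words[i], words[j])
    return DissimilarityMatrix(D, object_ids=list(words))


def kplus_augment(X, moments: int = 2) -> np.ndarray:
    """Append central-moment columns so mean-equating also equates spread.

    For ``moments=2`` each feature j gains a column ``(x_ij - mean_j)**2``;
    optimizing a k-means-type criterion on the augmented matrix then equates
    group means of both the raw features and their squared deviations, i.e.
    means and variances. Higher ``moments`` append higher central powers.
    """
    X = _check_features(X)
    if moments < 2:
        raise ValueError("moments must be >= 2")
    cols = [X]
    centered = X - X.mean(axis=0, keepdims=True)
    for m in range(2, moments + 1):
        cols.append(centered**m)
    return np.hstack(cols)
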