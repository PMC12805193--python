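"""Partitions with fixed group cardinalities.

A partition assigns each of N objects to one of K groups. Anticlustering
applications almost always fix the group sizes in advance ("cardinality
constraints"), most commonly as an equal split, so the partition type
validates and carries the size vector explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Partition",
    "canonical_assignment",
    "partition_count",
    "random_partition",
]


def canonical_assignment(assignment: np.ndarray) -> tuple[int, ...]:
    """Relabel clusters in order of their smallest member index.

    Two assignments describe the same (unlabeled) partition exactly when
    their canonical forms are equal, which is how duplicates are detected
    throughout the package.
    """
    assignment = np.asarray(assignment)
    mapping: dict[int, int] = {}
    out = np.empty(len(assignment), dtype=np.int64)
    for i, lab in enumerate(assignment):
        lab = int(lab)
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return tuple(int(x) for x in out)


@dataclass(frozen=True)
class Partition:
    """Assignment of N objects to K non-empty groups of fixed sizes.

    Parameters
    ----------
    assignment
        Integer labels in ``[0, K)``, one per object (0-based internally;
        file output uses 1-based cluster labels).
    K
        Number of groups. Inferred from the labels when omitted.
    """

    assignment: np.ndarray
    K: int = 0
    sizes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64)
        object.__setattr__(self, "assignment", a)
        k = int(self.K) if self.K else int(a.max()) + 1
        object.__setattr__(self, "K", k)
        if a.ndim != 1 or len(a) < 2:
            raise ValueError("assignment must be a 1-D array of length >= 2")
        if a.min() < 0 or a.max() >= k:
            raise ValueError(f"cluster labels must lie in [0, {k})")
        sizes = np.bincount(a, minlength=k)
        if (sizes == 0).any():
            raise ValueError("every cluster must be non-empty")
        object.__setattr__(self, "sizes", sizes)

    @property
    def N(self) -> int:
        return len(self.assignment)

    def canonical(self) -> tuple[int, ...]:
        return canonical_assignment(self.assignment)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == k)

    def __eq__(self, other: object) -> bool:  # partition identity = canonical form
        if not isinstance(other, Partition):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())


def partition_count(N: int, K: int) -> int:
    """Number of distinct partitions of N objects into K unlabeled equal groups.

    Computed exactly (arbitrary precision) as the product of binomial
    coefficients ``C(N - i*n, n)`` over the K groups of size ``n = N/K``,
    divided by ``K!`` to discount group relabelings.
    """
    if K < 1 or N < 1:
        raise ValueError("N and K must be positive")
    if N % K != 0:
        raise ValueError(f"K={K} must divide N={N} for equal-sized groups")
    n = N // K
    total = 1
    remaining = N
    for _ in range(K):
        total *= math.comb(remaining, n)
        remaining -= n
    return total // math.factorial(K)


def random_partition(
    N: int, sizes: np.ndarray | list[int], rng: np.random.Generator
) -> Partition:
    """Uniform random partition with the given cardinalities."""
    sizes = np.asarray(sizes, dtype=np.int64)
    if sizes.sum() != N:
        raise ValueError("group sizes must sum to N")
    labels = np.repeat(np.arange(len(sizes)), sizes)
    rng.shuffle(labels)
    return Partition(labels, K=len(sizes))
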