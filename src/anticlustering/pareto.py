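"""Pareto bookkeeping for (diversity, dispersion) pairs.

A partition dominates another when it is at least as good on both criteria
and strictly better on one. Bicriterion search maintains the list of
mutually non-dominated partitions seen so far; score comparisons are exact
(no tolerance), as required for the set to be order-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .partition import Partition

__all__ = ["ParetoEntry", "ParetoSet", "dominates", "pareto_update"]


@dataclass(frozen=True)
class ParetoEntry:
    partition: Partition
    diversity: float
    dispersion: float

    @property
    def scores(self) -> tuple[float, float]:
        return (self.diversity, self.dispersion)


def dominates(a: ParetoEntry, b: ParetoEntry) -> bool:
    """True iff ``a`` is no worse on both criteria and strictly better on one."""
    return (
        a.diversity >= b.diversity
        and a.dispersion >= b.dispersion
        and (a.diversity > b.diversity or a.dispersion > b.dispersion)
    )


@dataclass
class ParetoSet:
    """Ordered list of mutually non-dominated entries, deduplicated.

    Duplicates are detected by the canonical assignment vector, so cluster
    relabelings of an already-stored partition are never inserted twice.
    """

    entries: list[ParetoEntry] = field(default_factory=list)
    _keys: set[tuple[int, ...]] = field(default_factory=set, repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def would_reject(self, div: float, disp: float, margin: float = 0.0) -> bool:
        """Cheap pre-screen: is (div, disp) dominated by some entry by > margin?

        Used with approximate scores from the incremental search kernel;
        ``margin > 0`` keeps borderline candidates alive for an exact check.
        """
        for e in self.entries:
            if e.diversity >= div + margin and e.dispersion >= disp + margin:
                if e.diversity > div + margin or e.dispersion > disp + margin:
                    return True
        return False

    def add(self, entry: ParetoEntry) -> bool:
        """Insert unless dominated or duplicate; drop entries it dominates."""
        key = entry.partition.canonical()
        if key in self._keys:
            return False
        for e in self.entries:
            if dominates(e, entry):
                return False
        kept = []
        for e in self.entries:
            if dominates(entry, e):
                self._keys.discard(e.partition.canonical())
            else:
                kept.append(e)
        kept.append(entry)
        self.entries = kept
        self._keys.add(key)
        return True

    def score_pairs(self) -> set[tuple[float, float]]:
        return {e.scores for e in self.entries}

    def best(self, rule: str = "max-dispersion") -> ParetoEntry:
        """Select one entry; ties on the primary criterion break by the other."""
        if not self.entries:
            raise ValueError("Pareto set is empty")
        if rule == "max-dispersion":
            return max(self.entries, key=lambda e: (e.dispersion, e.diversity))
        if rule == "max-diversity":
            return max(self.entries, key=lambda e: (e.diversity, e.dispersion))
        raise ValueError(f"unknown selection rule {rule!r}")


def pareto_update(S: ParetoSet, entry: ParetoEntry) -> ParetoSet:
    """Functional wrapper around :meth:`ParetoSet.add` (mutates and returns S)."""
    S.add(entry)
    return S
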