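"""Weighted taxon bipartitions (splits) and split systems.

A split cuts the taxon set in two.  Splits are stored in a canonical
orientation — ``side_a`` is the side containing taxon index 0 — so that a
split and its complement compare and hash identically.  A
:class:`SplitSystem` bundles splits over one taxon set, either as the
circular system produced by the neighbour-net agglomeration or as a
frequency-weighted system from bootstrap consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .matrix import DistanceMatrix, ValidationError

__all__ = ["Split", "SplitSystem", "CircularOrdering", "splits_to_distance"]


@dataclass(frozen=True)
class Split:
    """A bipartition of taxon indices ``0..n_taxa-1`` with a weight."""

    side_a: frozenset[int]
    n_taxa: int
    weight: float = 1.0

    @classmethod
    def of(cls, side: Iterable[int], n_taxa: int, weight: float = 1.0) -> "Split":
        """Build a split in canonical orientation (side containing taxon 0)."""
        side = frozenset(int(i) for i in side)
        if not side or len(side) >= n_taxa:
            raise ValidationError(
                f"split side must be a nonempty proper subset of {n_taxa} taxa"
            )
        if any(i < 0 or i >= n_taxa for i in side):
            raise ValidationError("split references taxon index out of range")
        if 0 not in side:
            side = frozenset(range(n_taxa)) - side
        return cls(side, n_taxa, float(weight))

    @property
    def side_b(self) -> frozenset[int]:
        return frozenset(range(self.n_taxa)) - self.side_a

    @property
    def size(self) -> int:
        """Size of the smaller side."""
        return min(len(self.side_a), self.n_taxa - len(self.side_a))

    @property
    def is_trivial(self) -> bool:
        return self.size == 1

    def separates(self, i: int, j: int) -> bool:
        return (i in self.side_a) != (j in self.side_a)

    def key(self) -> frozenset[int]:
        """Orientation-independent identity (weight ignored)."""
        return self.side_a

    def with_weight(self, weight: float) -> "Split":
        return Split(self.side_a, self.n_taxa, float(weight))

    def compatible_with(self, other: "Split") -> bool:
        """Two splits are compatible iff some pair of opposite sides is disjoint."""
        a1, b1 = self.side_a, self.side_b
        a2, b2 = other.side_a, other.side_b
        return (
            not (a1 & a2) or not (a1 & b2) or not (b1 & a2) or not (b1 & b2)
        )


@dataclass(frozen=True)
class CircularOrdering:
    """A permutation of taxon indices giving a circular taxon arrangement."""

    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ValidationError("circular ordering must be a permutation of 0..n-1")

    def __len__(self) -> int:
        return len(self.order)

    def position(self) -> dict[int, int]:
        return {t: p for p, t in enumerate(self.order)}


@dataclass
class SplitSystem:
    """A set of weighted splits over one ordered taxon set."""

    taxa: list[str]
    splits: list[Split] = field(default_factory=list)
    circular_order: CircularOrdering | None = None
    kind: str = "circular"  # or "frequency"

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValidationError("duplicate taxon labels in split system")
        for s in self.splits:
            if s.n_taxa != n:
                raise ValidationError("split taxon count does not match system")
            if s.weight < 0:
                raise ValidationError("split weights must be nonnegative")
        if self.circular_order is not None:
            if len(self.circular_order) != n:
                raise ValidationError("circular ordering length mismatch")
            pos = self.circular_order.position()
            for s in self.splits:
                if not _is_interval(sorted(pos[i] for i in s.side_a), n):
                    raise ValidationError(
                        "split is not an interval of the circular ordering"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def nontrivial(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial]

    def split_labels(self, split: Split) -> tuple[tuple[str, ...], tuple[str, ...]]:
        a = tuple(self.taxa[i] for i in sorted(split.side_a))
        b = tuple(self.taxa[i] for i in sorted(split.side_b))
        return a, b


def _is_interval(positions: list[int], n: int) -> bool:
    """True if the positions form a contiguous arc on the n-cycle."""
    k = len(positions)
    if k in (0, n):
        return True
    present = [False] * n
    for p in positions:
        present[p] = True
    # count circular runs of present positions
    runs = sum(
        1 for i in range(n) if present[i] and not present[(i - 1) % n]
    )
    return runs == 1


def splits_to_distance(system: SplitSystem) -> DistanceMatrix:
    """Induced metric: d(i, j) = sum of weights of splits separating i and j."""
    n = system.n_taxa
    d = np.zeros((n, n), dtype=float)
    for s in system.splits:
        mask = np.zeros(n, dtype=bool)
        mask[list(s.side_a)] = True
        sep = mask[:, None] != mask[None, :]
        d[sep] += s.weight
    # split-induced metrics are not bounded by 1, so use the relaxed subclass
    return _UnboundedDistanceMatrix(system.taxa, d)


class _UnboundedDistanceMatrix(DistanceMatrix):
    """Distance matrix whose entries may exceed 1 (split-induced metrics)."""

    def validate(self) -> None:  # relax the [0, 1] range check only
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("matrix must be symmetric")
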