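"""Core data structures: categorical character matrices and distance matrices.

A :class:`CharacterMatrix` stores taxa as rows and unordered categorical
characters (binary or ternary) as columns.  Cells are sets of state symbols:
a singleton set is a defined observation, the empty set is a missing
observation, and a set of two or more symbols records ambiguity.  Distances
derived from such matrices are held in :class:`DistanceMatrix` together with
the per-pair count of characters that were actually comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "CharacterDefinition",
    "CellValue",
    "CharacterMatrix",
    "DistanceMatrix",
    "MISSING",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class CharacterDefinition:
    """Schema entry for one character column.

    ``index`` is the 1-based character number as used in annotated character
    lists; ``max_state`` is 1 for binary and 2 for ternary characters.
    """

    index: int
    label: str = ""
    state_labels: Mapping[str, str] = field(default_factory=dict)
    max_state: int = 2

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"character index must be >= 1, got {self.index}")
        if self.max_state not in (1, 2):
            raise ValidationError(
                f"character {self.index}: max_state must be 1 (binary) or 2 "
                f"(ternary), got {self.max_state}"
            )

    @property
    def states(self) -> tuple[int, ...]:
        return tuple(range(self.max_state + 1))


@dataclass(frozen=True)
class CellValue:
    """One matrix cell: a (possibly empty) set of integer state symbols."""

    states: frozenset[int]

    @classmethod
    def missing(cls) -> "CellValue":
        return cls(frozenset())

    @classmethod
    def defined(cls, state: int) -> "CellValue":
        return cls(frozenset((int(state),)))

    @classmethod
    def ambiguous(cls, states: Iterable[int]) -> "CellValue":
        s = frozenset(int(x) for x in states)
        if len(s) < 2:
            raise ValidationError("ambiguous cell needs at least two states")
        return cls(s)

    @property
    def kind(self) -> str:
        n = len(self.states)
        if n == 0:
            return "missing"
        if n == 1:
            return "defined"
        return "ambiguous"

    @property
    def is_missing(self) -> bool:
        return not self.states

    @property
    def is_defined(self) -> bool:
        return len(self.states) == 1

    @property
    def state(self) -> int:
        """The single state of a defined cell."""
        if len(self.states) != 1:
            raise ValidationError(f"cell of kind {self.kind!r} has no single state")
        return next(iter(self.states))


MISSING = CellValue.missing()


class CharacterMatrix:
    """Taxa-by-characters grid of categorical cells.

    Parameters
    ----------
    taxa:
        Ordered, unique taxon labels.
    characters:
        Ordered character schema; one entry per column.
    cells:
        Row-major grid, ``cells[i][j]`` for taxon ``i``, character ``j``.
    provenance:
        Optional free-text annotations keyed by ``(taxon, character_index)``.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[CharacterDefinition],
        cells: Sequence[Sequence[CellValue]],
        provenance: Mapping[tuple[str, int], str] | None = None,
    ) -> None:
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.cells = [list(row) for row in cells]
        self.provenance = dict(provenance or {})
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        if not self.taxa:
            raise ValidationError("matrix must contain at least one taxon")
        if len(self._taxon_index) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        if len(self.cells) != len(self.taxa):
            raise ValidationError(
                f"grid has {len(self.cells)} rows for {len(self.taxa)} taxa"
            )
        ncols = len(self.characters)
        seen_idx: set[int] = set()
        for c in self.characters:
            if c.index in seen_idx:
                raise ValidationError(f"duplicate character index {c.index}")
            seen_idx.add(c.index)
        for t, row in zip(self.taxa, self.cells):
            if len(row) != ncols:
                raise ValidationError(
                    f"taxon {t!r}: row has {len(row)} cells, expected {ncols}"
                )
            for c, cell in zip(self.characters, row):
                bad = [s for s in cell.states if s < 0 or s > c.max_state]
                if bad:
                    raise ValidationError(
                        f"taxon {t!r}, character {c.index}: state(s) {bad} "
                        f"exceed declared maximum {c.max_state}"
                    )

    # -- basic access ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self._taxon_index[taxon]
        except KeyError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def cell(self, taxon: str, column: int) -> CellValue:
        return self.cells[self.taxon_index(taxon)][column]

    def row(self, taxon: str) -> list[CellValue]:
        return list(self.cells[self.taxon_index(taxon)])

    # -- numpy views ----------------------------------------------------

    def state_array(self) -> np.ndarray:
        """Defined singleton states as int8; missing/ambiguous cells are -1."""
        a = np.full((self.n_taxa, self.n_characters), -1, dtype=np.int8)
        for i, row in enumerate(self.cells):
            for j, cell in enumerate(row):
                if cell.is_defined:
                    a[i, j] = cell.state
        return a

    def state_set_array(self) -> np.ndarray:
        """Cells as uint8 bitmasks (bit k = state k); missing = all legal states.

        This is the representation used by parsimony scoring, where a missing
        cell is free to take any legal state and an ambiguity set constrains
        the choice to its members.
        """
        a = np.zeros((self.n_taxa, self.n_characters), dtype=np.uint8)
        full = [sum(1 << s for s in c.states) for c in self.characters]
        for i, row in enumerate(self.cells):
            for j, cell in enumerate(row):
                if cell.is_missing:
                    a[i, j] = full[j]
                else:
                    a[i, j] = sum(1 << s for s in cell.states)
        return a

    # -- restriction ----------------------------------------------------

    def restrict(
        self,
        taxa: Sequence[str] | None = None,
        columns: Sequence[int] | None = None,
    ) -> "CharacterMatrix":
        """Sub-matrix over the given taxa (by label) and columns (0-based)."""
        taxa = list(self.taxa) if taxa is None else list(taxa)
        columns = list(range(self.n_characters)) if columns is None else list(columns)
        rows = [self.taxon_index(t) for t in taxa]
        chars = [self.characters[j] for j in columns]
        cells = [[self.cells[i][j] for j in columns] for i in rows]
        keep_idx = {c.index for c in chars}
        prov = {
            (t, k): v
            for (t, k), v in self.provenance.items()
            if t in set(taxa) and k in keep_idx
        }
        return CharacterMatrix(taxa, chars, cells, prov)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and self.cells == other.cells
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


class DistanceMatrix:
    """Symmetric matrix of pairwise distances in [0, 1] with zero diagonal."""

    def __init__(
        self,
        taxa: Sequence[str],
        values: np.ndarray,
        comparable_counts: np.ndarray | None = None,
    ) -> None:
        self.taxa = list(taxa)
        self.values = np.asarray(values, dtype=float)
        if comparable_counts is None:
            comparable_counts = np.zeros_like(self.values, dtype=int)
        self.comparable_counts = np.asarray(comparable_counts, dtype=int)
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self.validate()

    def validate(self) -> None:
        n = len(self.taxa)
        if len(self._taxon_index) != n:
            raise ValidationError("duplicate taxon labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} taxa"
            )
        if self.comparable_counts.shape != (n, n):
            raise ValidationError("comparable_counts shape mismatch")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValidationError("distance matrix must be symmetric")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < -1e-12) or np.any(self.values[finite] > 1 + 1e-12):
            raise ValidationError("distances must lie in [0, 1]")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self._taxon_index[taxon]
        except KeyError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxon_index(a), self.taxon_index(b)])

    def comparable(self, a: str, b: str) -> int:
        return int(self.comparable_counts[self.taxon_index(a), self.taxon_index(b)])

    def restrict(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxon_index(t) for t in taxa]
        return DistanceMatrix(
            list(taxa),
            self.values[np.ix_(idx, idx)],
            self.comparable_counts[np.ix_(idx, idx)],
        )

    def __repr__(self) -> str:
        return f"<DistanceMatrix {self.n_taxa} taxa>"
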