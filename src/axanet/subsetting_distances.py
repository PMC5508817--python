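"""Taxon exclusion, invariant-character removal, and mean Hamming distances.

The analysis pipeline applies two filters before distances are computed:
taxa with more than 60% missing cells (measured against the full parent
matrix) are dropped, then characters without at least two distinct defined
states within the retained taxon set are removed.  Distances are mean
character differences with pairwise deletion — ambiguous cells are treated
as incomparable, so a distance of 0.1 means the pair differs in 10% of the
characters defined in both taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .matrix import CharacterMatrix, DistanceMatrix, ValidationError

__all__ = [
    "SubsetDefinition",
    "SubsetMatrix",
    "SubsetWarning",
    "ComputationError",
    "missing_fraction",
    "exclude_sparse_taxa",
    "variable_characters",
    "build_subset",
    "mean_hamming",
    "distance_summary",
    "DistanceSummary",
    "load_subset_definitions",
    "packaged_subset_definitions",
]


class ComputationError(RuntimeError):
    """A distance or statistic could not be computed from the given data."""


class SubsetWarning(UserWarning):
    pass


@dataclass
class SubsetDefinition:
    """A named taxon subset.

    Membership can be given as an explicit taxon list, as a list of label
    prefixes (typically genus names) resolved against a concrete matrix, or
    both.  ``exclude`` removes taxa after prefix resolution.
    """

    name: str
    taxa: list[str] = field(default_factory=list)
    prefixes: list[str] = field(default_factory=list)
    exclude: list[str] = field(default_factory=list)
    notes: str = ""

    def resolve(self, matrix: CharacterMatrix) -> list[str]:
        """Member taxa present in the matrix, in matrix order."""
        members: set[str] = set()
        explicit_missing = [t for t in self.taxa if t not in set(matrix.taxa)]
        members.update(t for t in self.taxa if t in set(matrix.taxa))
        for p in self.prefixes:
            members.update(t for t in matrix.taxa if t.startswith(p))
        for e in self.exclude:
            members.discard(e)
            members -= {t for t in matrix.taxa if t.startswith(e)}
        resolved = [t for t in matrix.taxa if t in members]
        if not resolved:
            raise ValidationError(
                f"subset {self.name!r} resolves to no taxa in the matrix"
                + (f" (missing: {explicit_missing})" if explicit_missing else "")
            )
        return resolved


@dataclass
class SubsetMatrix:
    """A matrix restricted to a subset, with full drop provenance."""

    parent: CharacterMatrix
    matrix: CharacterMatrix
    dropped_taxa: list[str]
    dropped_characters: list[int]  # 1-based character indices


def missing_fraction(matrix: CharacterMatrix, taxon: str) -> float:
    """Fraction of missing cells for one taxon (ambiguous cells count as data)."""
    row = matrix.cells[matrix.taxon_index(taxon)]
    return sum(1 for c in row if c.is_missing) / len(row)


def exclude_sparse_taxa(
    matrix: CharacterMatrix, threshold: float = 0.6
) -> SubsetMatrix:
    """Drop every taxon whose missing fraction strictly exceeds ``threshold``."""
    dropped = [t for t in matrix.taxa if missing_fraction(matrix, t) > threshold]
    kept = [t for t in matrix.taxa if t not in set(dropped)]
    if not kept:
        raise ComputationError(
            f"all {matrix.n_taxa} taxa exceed the {threshold:.0%} missing-data "
            "threshold"
        )
    return SubsetMatrix(
        parent=matrix,
        matrix=matrix.restrict(taxa=kept),
        dropped_taxa=dropped,
        dropped_characters=[],
    )


def variable_characters(
    matrix: CharacterMatrix, taxa: Sequence[str] | None = None
) -> list[int]:
    """0-based columns with >= 2 distinct defined singleton states among ``taxa``.

    Ambiguous and missing cells never establish variability.
    """
    taxa = list(matrix.taxa) if taxa is None else list(taxa)
    rows = [matrix.taxon_index(t) for t in taxa]
    out = []
    for j in range(matrix.n_characters):
        states = {
            matrix.cells[i][j].state
            for i in rows
            if matrix.cells[i][j].is_defined
        }
        if len(states) >= 2:
            out.append(j)
    return out


def build_subset(
    matrix: CharacterMatrix,
    definition: SubsetDefinition | None = None,
    sparsity_threshold: float = 0.6,
) -> SubsetMatrix:
    """Resolve a subset, drop sparse taxa, then drop invariant characters.

    The sparsity rule is evaluated against the full parent character set;
    the variability rule against the retained focal taxa only.
    """
    taxa = definition.resolve(matrix) if definition else list(matrix.taxa)
    dropped_taxa = [
        t for t in taxa if missing_fraction(matrix, t) > sparsity_threshold
    ]
    kept = [t for t in taxa if t not in set(dropped_taxa)]
    if len(kept) < 2:
        raise ComputationError(
            f"subset {(definition.name if definition else 'all')!r}: fewer than "
            "2 taxa remain after the missing-data filter"
        )
    if len(kept) < 4:
        import warnings

        warnings.warn(
            f"subset retains only {len(kept)} taxa; quartet statistics are "
            "undefined below 4",
            SubsetWarning,
            stacklevel=2,
        )
    keep_cols = variable_characters(matrix, kept)
    dropped_chars = [
        matrix.characters[j].index
        for j in range(matrix.n_characters)
        if j not in set(keep_cols)
    ]
    if not keep_cols:
        raise ComputationError(
            "no variable characters remain within the subset"
        )
    return SubsetMatrix(
        parent=matrix,
        matrix=matrix.restrict(taxa=kept, columns=keep_cols),
        dropped_taxa=dropped_taxa,
        dropped_characters=dropped_chars,
    )


def mean_hamming(matrix: CharacterMatrix) -> DistanceMatrix:
    """Pairwise mean character difference with pairwise deletion.

    For each pair the comparable characters are those with defined singleton
    states in both taxa; the distance is the mismatch count divided by the
    number of comparable characters.  A pair with no comparable characters is
    an error (the caller is expected to have filtered sparse taxa first).
    """
    if matrix.n_taxa < 2:
        raise ComputationError("need at least 2 taxa for distances")
    a = matrix.state_array()          # -1 = missing/ambiguous
    defined = a >= 0
    n = matrix.n_taxa
    # comparable[i, j] = #columns defined in both; mismatch via broadcasting
    comp = (defined[:, None, :] & defined[None, :, :])
    mism = comp & (a[:, None, :] != a[None, :, :])
    counts = comp.sum(axis=2)
    mismatches = mism.sum(axis=2)
    off = ~np.eye(n, dtype=bool)
    if np.any(counts[off] == 0):
        i, j = np.argwhere((counts == 0) & off)[0]
        raise ComputationError(
            f"taxa {matrix.taxa[i]!r} and {matrix.taxa[j]!r} share no "
            "comparable characters"
        )
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, mismatches / np.maximum(counts, 1), 0.0)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(matrix.taxa, values, counts)


@dataclass(frozen=True)
class DistanceSummary:
    max_distance: float
    max_pair: tuple[str, str]
    zero_pairs: tuple[tuple[str, str], ...]

    @property
    def n_zero_pairs(self) -> int:
        return len(self.zero_pairs)


def distance_summary(d: DistanceMatrix) -> DistanceSummary:
    """Exact maximum off-diagonal entry and census of zero-distance pairs."""
    n = d.n_taxa
    iu = np.triu_indices(n, k=1)
    vals = d.values[iu]
    if len(vals) == 0:
        raise ComputationError("distance summary needs at least 2 taxa")
    best = int(np.argmax(vals))
    zeros = tuple(
        (d.taxa[i], d.taxa[j])
        for i, j in zip(*iu)
        if d.values[i, j] == 0.0
    )
    return DistanceSummary(
        max_distance=float(vals[best]),
        max_pair=(d.taxa[iu[0][best]], d.taxa[iu[1][best]]),
        zero_pairs=zeros,
    )


# ---------------------------------------------------------------------------
# named subset configuration
# ---------------------------------------------------------------------------


def load_subset_definitions(path: str | Path) -> dict[str, SubsetDefinition]:
    """Load subset definitions from a YAML mapping name -> spec.

    Each spec may have ``taxa``, ``prefixes``, ``exclude`` and ``notes``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, SubsetDefinition] = {}
    for name, spec in raw.items():
        spec = spec or {}
        out[name] = SubsetDefinition(
            name=name,
            taxa=list(spec.get("taxa", [])),
            prefixes=list(spec.get("prefixes", [])),
            exclude=list(spec.get("exclude", [])),
            notes=str(spec.get("notes", "")),
        )
    return out


def packaged_subset_definitions() -> dict[str, SubsetDefinition]:
    """The named subsets shipped with the package."""
    here = Path(__file__).parent / "data" / "subsets.yml"
    return load_subset_definitions(here)
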