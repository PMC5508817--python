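"""Character-resampling bootstrap, split supports, consensus networks.

Each pseudoreplicate resamples characters with replacement, builds one tree
(BioNJ on mean Hamming distances, or an NNI parsimony search), and records
the tree's nontrivial splits.  Split frequencies over all replicates are the
bootstrap supports; splits at or above a frequency cutoff form the
frequency-weighted consensus ("bipartition") network.

Randomness: one master seed; replicate ``r`` uses the independent stream
seeded by ``(seed, r)`` so any replicate is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix, DistanceMatrix, ValidationError
from .splits import Split, SplitSystem
from .subsetting_distances import ComputationError, mean_hamming
from .tree_inference import bionj, parsimony_search, tree_splits

__all__ = [
    "BootstrapConfig",
    "SupportTable",
    "resample_characters",
    "bootstrap_supports",
    "support_for",
    "consensus_network",
]


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 10000
    criterion: str = "nj_ls"            # or "parsimony"
    seed: int = 0
    min_consensus_freq: float = 0.10

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not 0.0 <= self.min_consensus_freq <= 1.0:
            raise ValidationError("min_consensus_freq must lie in [0, 1]")
        if self.criterion not in ("nj_ls", "parsimony"):
            raise ValidationError(f"unknown criterion {self.criterion!r}")


@dataclass
class SupportTable:
    taxa: list[str]
    frequencies: dict[frozenset[int], float] = field(default_factory=dict)
    replicates_completed: int = 0
    replicates_skipped: int = 0

    def items(self):
        return self.frequencies.items()


def resample_characters(matrix: CharacterMatrix, rng: np.random.Generator) -> CharacterMatrix:
    """Draw characters with replacement up to the original character count.

    The resampled matrix records the drawn source columns (0-based) in its
    ``resample_sources`` attribute; character indices are renumbered 1..m.
    """
    m = matrix.n_characters
    if m < 1:
        raise ValidationError("matrix has no characters to resample")
    picks = np.sort(rng.integers(0, m, size=m))
    chars = []
    for new_idx, j in enumerate(picks, start=1):
        src = matrix.characters[j]
        chars.append(
            type(src)(
                index=new_idx,
                label=src.label,
                state_labels=src.state_labels,
                max_state=src.max_state,
            )
        )
    cells = [[row[j] for j in picks] for row in matrix.cells]
    out = CharacterMatrix(matrix.taxa, chars, cells)
    out.resample_sources = [int(j) for j in picks]  # type: ignore[attr-defined]
    return out


def _pair_profiles(matrix: CharacterMatrix):
    """Per-pair per-character comparability and mismatch indicator matrices."""
    a = matrix.state_array()
    defined = a >= 0
    n, m = a.shape
    ii, jj = np.triu_indices(n, k=1)
    comp = defined[ii] & defined[jj]                      # pairs x chars
    mism = comp & (a[ii] != a[jj])
    return ii, jj, comp.astype(np.float64), mism.astype(np.float64)


def bootstrap_supports(
    matrix: CharacterMatrix, config: BootstrapConfig
) -> SupportTable:
    """Split frequencies over character-resampled single-tree replicates.

    Replicates in which some taxon pair has no comparable characters are
    skipped and counted; more than 10% skipped aborts (signal too sparse).
    """
    n = matrix.n_taxa
    if n < 4:
        raise ValidationError("bootstrap supports need at least 4 taxa")
    m = matrix.n_characters
    counts: dict[frozenset[int], int] = {}
    skipped = 0
    completed = 0

    ii, jj, comp, mism = _pair_profiles(matrix)

    for r in range(config.replicates):
        rng = np.random.default_rng([config.seed, r])
        if config.criterion == "nj_ls":
            w = np.bincount(rng.integers(0, m, size=m), minlength=m).astype(
                np.float64
            )
            comparable = comp @ w
            if np.any(comparable == 0):
                skipped += 1
                continue
            dist = (mism @ w) / comparable
            dm = np.zeros((n, n))
            dm[ii, jj] = dist
            dm = dm + dm.T
            tree = bionj(DistanceMatrix(matrix.taxa, dm))
        else:
            resampled = resample_characters(matrix, rng)
            try:
                start = bionj(mean_hamming(resampled))
            except ComputationError:
                skipped += 1
                continue
            tree = parsimony_search(resampled, start=start, seed=int(r))
        completed += 1
        for split in tree_splits(tree):
            counts[split.key()] = counts.get(split.key(), 0) + 1

    if completed == 0 or skipped / config.replicates > 0.10:
        raise ComputationError(
            f"{skipped}/{config.replicates} bootstrap replicates had a taxon "
            "pair with no comparable characters; signal too sparse"
        )
    freqs = {k: v / completed for k, v in counts.items()}
    return SupportTable(
        taxa=list(matrix.taxa),
        frequencies=freqs,
        replicates_completed=completed,
        replicates_skipped=skipped,
    )


def support_for(table: SupportTable, side_a: set[str]) -> float:
    """Bootstrap frequency of the bipartition ``side_a`` vs the rest."""
    n = len(table.taxa)
    index = {t: i for i, t in enumerate(table.taxa)}
    unknown = [t for t in side_a if t not in index]
    if unknown:
        raise KeyError(f"unknown taxa in split query: {unknown}")
    ids = {index[t] for t in side_a}
    if not 0 < len(ids) < n:
        raise ValidationError("split side must be a nonempty proper subset")
    split = Split.of(ids, n)
    if split.is_trivial:
        raise ValidationError(
            "trivial (single-taxon) splits are not tabulated by the bootstrap"
        )
    return table.frequencies.get(split.key(), 0.0)


def consensus_network(table: SupportTable, min_freq: float = 0.10) -> SplitSystem:
    """Frequency-weighted consensus of the bootstrap sample.

    Keeps splits with frequency >= ``min_freq`` (weight = frequency) and adds
    the trivial splits at weight 1 so the system stays drawable.
    """
    n = len(table.taxa)
    splits = [
        Split(side, n, freq)
        for side, freq in sorted(
            table.frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        )
        if freq >= min_freq
    ]
    for i in range(n):
        splits.append(Split.of({i}, n, 1.0))
    return SplitSystem(taxa=list(table.taxa), splits=splits, kind="frequency")


def write_support_table(table: SupportTable, path) -> None:
    """TSV: smaller split side as comma-joined labels, frequency, count."""
    from pathlib import Path

    lines = ["split\tfrequency\tcount"]
    for side, freq in sorted(
        table.frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
    ):
        small = side if len(side) <= len(table.taxa) / 2 else (
            frozenset(range(len(table.taxa))) - side
        )
        labels = ",".join(table.taxa[i] for i in sorted(small))
        lines.append(
            f"{labels}\t{freq:.6f}\t{round(freq * table.replicates_completed)}"
        )
    lines.append(
        f"#replicates\t{table.replicates_completed}\tskipped={table.replicates_skipped}"
    )
    Path(path).write_text("\n".join(lines) + "\n")
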