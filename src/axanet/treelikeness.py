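"""Quartet-based treelikeness statistics.

For four taxa w, x, y, z the three pairings of the six pairwise distances
give sums s1, s2, s3; ordered m1 >= m2 >= m3, the quartet delta is
``(m1 - m2) / (m1 - m3)`` (0 when m1 = m3).  A tree metric satisfies the
four-point condition, making the two largest sums equal and the delta 0; a
star-like, conflicting signal drives it toward 1.  The matrix value (mDV)
averages all quartets; the individual value (iDV) of a taxon averages the
quartets containing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .matrix import DistanceMatrix

__all__ = ["DeltaReport", "quartet_delta", "delta_report", "write_delta_report"]


@dataclass(frozen=True)
class DeltaReport:
    mdv: float
    idv: dict[str, float]
    idv_quartet_counts: dict[str, int]
    quartets_evaluated: int
    quartets_skipped: int


def quartet_delta(d: DistanceMatrix, quartet: Sequence[str]) -> float:
    """Delta of one quartet of taxon labels; all six distances must be defined."""
    if len(set(quartet)) != 4:
        raise ValueError("quartet must contain four distinct taxa")
    w, x, y, z = (d.taxon_index(t) for t in quartet)
    D = d.values
    sums = (
        D[w, x] + D[y, z],
        D[w, y] + D[x, z],
        D[w, z] + D[x, y],
    )
    if not all(np.isfinite(sums)):
        raise ValueError("quartet has an undefined pairwise distance")
    m1, m2, m3 = sorted(sums, reverse=True)
    if m1 == m3:
        return 0.0
    return (m1 - m2) / (m1 - m3)


def delta_report(d: DistanceMatrix) -> DeltaReport:
    """Full enumeration of all C(n, 4) quartets with vectorized accumulation.

    Quartets containing an undefined (non-finite) distance are skipped and
    excluded from every average.  Internally each quartet is visited once per
    pairing (three times); the triple counting cancels in all averages.
    """
    n = d.n_taxa
    if n < 4:
        raise ValueError(f"delta statistics need at least 4 taxa, got {n}")
    D = np.asarray(d.values, dtype=float)

    K, L = np.triu_indices(n, k=1)   # all pairs k < l
    P = len(K)
    delta_total = 0.0
    valid_total = 0
    idv_sum = np.zeros(n)
    idv_cnt = np.zeros(n, dtype=np.int64)

    for a in range(P):
        i, j = int(K[a]), int(L[a])
        sel = np.arange(a + 1, P)
        kb, lb = K[sel], L[sel]
        disjoint = (kb != i) & (kb != j) & (lb != i) & (lb != j)
        kb, lb = kb[disjoint], lb[disjoint]
        if len(kb) == 0:
            continue
        s1 = D[i, j] + D[kb, lb]
        s2 = D[i, kb] + D[j, lb]
        s3 = D[i, lb] + D[j, kb]
        valid = np.isfinite(s1) & np.isfinite(s2) & np.isfinite(s3)
        if not valid.all():
            kb, lb = kb[valid], lb[valid]
            s1, s2, s3 = s1[valid], s2[valid], s3[valid]
            if len(kb) == 0:
                continue
        m1 = np.maximum(np.maximum(s1, s2), s3)
        m3 = np.minimum(np.minimum(s1, s2), s3)
        m2 = s1 + s2 + s3 - m1 - m3
        spread = m1 - m3
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(spread > 0, (m1 - m2) / spread, 0.0)
        delta_total += float(delta.sum())
        valid_total += len(delta)
        block = float(delta.sum())
        idv_sum[i] += block
        idv_sum[j] += block
        np.add.at(idv_sum, kb, delta)
        np.add.at(idv_sum, lb, delta)
        idv_cnt[i] += len(delta)
        idv_cnt[j] += len(delta)
        np.add.at(idv_cnt, kb, 1)
        np.add.at(idv_cnt, lb, 1)

    # every quartet was visited exactly three times (once per pairing)
    assert valid_total % 3 == 0
    evaluated = valid_total // 3
    total_quartets = n * (n - 1) * (n - 2) * (n - 3) // 24
    mdv = delta_total / valid_total if valid_total else 0.0
    idv = {
        d.taxa[t]: (idv_sum[t] / idv_cnt[t] if idv_cnt[t] else 0.0)
        for t in range(n)
    }
    counts = {d.taxa[t]: int(idv_cnt[t] // 3) for t in range(n)}
    return DeltaReport(
        mdv=mdv,
        idv=idv,
        idv_quartet_counts=counts,
        quartets_evaluated=evaluated,
        quartets_skipped=total_quartets - evaluated,
    )


def write_delta_report(report: DeltaReport, path: str | Path) -> None:
    """Write the per-taxon values as a TSV with a trailing summary line."""
    lines = ["taxon\tidv\tquartets"]
    for taxon in sorted(report.idv, key=lambda t: report.idv[t]):
        lines.append(
            f"{taxon}\t{report.idv[taxon]:.6f}\t{report.idv_quartet_counts[taxon]}"
        )
    lines.append(
        f"#mdv\t{report.mdv:.6f}\tevaluated={report.quartets_evaluated}"
        f"\tskipped={report.quartets_skipped}"
    )
    Path(path).write_text("\n".join(lines) + "\n")
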