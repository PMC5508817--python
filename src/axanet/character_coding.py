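"""Derived quantitative characters and their state-assignment rules.

Two anatomical ratios are computed from per-taxon axis measurements:

* perforations per millimetre of stele perimeter,
  ``pmms = n_cp_max / (d_stele_max * pi)``;
* relative cortex thickness,
  ``rtc = (d_stem_max - d_stele_max) / d_stele_max``.

State thresholds for the corresponding matrix columns were originally set by
one-dimensional k-median clustering; both a restart-based solver and an
exact interval-enumeration solver are provided, the latter doubling as an
independent oracle.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AxisMeasurements",
    "DerivedScores",
    "KMediansResult",
    "pmms",
    "rtc",
    "k_medians_1d",
    "k_medians_1d_exact",
    "code_perforation_state",
    "code_rtc_state",
    "derive_scores",
    "read_measurement_table",
]


@dataclass(frozen=True)
class AxisMeasurements:
    """Raw per-taxon measurements (diameters in mm)."""

    taxon: str
    n_cp_max: int | None = None       # max complete stele perforations seen
    d_stele_max: float | None = None  # max stele diameter
    d_stem_max: float | None = None   # max stem diameter

    def __post_init__(self) -> None:
        if self.n_cp_max is not None and self.n_cp_max < 0:
            raise ValueError(f"{self.taxon}: perforation count must be >= 0")
        if self.d_stele_max is not None and self.d_stele_max <= 0:
            raise ValueError(f"{self.taxon}: stele diameter must be positive")


@dataclass(frozen=True)
class DerivedScores:
    taxon: str
    pmms: float | None
    rtc: float | None


def pmms(n_cp_max: int, d_stele_max: float) -> float:
    """Complete perforations per mm of stele perimeter."""
    if d_stele_max <= 0:
        raise ValueError(f"stele diameter must be positive, got {d_stele_max}")
    if n_cp_max < 0:
        raise ValueError(f"perforation count must be >= 0, got {n_cp_max}")
    return n_cp_max / (d_stele_max * math.pi)


def rtc(d_stem_max: float, d_stele_max: float) -> float:
    """Relative cortex thickness."""
    if d_stele_max <= 0:
        raise ValueError(f"stele diameter must be positive, got {d_stele_max}")
    if d_stem_max < d_stele_max:
        raise ValueError(
            f"stem diameter {d_stem_max} smaller than stele diameter "
            f"{d_stele_max}; stem/stele terms may be confused"
        )
    return (d_stem_max - d_stele_max) / d_stele_max


def derive_scores(m: AxisMeasurements) -> DerivedScores:
    """Compute both ratios; missing inputs yield missing scores, never zeros."""
    p = None
    if m.n_cp_max is not None and m.d_stele_max is not None:
        p = pmms(m.n_cp_max, m.d_stele_max)
    r = None
    if m.d_stem_max is not None and m.d_stele_max is not None:
        r = rtc(m.d_stem_max, m.d_stele_max)
    return DerivedScores(taxon=m.taxon, pmms=p, rtc=r)


# ---------------------------------------------------------------------------
# one-dimensional k-medians
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMediansResult:
    k: int
    medians: tuple[float, ...]          # strictly increasing
    assignments: tuple[int, ...]        # cluster id per input value, 0 = lowest
    objective: float                    # total within-cluster |x - median|
    boundaries: tuple[float, ...]       # k-1 midpoints between adjacent clusters

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.medians[1:], self.medians)):
            raise ValueError("cluster medians must be strictly increasing")


def _cluster_cost(sorted_vals: np.ndarray) -> float:
    med = float(np.median(sorted_vals))
    return float(np.abs(sorted_vals - med).sum())


def _result_from_cuts(values: np.ndarray, order: np.ndarray, cuts: list[int]) -> KMediansResult:
    """Build a result from boundary positions in the sorted value sequence."""
    sv = values[order]
    n = len(sv)
    edges = [0, *cuts, n]
    medians: list[float] = []
    objective = 0.0
    assign_sorted = np.empty(n, dtype=int)
    boundaries: list[float] = []
    for c, (lo, hi) in enumerate(zip(edges, edges[1:])):
        seg = sv[lo:hi]
        medians.append(float(np.median(seg)))
        objective += _cluster_cost(seg)
        assign_sorted[lo:hi] = c
        if hi < n:
            boundaries.append(float((sv[hi - 1] + sv[hi]) / 2.0))
    assignments = np.empty(n, dtype=int)
    assignments[order] = assign_sorted
    return KMediansResult(
        k=len(edges) - 1,
        medians=tuple(medians),
        assignments=tuple(int(a) for a in assignments),
        objective=objective,
        boundaries=tuple(boundaries),
    )


def k_medians_1d_exact(values: list[float], k: int) -> KMediansResult:
    """Optimal 1-D k-medians by dynamic programming over interval partitions.

    For one-dimensional data an optimal k-medians solution is always an
    interval partition of the sorted values, so exhaustive search over the
    k-1 boundary placements (done here with O(k n^2) DP) is exact.  Used both
    as the production solver for small inputs and as the test oracle for the
    restart-based solver.
    """
    values_arr = np.asarray(values, dtype=float)
    n = len(values_arr)
    _check_k(values_arr, k)
    order = np.argsort(values_arr, kind="stable")
    sv = values_arr[order]
    # cost[i][j] = L1 cost of one cluster over sorted slice i..j-1
    cost = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(i + 1, n + 1):
            cost[i, j] = _cluster_cost(sv[i:j])
    best = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(1, n + 1):
            for i in range(c - 1, j):
                cand = best[c - 1, i] + cost[i, j]
                if cand < best[c, j] - 1e-12:
                    best[c, j] = cand
                    back[c, j] = i
    cuts: list[int] = []
    j = n
    for c in range(k, 0, -1):
        i = int(back[c, j])
        if c > 1:
            cuts.append(i)
        j = i
    cuts.reverse()
    # guard against empty clusters from degenerate DP ties
    cuts = _repair_cuts(sv, cuts, k)
    return _result_from_cuts(values_arr, order, cuts)


def k_medians_1d(
    values: list[float], k: int, restarts: int = 1000, seed: int = 0
) -> KMediansResult:
    """Lloyd-style 1-D k-medians with random distinct-value seeding.

    Returns the best (lowest-objective) interval partition found over
    ``restarts`` seeded initializations.  Ties in point assignment are broken
    toward the lower-median cluster.
    """
    values_arr = np.asarray(values, dtype=float)
    _check_k(values_arr, k)
    if k == 1:
        order = np.argsort(values_arr, kind="stable")
        return _result_from_cuts(values_arr, order, [])
    rng = np.random.default_rng(seed)
    order = np.argsort(values_arr, kind="stable")
    sv = values_arr[order]
    distinct = np.unique(sv)
    n = len(sv)
    best_cuts: list[int] | None = None
    best_obj = np.inf
    for _ in range(max(1, restarts)):
        medians = np.sort(rng.choice(distinct, size=k, replace=False))
        for _ in range(200):
            # assign to nearest median; ties toward the lower-median cluster
            dist = np.abs(sv[:, None] - medians[None, :])
            assign = np.argmin(dist, axis=1)  # argmin takes the first (lower) tie
            new_medians = []
            for c in range(k):
                members = sv[assign == c]
                if len(members) == 0:
                    continue
                new_medians.append(float(np.median(members)))
            new = np.sort(np.array(new_medians))
            if len(new) == len(medians) and np.allclose(new, medians):
                break
            medians = new if len(new) > 0 else medians
        k_eff = len(medians)
        if k_eff < k:
            continue
        cuts = [int(np.searchsorted(sv, 0.5 * (medians[c] + medians[c + 1]), side="right"))
                for c in range(k - 1)]
        cuts = _repair_cuts(sv, cuts, k)
        obj = sum(
            _cluster_cost(sv[lo:hi])
            for lo, hi in zip([0, *cuts], [*cuts, n])
        )
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_cuts = cuts
    if best_cuts is None:  # pragma: no cover - defensive
        return k_medians_1d_exact(list(values_arr), k)
    return _result_from_cuts(values_arr, order, best_cuts)


def _check_k(values: np.ndarray, k: int) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    distinct = len(np.unique(values))
    if k > distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({distinct})"
        )


def _repair_cuts(sv: np.ndarray, cuts: list[int], k: int) -> list[int]:
    """Force cuts to be strictly increasing in (0, n) so clusters are non-empty,
    and never cut between equal values."""
    n = len(sv)
    out: list[int] = []
    prev = 0
    for c, cut in enumerate(sorted(cuts)):
        lo = prev + 1
        hi = n - (k - 1 - c)
        cut = min(max(cut, lo), hi)
        # don't split a run of identical values if avoidable
        while cut < hi and sv[cut - 1] == sv[cut]:
            cut += 1
        while cut > lo and sv[cut - 1] == sv[cut]:
            cut -= 1
        out.append(cut)
        prev = cut
    return out


# ---------------------------------------------------------------------------
# final state-assignment rules
# ---------------------------------------------------------------------------


def code_perforation_state(n_cp_max: int, pmms_value: float) -> int:
    """State for the stele-perforation character.

    0: at most 3 complete perforations ((nearly) imperforate).
    2: at least 16 complete perforations and a perimeter-normalized
       perforation density of at least 0.30 (highly perforated).
    1: everything else (moderately to densely perforated) — including
       few-perforation units with high density and many-perforation units
       with low density.
    """
    if n_cp_max < 0 or pmms_value < 0:
        raise ValueError("inputs must be nonnegative")
    if n_cp_max <= 3:
        return 0
    if n_cp_max >= 16 and pmms_value >= 0.30:
        return 2
    return 1


def code_rtc_state(rtc_value: float) -> int:
    """State for the relative-cortex-thickness character.

    0 below 1.2; 1 in the closed interval [1.2, 2.8]; 2 above 2.8.
    """
    if rtc_value < 0:
        raise ValueError("relative cortex thickness must be >= 0")
    if rtc_value < 1.2:
        return 0
    if rtc_value <= 2.8:
        return 1
    return 2


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


def read_measurement_table(path: str | Path) -> list[AxisMeasurements]:
    """Read a delimited table: taxon, n_cp_max, d_stele_max, d_stem_max.

    Tab- or comma-delimited with a header row; empty fields are missing.
    """
    path = Path(path)
    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    out: list[AxisMeasurements] = []
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    required = {"taxon", "n_cp_max", "d_stele_max", "d_stem_max"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(
            f"measurement table must have columns {sorted(required)}; "
            f"got {reader.fieldnames}"
        )
    for rec in reader:
        def _num(field: str, cast):
            raw = (rec.get(field) or "").strip()
            return cast(raw) if raw else None

        out.append(
            AxisMeasurements(
                taxon=rec["taxon"].strip(),
                n_cp_max=_num("n_cp_max", lambda s: int(float(s))),
                d_stele_max=_num("d_stele_max", float),
                d_stem_max=_num("d_stem_max", float),
            )
        )
    return out
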