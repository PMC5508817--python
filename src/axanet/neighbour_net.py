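"""Neighbour-net: circular taxon orderings and nonnegative split weights.

The agglomeration follows the published scheme: clusters are linked chains
of at most two active nodes; the cluster pair to join is chosen by the
net-divergence-adjusted selection criterion, the concrete nodes to link by
the same criterion with the chosen clusters expanded into singletons, and
any chain that grows beyond two nodes is reduced with the 2/3-1/3 distance
reduction.  Unwinding the reductions yields a circular ordering whose
interval splits form the candidate system; weights are then fitted by
nonnegative least squares.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .matrix import DistanceMatrix, ValidationError
from .splits import CircularOrdering, Split, SplitSystem

__all__ = [
    "nnet_ordering",
    "estimate_split_weights",
    "neighbour_net",
]

_DENSE_PAIR_LIMIT = 1200  # use exact dense NNLS up to this many taxon pairs


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------


def nnet_ordering(d: DistanceMatrix, seed: int | None = None) -> CircularOrdering:
    """Compute the neighbour-net circular taxon ordering.

    Ties in pair selection are broken toward the lowest index pair; passing a
    ``seed`` randomizes tie-breaking instead (robustness testing only).
    """
    n = d.n_taxa
    if not np.allclose(d.values, d.values.T):
        raise ValidationError("neighbour-net requires a symmetric matrix")
    if np.any(~np.isfinite(d.values)):
        raise ValidationError("neighbour-net requires finite distances")
    if n <= 3:
        return CircularOrdering(tuple(range(n)))
    rng = np.random.default_rng(seed) if seed is not None else None

    cap = 3 * n + 4
    D = np.zeros((cap, cap))
    D[:n, :n] = d.values
    next_node = n
    clusters: list[list[int]] = [[i] for i in range(n)]
    reductions: list[tuple[int, int, int, int, int]] = []

    def cluster_dist(A: list[int], B: list[int]) -> float:
        return float(np.mean([[D[a, b] for b in B] for a in A]))

    while len(clusters) > 1:
        N = len(clusters)
        if N == 2:
            ai, bi = 0, 1
        else:
            cd = np.zeros((N, N))
            for p in range(N):
                for q in range(p + 1, N):
                    cd[p, q] = cd[q, p] = cluster_dist(clusters[p], clusters[q])
            R = cd.sum(axis=1)
            Q = (N - 2) * cd - R[:, None] - R[None, :]
            np.fill_diagonal(Q, np.inf)
            if rng is None:
                ai, bi = divmod(int(np.argmin(Q)), N)
            else:
                mn = Q.min()
                cands = np.argwhere(Q <= mn + 1e-12)
                ai, bi = cands[rng.integers(len(cands))]
            if ai > bi:
                ai, bi = bi, ai
        A, B = clusters[ai], clusters[bi]

        x, y = _select_nodes(D, clusters, ai, bi, rng)

        # orient chains so A ends at x and B starts at y, then concatenate
        pa = list(A) if A[-1] == x else list(reversed(A))
        pb = list(B) if B[0] == y else list(reversed(B))
        path = pa + pb

        # reduce any chain of three into two replacement nodes
        while len(path) > 2:
            a, b, c = path[0], path[1], path[2]
            u, v = next_node, next_node + 1
            next_node += 2
            active = [nd for cl in clusters for nd in cl if nd not in (a, b, c)]
            active += path[3:]
            for z in set(active):
                D[u, z] = D[z, u] = 2.0 / 3.0 * D[a, z] + 1.0 / 3.0 * D[b, z]
                D[v, z] = D[z, v] = 2.0 / 3.0 * D[c, z] + 1.0 / 3.0 * D[b, z]
            D[u, v] = D[v, u] = (D[a, b] + D[a, c] + D[b, c]) / 3.0
            reductions.append((u, v, a, b, c))
            path = [u, v] + path[3:]

        new_clusters = [cl for k, cl in enumerate(clusters) if k not in (ai, bi)]
        new_clusters.append(path)
        clusters = new_clusters

    # unwind reductions to recover the full circular path of original taxa
    path = list(clusters[0])
    for u, v, a, b, c in reversed(reductions):
        iu = path.index(u)
        iv = path.index(v)
        if iv == iu + 1:
            path[iu : iv + 1] = [a, b, c]
        elif iu == iv + 1:
            path[iv : iu + 1] = [c, b, a]
        elif {iu, iv} == {0, len(path) - 1}:
            # adjacent around the circular closure; rotate so they are inline
            path = path[max(iu, iv) :] + path[: max(iu, iv)]
            iu = path.index(u)
            iv = path.index(v)
            if iv == iu + 1:
                path[iu : iv + 1] = [a, b, c]
            else:
                path[iv : iu + 1] = [c, b, a]
        else:  # pragma: no cover - should not happen
            raise RuntimeError("reduction nodes not adjacent during expansion")
    if sorted(path) != list(range(n)):  # pragma: no cover - structural guard
        raise RuntimeError("expansion did not recover all taxa")
    return CircularOrdering(tuple(path))


def _select_nodes(
    D: np.ndarray,
    clusters: list[list[int]],
    ai: int,
    bi: int,
    rng,
) -> tuple[int, int]:
    """Pick the concrete node pair to link between two chosen clusters.

    The chosen clusters' nodes are treated as singleton entities; all other
    clusters stay collapsed.
    """
    A, B = clusters[ai], clusters[bi]
    others = [cl for k, cl in enumerate(clusters) if k not in (ai, bi)]
    entities: list[list[int]] = [[nd] for nd in A + B] + others
    m = len(entities)

    def ent_dist(node: int, E: list[int]) -> float:
        return float(np.mean([D[node, e] for e in E]))

    best: tuple[float, int, int] | None = None
    cands: list[tuple[int, int]] = []
    for x in A:
        for y in B:
            if m > 2:
                rx = sum(ent_dist(x, E) for E in entities if E != [x])
                ry = sum(ent_dist(y, E) for E in entities if E != [y])
                q = (m - 2) * D[x, y] - rx - ry
            else:
                q = D[x, y]
            if best is None or q < best[0] - 1e-12:
                best = (q, x, y)
                cands = [(x, y)]
            elif abs(q - best[0]) <= 1e-12:
                cands.append((x, y))
    assert best is not None
    if rng is not None and len(cands) > 1:
        return cands[rng.integers(len(cands))]
    return best[1], best[2]


# ---------------------------------------------------------------------------
# split weight estimation
# ---------------------------------------------------------------------------


def _interval_splits(order: CircularOrdering) -> list[tuple[int, int]]:
    """Candidate splits as position intervals [p, q] with 1 <= p <= q <= n-1."""
    n = len(order)
    return [(p, q) for p in range(1, n) for q in range(p, n)]


def estimate_split_weights(
    d: DistanceMatrix,
    order: CircularOrdering,
    threshold: float = 1e-8,
) -> SplitSystem:
    """Fit nonnegative least-squares weights to the interval splits of ``order``.

    Exact active-set NNLS is used while the pair count is small; larger
    problems fall back to an accelerated projected-gradient solve that
    exploits the circular structure (O(n^2) per iteration).
    """
    n = d.n_taxa
    if len(order) != n:
        raise ValidationError("ordering does not match distance matrix")
    if n < 2:
        return SplitSystem(taxa=list(d.taxa), splits=[], circular_order=order)
    perm = list(order.order)
    Dpos = d.values[np.ix_(perm, perm)]
    iu = np.triu_indices(n, k=1)
    dvec = Dpos[iu]
    if np.any(~np.isfinite(dvec)):
        raise ValidationError("split weights need fully defined distances")
    intervals = _interval_splits(order)

    if len(dvec) <= _DENSE_PAIR_LIMIT:
        A = _dense_design(n, intervals, iu)
        w, rnorm = _scipy_nnls(A, dvec)
    else:
        w = _fista_nnls(n, dvec, iu, intervals)

    splits = []
    for (p, q), weight in zip(intervals, w):
        if weight > threshold:
            side = [perm[k] for k in range(p, q + 1)]
            splits.append(Split.of(side, n, float(weight)))
    return SplitSystem(
        taxa=list(d.taxa), splits=splits, circular_order=order, kind="circular"
    )


def _dense_design(
    n: int, intervals: list[tuple[int, int]], iu: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    rows_i, rows_j = iu
    A = np.zeros((len(rows_i), len(intervals)))
    for col, (p, q) in enumerate(intervals):
        inside_i = (rows_i >= p) & (rows_i <= q)
        inside_j = (rows_j >= p) & (rows_j <= q)
        A[:, col] = (inside_i ^ inside_j).astype(float)
    return A


def _forward(n: int, w_mat: np.ndarray) -> np.ndarray:
    """A @ w for the full interval-split system, as an n x n position matrix.

    ``w_mat[p, q]`` holds the weight of interval split [p, q] (zero
    elsewhere).  Rectangle updates via a 2D difference array give O(n^2).
    """
    diff = np.zeros((n + 1, n + 1))

    ps, qs = np.nonzero(w_mat)
    for p, q, wv in zip(ps, qs, w_mat[ps, qs]):
        # pairs (i in [p,q], j in [q+1, n-1]) and (i in [0,p-1], j in [p,q])
        diff[p, q + 1] += wv
        diff[q + 1, q + 1] -= wv
        diff[p, n] -= wv
        diff[q + 1, n] += wv
        diff[0, p] += wv
        diff[p, p] -= wv
        diff[0, q + 1] -= wv
        diff[p, q + 1] += wv
    acc = np.cumsum(np.cumsum(diff, axis=0), axis=1)[:n, :n]
    out = np.triu(acc, k=1)
    return out + out.T


def _adjoint(n: int, R: np.ndarray) -> np.ndarray:
    """A.T @ r where r is given as a symmetric n x n position matrix.

    For interval I = [p, q]:  sum_{i in I, j not in I} R[i, j]
    = sum_{i in I} rowsum(i) - (ordered within-interval sum).
    """
    rowsum = R.sum(axis=1)
    crow = np.concatenate([[0.0], np.cumsum(rowsum)])
    out = np.zeros((n, n))
    # within[p, q] accumulated over growing q
    for p in range(1, n):
        within = 0.0
        run = 0.0  # sum over i in [p, q-1] of R[i, q], built cumulatively
        for q in range(p, n):
            if q > p:
                run = R[p : q, q].sum()
                within += 2.0 * run
            out[p, q] = (crow[q + 1] - crow[p]) - within
    return out


def _fista_nnls(
    n: int,
    dvec: np.ndarray,
    iu: tuple[np.ndarray, np.ndarray],
    intervals: list[tuple[int, int]],
    iters: int = 2000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Projected-gradient NNLS using the O(n^2) structured operators."""
    Dmat = np.zeros((n, n))
    Dmat[iu] = dvec
    Dmat = Dmat + Dmat.T

    # valid weight slots: intervals [p, q], 1 <= p <= q <= n-1
    mask = np.triu(np.ones((n, n), dtype=bool))
    mask[0, :] = False

    # Lipschitz estimate by power iteration on A.T A
    rng = np.random.default_rng(0)
    v = rng.random((n, n)) * mask
    lam = 1.0
    for _ in range(30):
        atav = _adjoint(n, _forward(n, v)) * mask
        lam = np.linalg.norm(atav)
        if lam == 0:
            break
        v = atav / lam
    L = max(lam, 1e-12)

    w = np.zeros((n, n))
    z = w.copy()
    t = 1.0
    prev_obj = np.inf
    for it in range(iters):
        resid = _forward(n, z) - Dmat
        grad = _adjoint(n, resid) * mask
        w_new = np.clip(z - grad / L, 0.0, None) * mask
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = w_new + ((t - 1) / t_new) * (w_new - w)
        z = np.clip(z, 0.0, None) * mask
        w, t = w_new, t_new
        if it % 50 == 0:
            obj = float(np.sum((_forward(n, w) - Dmat) ** 2))
            if abs(prev_obj - obj) < tol * max(1.0, obj):
                break
            prev_obj = obj
    return np.array([w[p, q] for p, q in intervals])


def neighbour_net(
    d: DistanceMatrix, threshold: float = 1e-8, seed: int | None = None
) -> SplitSystem:
    """Convenience wrapper: ordering then weight estimation."""
    order = nnet_ordering(d, seed=seed)
    return estimate_split_weights(d, order, threshold=threshold)
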