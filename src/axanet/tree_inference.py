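"""Per-replicate tree builders: BioNJ distance trees and Fitch parsimony.

BioNJ is the variance-weighted refinement of neighbor joining: pair
selection uses the plain NJ criterion, but the distance update to the new
node mixes the two joined nodes with a variance-minimizing weight.
Parsimony scoring is unordered Fitch with missing cells free to take any
legal state and ambiguity sets restricted to their members; the heuristic
search is nearest-neighbour-interchange hill climbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix, DistanceMatrix, ValidationError
from .splits import Split

__all__ = [
    "PhyloTree",
    "bionj",
    "fitch_score",
    "parsimony_search",
    "tree_splits",
]


@dataclass
class PhyloTree:
    """Unrooted tree over labelled leaves.

    ``adjacency`` maps node id -> {neighbour id: branch length}; leaves carry
    labels in ``leaf_labels``.  ``taxa`` fixes the index order used when
    splits are extracted.
    """

    taxa: list[str]
    adjacency: dict[int, dict[int, float]]
    leaf_labels: dict[int, str]
    score: int | None = None                     # parsimony length, if set
    clamped_edges: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        labels = sorted(self.leaf_labels.values())
        if labels != sorted(self.taxa):
            raise ValidationError("tree leaves do not match the taxon set")
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if u not in self.adjacency.get(v, {}):
                    raise ValidationError("adjacency is not symmetric")
        for u, nbrs in self.adjacency.items():
            deg = len(nbrs)
            if u in self.leaf_labels:
                if deg != 1 and len(self.adjacency) > 1:
                    raise ValidationError(f"leaf {u} has degree {deg}")
            elif deg < 3:
                raise ValidationError(f"internal node {u} has degree {deg} < 3")

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels)

    @property
    def internal_nodes(self) -> list[int]:
        return sorted(set(self.adjacency) - set(self.leaf_labels))

    def internal_edges(self) -> list[tuple[int, int]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if u < v and u not in self.leaf_labels and v not in self.leaf_labels:
                    out.append((u, v))
        return sorted(out)

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            taxa=list(self.taxa),
            adjacency={u: dict(nbrs) for u, nbrs in self.adjacency.items()},
            leaf_labels=dict(self.leaf_labels),
            score=self.score,
            clamped_edges=list(self.clamped_edges),
        )

    def side_of(self, u: int, v: int) -> set[int]:
        """Leaf node-ids reachable from ``u`` without crossing edge (u, v)."""
        seen = {v, u}
        stack = [u]
        leaves = set()
        while stack:
            x = stack.pop()
            if x in self.leaf_labels:
                leaves.add(x)
            for y in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if u in self.leaf_labels:
            leaves.add(u)
        return leaves

    def to_newick(self) -> str:
        if len(self.adjacency) == 1:
            (only,) = self.adjacency
            return f"{_nwk_label(self.leaf_labels[only])};"
        root = self.internal_nodes[0] if self.internal_nodes else self.leaves[0]

        def rec(u: int, parent: int | None) -> str:
            children = [v for v in self.adjacency[u] if v != parent]
            if not children:
                return _nwk_label(self.leaf_labels[u])
            inner = ",".join(
                f"{rec(v, u)}:{self.adjacency[u][v]:.10g}" for v in children
            )
            label = _nwk_label(self.leaf_labels[u]) if u in self.leaf_labels else ""
            return f"({inner}){label}"

        return rec(root, None) + ";"


def _nwk_label(label: str) -> str:
    if any(c in label for c in " ():,;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# BioNJ
# ---------------------------------------------------------------------------


def bionj(d: DistanceMatrix) -> PhyloTree:
    """BioNJ tree from a distance matrix; negative lengths clamped to zero."""
    n = d.n_taxa
    if n < 2:
        raise ValidationError("need at least 2 taxa")
    if np.any(~np.isfinite(d.values)):
        raise ValidationError("BioNJ requires fully defined distances")

    if n == 2:
        adj = {0: {1: float(d.values[0, 1])}, 1: {0: float(d.values[0, 1])}}
        return PhyloTree(list(d.taxa), adj, {0: d.taxa[0], 1: d.taxa[1]})

    # active nodes carry working distance and variance matrices
    D = d.values.astype(float).copy()
    V = D.copy()
    node_ids = list(range(n))          # tree-node id per active row
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = {i: t for i, t in enumerate(d.taxa)}
    next_id = n
    clamped: list[tuple[int, int]] = []

    def add_edge(a: int, b: int, length: float) -> None:
        if length < 0:
            clamped.append((a, b))
            length = 0.0
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    while len(node_ids) > 3:
        m = len(node_ids)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), m)     # lowest index pair on ties
        if i > j:
            i, j = j, i
        dij = D[i, j]
        bi = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        bj = dij - bi
        u = next_id
        next_id += 1
        add_edge(node_ids[i], u, bi)
        add_edge(node_ids[j], u, bj)

        vij = V[i, j]
        keep = [k for k in range(m) if k not in (i, j)]
        if vij > 0:
            lam = 0.5 + float(np.sum(V[j, keep] - V[i, keep])) / (
                2.0 * (m - 2) * vij
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        newD = lam * (D[i, keep] - bi) + (1 - lam) * (D[j, keep] - bj)
        newV = lam * V[i, keep] + (1 - lam) * V[j, keep] - lam * (1 - lam) * vij

        D = D[np.ix_(keep, keep)]
        V = V[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = newD
        V[-1, :-1] = V[:-1, -1] = np.maximum(newV, 0.0)
        node_ids = [node_ids[k] for k in keep] + [u]

    # connect the final three nodes through a central vertex
    c = next_id
    (a, b, e) = node_ids
    da = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    db = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    de = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    add_edge(a, c, da)
    add_edge(b, c, db)
    add_edge(e, c, de)

    tree = PhyloTree(list(d.taxa), adjacency, leaf_labels, clamped_edges=clamped)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def fitch_score(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Minimum number of unordered state changes over all characters."""
    if sorted(tree.leaf_labels.values()) != sorted(matrix.taxa):
        raise ValidationError("tree leaves do not match matrix taxa")
    masks = matrix.state_set_array()    # taxon x character uint8 bitmasks
    label_row = {t: i for i, t in enumerate(matrix.taxa)}
    leaf_mask = {
        node: masks[label_row[lab]] for node, lab in tree.leaf_labels.items()
    }
    if len(tree.adjacency) <= 2:
        return 0

    # root on an edge incident to the smallest leaf: every internal node is
    # then strictly binary and plain Fitch is exact
    start_leaf = tree.leaves[0]
    (nbr,) = tree.adjacency[start_leaf].keys()
    total_changes = np.zeros(matrix.n_characters, dtype=np.int64)

    # iterative post-order from nbr, excluding the start leaf
    parent = {nbr: start_leaf}
    order = []
    stack = [nbr]
    while stack:
        x = stack.pop()
        order.append(x)
        for y in tree.adjacency[x]:
            if y != parent.get(x):
                parent[y] = x
                stack.append(y)
    node_mask: dict[int, np.ndarray] = {}
    for x in reversed(order):
        if x in tree.leaf_labels:
            node_mask[x] = leaf_mask[x]
            continue
        acc: np.ndarray | None = None
        for y in tree.adjacency[x]:
            if y == parent.get(x):
                continue
            child = node_mask[y]
            if acc is None:
                acc = child
            else:
                inter = acc & child
                empty = inter == 0
                total_changes += empty
                acc = np.where(empty, acc | child, inter)
        node_mask[x] = acc  # type: ignore[assignment]
    inter = node_mask[nbr] & leaf_mask[start_leaf]
    total_changes += inter == 0
    return int(total_changes.sum())


# ---------------------------------------------------------------------------
# NNI hill climbing
# ---------------------------------------------------------------------------


def _nni_neighbours(tree: PhyloTree, edge: tuple[int, int]):
    """The two alternative trees for one internal edge."""
    u, v = edge
    u_nbrs = [x for x in tree.adjacency[u] if x != v]
    v_nbrs = [x for x in tree.adjacency[v] if x != u]
    if len(u_nbrs) != 2 or len(v_nbrs) != 2:
        return
    b = u_nbrs[1]
    for c in v_nbrs:
        alt = tree.copy()
        lb = alt.adjacency[u].pop(b)
        del alt.adjacency[b][u]
        lc = alt.adjacency[v].pop(c)
        del alt.adjacency[c][v]
        alt.adjacency[u][c] = lc
        alt.adjacency[c][u] = lc
        alt.adjacency[v][b] = lb
        alt.adjacency[b][v] = lb
        yield alt


def parsimony_search(
    matrix: CharacterMatrix,
    start: PhyloTree | None = None,
    seed: int = 0,
) -> PhyloTree:
    """First-improvement NNI hill climb on the Fitch score.

    The starting tree defaults to BioNJ on the mean Hamming distances of the
    matrix.  Move order is shuffled deterministically from ``seed``; the
    returned tree carries its parsimony score.
    """
    from .subsetting_distances import mean_hamming

    if start is None:
        start = bionj(mean_hamming(matrix))
    rng = np.random.default_rng(seed)
    current = start.copy()
    current_score = fitch_score(current, matrix)
    improved = True
    while improved:
        improved = False
        edges = current.internal_edges()
        rng.shuffle(edges)
        for edge in edges:
            for alt in _nni_neighbours(current, edge):
                s = fitch_score(alt, matrix)
                if s < current_score:
                    current, current_score = alt, s
                    improved = True
                    break
            if improved:
                break
    current.score = current_score
    return current


def tree_splits(tree: PhyloTree) -> set[Split]:
    """Nontrivial bipartitions induced by the tree's internal edges."""
    index = {t: i for i, t in enumerate(tree.taxa)}
    n = len(tree.taxa)
    out: set[Split] = set()
    for u, v in tree.internal_edges():
        side = {index[tree.leaf_labels[x]] for x in tree.side_of(u, v)}
        if 1 < len(side) < n - 1:
            out.add(Split.of(side, n, 1.0))
    return out


# ---------------------------------------------------------------------------
# exhaustive enumeration (small-n oracle and perfect-phylogeny helper)
# ---------------------------------------------------------------------------


def all_topologies(taxa: list[str]):
    """Yield every unrooted binary topology (no lengths); feasible to n ~ 8."""
    n = len(taxa)
    if n < 3:
        raise ValidationError("need at least 3 taxa to enumerate topologies")

    def build(labels: list[int]):
        # recursive leaf insertion: trees over labels[0..k] extended by
        # attaching labels[k+1] to each edge
        base = PhyloTree(
            taxa=list(taxa),
            adjacency={
                0: {len(taxa): 1.0},
                1: {len(taxa): 1.0},
                2: {len(taxa): 1.0},
                len(taxa): {0: 1.0, 1: 1.0, 2: 1.0},
            },
            leaf_labels={i: taxa[i] for i in range(3)},
        )
        trees = [base]
        next_internal = len(taxa) + 1
        for leaf in range(3, n):
            new_trees = []
            for t in trees:
                edges = [
                    (u, v)
                    for u in t.adjacency
                    for v in t.adjacency[u]
                    if u < v
                ]
                for u, v in edges:
                    t2 = t.copy()
                    w = next_internal + leaf * 1000  # unique per level
                    length = t2.adjacency[u].pop(v)
                    del t2.adjacency[v][u]
                    t2.adjacency[u][w] = length / 2
                    t2.adjacency[v][w] = length / 2
                    t2.adjacency[w] = {u: length / 2, v: length / 2, leaf: 1.0}
                    t2.adjacency[leaf] = {w: 1.0}
                    t2.leaf_labels[leaf] = taxa[leaf]
                    new_trees.append(t2)
            trees = new_trees
        return trees

    yield from build(list(range(n)))
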