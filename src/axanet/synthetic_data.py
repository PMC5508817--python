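"""Simulated morphological matrices with known generating structure.

Characters evolve independently under a symmetric k-state change process on
a known tree (root state uniform; change events Poisson along branches, each
picking a different state uniformly).  A tunable fraction of characters is
replaced by pure noise (leaf states re-drawn independently) to emulate
unsorted homoplastic signal, and per-taxon missingness masks emulate
preservational data loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import CellValue, CharacterDefinition, CharacterMatrix, DistanceMatrix
from .splits import Split
from .tree_inference import PhyloTree, tree_splits

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_tree",
    "simulate_matrix",
    "fixture_suite",
    "matrix_from_array",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_taxa: int = 10
    n_characters: int = 45
    ternary_fraction: float = 0.3       # fraction of 3-state characters
    tree_shape: str = "random_coalescent_like"
    change_rate: float = 2.0            # expected changes per character on the tree
    homoplasy_boost: float = 0.0        # fraction of characters re-drawn as noise
    missing_fraction_per_taxon: float | Sequence[float] = 0.0
    min_branch_length: float = 0.0      # floor added to exponential(1) draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_characters < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.ternary_fraction <= 1.0:
            raise ValueError("ternary_fraction must lie in [0, 1]")
        if not 0.0 <= self.homoplasy_boost <= 1.0:
            raise ValueError("homoplasy_boost must lie in [0, 1]")
        if self.tree_shape not in (
            "random_coalescent_like",
            "balanced",
            "caterpillar",
        ):
            raise ValueError(f"unknown tree shape {self.tree_shape!r}")
        rates = self.missing_rates()
        if any(r < 0 or r > 0.9 for r in rates):
            raise ValueError("missing fractions must lie in [0, 0.9]")

    def missing_rates(self) -> list[float]:
        if isinstance(self.missing_fraction_per_taxon, (int, float)):
            return [float(self.missing_fraction_per_taxon)] * self.n_taxa
        rates = list(self.missing_fraction_per_taxon)
        if len(rates) != self.n_taxa:
            raise ValueError("missing fraction list length must equal n_taxa")
        return [float(r) for r in rates]


@dataclass
class SimulationTruth:
    tree: PhyloTree
    true_splits: set[Split]
    change_counts: list[int]
    missing_mask: np.ndarray            # taxa x characters bool
    noise_characters: list[int]         # 0-based columns that are pure noise


def _taxon_names(n: int) -> list[str]:
    return [f"t{i + 1:03d}" for i in range(n)]


def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """Random unrooted binary tree with exponential(1) branch lengths."""
    n = config.n_taxa
    if n < 4:
        raise ValueError("tree simulation needs at least 4 taxa")
    rng = np.random.default_rng([config.seed, 7])
    taxa = _taxon_names(n)
    adjacency: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    leaf_labels = {i: taxa[i] for i in range(n)}
    next_id = n

    def connect(a: int, b: int) -> None:
        length = config.min_branch_length + float(rng.exponential(1.0))
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    if config.tree_shape == "caterpillar":
        spine = []
        connect(0, n)  # first internal node
        spine.append(n)
        next_id = n + 1
        for leaf in range(1, n - 1):
            connect(leaf, spine[-1])
            if leaf < n - 2:
                new = next_id
                next_id += 1
                connect(spine[-1], new)
                spine.append(new)
        connect(n - 1, spine[-1])
    elif config.tree_shape == "balanced":
        nodes = list(range(n))
        while len(nodes) > 2:
            new_nodes = []
            for k in range(0, len(nodes) - 1, 2):
                parent = next_id
                next_id += 1
                connect(nodes[k], parent)
                connect(nodes[k + 1], parent)
                new_nodes.append(parent)
            if len(nodes) % 2:
                new_nodes.append(nodes[-1])
            nodes = new_nodes
        connect(nodes[0], nodes[1])
    else:  # random_coalescent_like: random sequential pair joins
        nodes = list(range(n))
        while len(nodes) > 3:
            k1, k2 = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = next_id
            next_id += 1
            connect(nodes[k1], parent)
            connect(nodes[k2], parent)
            nodes = [x for t, x in enumerate(nodes) if t not in (k1, k2)]
            nodes.append(parent)
        center = next_id
        for x in nodes:
            connect(x, center)

    tree = PhyloTree(taxa, adjacency, leaf_labels)
    tree.validate()
    return tree


def simulate_matrix(
    config: SimulationConfig, tree: PhyloTree | None = None
) -> tuple[CharacterMatrix, SimulationTruth]:
    """Evolve characters on a (possibly provided) tree and apply missingness."""
    if tree is None:
        tree = simulate_tree(config)
    rng = np.random.default_rng([config.seed, 13])
    n, m = config.n_taxa, config.n_characters
    taxa = tree.taxa

    total_len = sum(
        l for u, nbrs in tree.adjacency.items() for v, l in nbrs.items() if u < v
    )
    scale = config.change_rate / total_len if total_len > 0 else 0.0

    n_states = np.where(rng.random(m) < config.ternary_fraction, 3, 2)
    n_noise = int(round(config.homoplasy_boost * m))
    noise_cols = sorted(rng.choice(m, size=n_noise, replace=False).tolist())
    noise_set = set(noise_cols)

    # root at an arbitrary internal node and evolve down the tree
    root = tree.internal_nodes[0]
    order: list[tuple[int, int | None]] = [(root, None)]
    stack = [(root, None)]
    while stack:
        x, parent = stack.pop()
        for y in tree.adjacency[x]:
            if y != parent:
                order.append((y, x))
                stack.append((y, x))

    leaf_states = np.zeros((n, m), dtype=np.int8)
    change_counts = [0] * m
    node_state: dict[int, np.ndarray] = {}
    leaf_row = {tree.leaf_labels[nd]: i for i, nd in enumerate(sorted(tree.leaf_labels))}
    taxa_rows = {t: i for i, t in enumerate(taxa)}
    for x, parent in order:
        if parent is None:
            state = np.array(
                [rng.integers(0, k) for k in n_states], dtype=np.int8
            )
        else:
            length = tree.adjacency[parent][x] * scale
            state = node_state[parent].copy()
            n_events = rng.poisson(length, size=m)
            for j in np.nonzero(n_events)[0]:
                s = int(state[j])
                for _ in range(n_events[j]):
                    s = int((s + 1 + rng.integers(0, n_states[j] - 1)) % n_states[j])
                change_counts[j] += int(n_events[j])
                state[j] = s
        node_state[x] = state
        if x in tree.leaf_labels:
            leaf_states[taxa_rows[tree.leaf_labels[x]]] = state

    for j in noise_cols:
        leaf_states[:, j] = rng.integers(0, n_states[j], size=n)
        change_counts[j] = -1  # noise column: change count not meaningful

    rates = config.missing_rates()
    missing = np.zeros((n, m), dtype=bool)
    for i, r in enumerate(rates):
        missing[i] = rng.random(m) < r

    matrix = matrix_from_array(taxa, np.where(missing, -1, leaf_states))
    truth = SimulationTruth(
        tree=tree,
        true_splits=tree_splits(tree),
        change_counts=change_counts,
        missing_mask=missing,
        noise_characters=noise_cols,
    )
    return matrix, truth


def matrix_from_array(taxa: Sequence[str], states: np.ndarray) -> CharacterMatrix:
    """Build a CharacterMatrix from an int array; -1 encodes missing."""
    states = np.asarray(states)
    n, m = states.shape
    chars = []
    for j in range(m):
        observed = states[:, j][states[:, j] >= 0]
        max_obs = int(observed.max()) if len(observed) else 1
        chars.append(CharacterDefinition(index=j + 1, max_state=min(2, max(1, max_obs))))
    cells = [
        [
            CellValue.missing() if states[i, j] < 0 else CellValue.defined(int(states[i, j]))
            for j in range(m)
        ]
        for i in range(n)
    ]
    return CharacterMatrix(list(taxa), chars, cells)


# ---------------------------------------------------------------------------
# deterministic named fixtures
# ---------------------------------------------------------------------------


def fixture_suite(seed: int = 0) -> dict[str, tuple[CharacterMatrix, SimulationTruth | None]]:
    """Small deterministic fixtures reused across the test surface.

    * ``perfect8`` — 8 taxa, 30 binary characters all compatible with one tree.
    * ``conflict6`` — two 15-character blocks supporting incompatible splits.
    * ``sparse`` — one taxon just above the 60% missing threshold.
    * ``clean20`` — 8 taxa, 20 characters evolved without noise.
    """
    out: dict[str, tuple[CharacterMatrix, SimulationTruth | None]] = {}

    # perfect8: characters are indicators of the 5 internal splits of a fixed
    # caterpillar tree plus informative two-leaf groupings along it
    cfg8 = SimulationConfig(n_taxa=8, tree_shape="caterpillar", seed=seed)
    tree8 = simulate_tree(cfg8)
    splits8 = sorted(tree_splits(tree8), key=lambda s: sorted(s.side_a))
    cols = []
    while len(cols) < 30:
        s = splits8[len(cols) % len(splits8)]
        col = np.zeros(8, dtype=np.int8)
        col[sorted(s.side_a)] = 1
        cols.append(col)
    states8 = np.stack(cols, axis=1)
    m8 = matrix_from_array(tree8.taxa, states8)
    truth8 = SimulationTruth(
        tree=tree8,
        true_splits=set(splits8),
        change_counts=[1] * 30,
        missing_mask=np.zeros((8, 30), dtype=bool),
        noise_characters=[],
    )
    out["perfect8"] = (m8, truth8)

    # conflict6: block A supports {0,1,2} vs {3,4,5}; block B supports
    # {0,1,3} vs {2,4,5} -- the two splits are incompatible
    taxa6 = _taxon_names(6)
    a = np.zeros(6, dtype=np.int8)
    a[[0, 1, 2]] = 1
    b = np.zeros(6, dtype=np.int8)
    b[[0, 1, 3]] = 1
    states6 = np.stack([a] * 15 + [b] * 15, axis=1)
    out["conflict6"] = (matrix_from_array(taxa6, states6), None)

    # sparse: taxon 1 misses 28/45 cells (62%) -- above the 60% rule
    cfg_sp = SimulationConfig(
        n_taxa=6,
        n_characters=45,
        change_rate=4.0,
        missing_fraction_per_taxon=[0.0] * 6,
        seed=seed + 1,
    )
    m_sp, truth_sp = simulate_matrix(cfg_sp)
    cells = [list(row) for row in m_sp.cells]
    for j in range(28):
        cells[1][j] = CellValue.missing()
    out["sparse"] = (
        CharacterMatrix(m_sp.taxa, m_sp.characters, cells),
        truth_sp,
    )

    # clean20: moderate-rate no-noise simulation for recovery checks
    cfg_cl = SimulationConfig(
        n_taxa=8, n_characters=20, change_rate=3.0, seed=seed + 2
    )
    out["clean20"] = simulate_matrix(cfg_cl)
    return out


def circular_metric_fixture(seed: int = 0) -> tuple[DistanceMatrix, list[Split]]:
    """A 6-taxon circular-decomposable metric built from known interval splits."""
    rng = np.random.default_rng([seed, 99])
    n = 6
    taxa = _taxon_names(n)
    order = list(range(n))
    splits: list[Split] = []
    for i in range(n):  # trivial splits
        splits.append(Split.of({i}, n, float(rng.uniform(0.05, 0.2))))
    # a few nontrivial intervals of the identity ordering
    for p, q in [(1, 2), (2, 4), (4, 5), (1, 3)]:
        side = set(order[p : q + 1])
        splits.append(Split.of(side, n, float(rng.uniform(0.05, 0.2))))
    d = np.zeros((n, n))
    for s in splits:
        for i in range(n):
            for j in range(n):
                if s.separates(i, j):
                    d[i, j] += s.weight
    scale = d.max()
    d = d / (scale * 1.25)  # keep inside [0, 1]
    splits = [s.with_weight(s.weight / (scale * 1.25)) for s in splits]
    return DistanceMatrix(taxa, d), splits
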