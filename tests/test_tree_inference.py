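import itertools

import numpy as np
import pytest

from axanet.matrix import CellValue, CharacterDefinition, CharacterMatrix, DistanceMatrix, ValidationError
from axanet.subsetting_distances import mean_hamming
from axanet.synthetic_data import SimulationConfig, matrix_from_array, simulate_tree
from axanet.tree_inference import (
    all_topologies,
    bionj,
    fitch_score,
    parsimony_search,
    tree_splits,
)

from test_treelikeness import tree_path_distance


def brute_force_fitch(tree, matrix):
    """Independent oracle: minimize changes over all internal state choices."""
    internals = tree.internal_nodes
    leaves = tree.leaves
    edges = [
        (u, v) for u in tree.adjacency for v in tree.adjacency[u] if u < v
    ]
    total = 0
    for j, char in enumerate(matrix.characters):
        states = list(range(char.max_state + 1))
        leaf_allowed = {}
        for nd in leaves:
            cell = matrix.cell(tree.leaf_labels[nd], j)
            leaf_allowed[nd] = list(cell.states) if cell.states else states
        best = None
        for internal_assign in itertools.product(states, repeat=len(internals)):
            assign = dict(zip(internals, internal_assign))
            for leaf_assign in itertools.product(
                *(leaf_allowed[nd] for nd in leaves)
            ):
                full = dict(assign)
                full.update(dict(zip(leaves, leaf_assign)))
                changes = sum(1 for u, v in edges if full[u] != full[v])
                if best is None or changes < best:
                    best = changes
        total += best
    return total


class TestBionj:
    def test_additive_metric_exact(self):
        tree = simulate_tree(SimulationConfig(n_taxa=5, seed=1))
        d = tree_path_distance(tree)
        est = bionj(d)
        assert tree_splits(est) == tree_splits(tree)
        d2 = tree_path_distance(est)
        assert np.abs(d2.values - d.values).max() < 1e-10

    def test_three_taxa_star(self):
        vals = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        d = DistanceMatrix(list("abc"), vals)
        tree = bionj(d)
        assert len(tree.internal_nodes) == 1
        center = tree.internal_nodes[0]
        # three-point formulas
        assert tree.adjacency[0][center] == pytest.approx(0.5 * (0.4 + 0.6 - 0.8))
        assert tree.adjacency[1][center] == pytest.approx(0.5 * (0.4 + 0.8 - 0.6))
        assert tree.adjacency[2][center] == pytest.approx(0.5 * (0.6 + 0.8 - 0.4))

    @pytest.mark.parametrize("seed", range(5))
    def test_noise_robust_topology(self, seed):
        tree = simulate_tree(SimulationConfig(n_taxa=8, seed=seed + 30))
        d = tree_path_distance(tree)
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, 0.01, size=d.values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        vals = np.clip(d.values + noise, 0, 1)
        noisy = DistanceMatrix(d.taxa, vals)
        assert tree_splits(bionj(noisy)) == tree_splits(tree)

    def test_negative_lengths_clamped(self):
        # strongly non-additive matrix can force negative estimates
        vals = np.array(
            [
                [0, 0.9, 0.05, 0.9],
                [0.9, 0, 0.9, 0.05],
                [0.05, 0.9, 0, 0.9],
                [0.9, 0.05, 0.9, 0],
            ]
        )
        tree = bionj(DistanceMatrix(list("abcd"), vals))
        for u, nbrs in tree.adjacency.items():
            for v, l in nbrs.items():
                assert l >= 0

    def test_undefined_distance_rejected(self):
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = np.nan
        d = DistanceMatrix(list("abcd"), vals)
        with pytest.raises(ValidationError):
            bionj(d)

    def test_reduces_to_nj_with_equal_variances(self):
        """With V constant, the BioNJ mixing weight is 1/2 (plain NJ update)."""
        tree = simulate_tree(SimulationConfig(n_taxa=7, seed=77))
        d = tree_path_distance(tree)
        est = bionj(d)
        # plain NJ on additive data recovers the generating topology too
        assert tree_splits(est) == tree_splits(tree)


class TestFitch:
    def test_single_congruent_character(self, fixtures):
        m, truth = fixtures["perfect8"]
        one = m.restrict(columns=[0])
        assert fitch_score(truth.tree, one) == 1

    def test_all_missing_character(self, fixtures):
        m, truth = fixtures["perfect8"]
        chars = [CharacterDefinition(index=1)]
        cells = [[CellValue.missing()] for _ in m.taxa]
        blank = CharacterMatrix(m.taxa, chars, cells)
        assert fitch_score(truth.tree, blank) == 0

    def test_perfect_matrix_score(self, fixtures):
        m, truth = fixtures["perfect8"]
        # every binary split-indicator character costs exactly one change
        assert fitch_score(truth.tree, m) == m.n_characters

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(SimulationConfig(n_taxa=6, seed=seed))
        states = rng.integers(0, 3, size=(6, 5)).astype(np.int8)
        states[rng.random(states.shape) < 0.2] = -1
        m = matrix_from_array(tree.taxa, states)
        assert fitch_score(tree, m) == brute_force_fitch(tree, m)

    def test_ambiguity_constrains_states(self):
        tree = simulate_tree(SimulationConfig(n_taxa=4, tree_shape="balanced", seed=0))
        chars = [CharacterDefinition(index=1, max_state=2)]
        # cherry (t1,t2) vs (t3,t4); ambiguity {1,2} on t1 lets it match t2's 1
        cells = [
            [CellValue.ambiguous({1, 2})],
            [CellValue.defined(1)],
            [CellValue.defined(0)],
            [CellValue.defined(0)],
        ]
        m = CharacterMatrix(tree.taxa, chars, cells)
        assert fitch_score(tree, m) == 1

    def test_leaf_permutation_invariance(self):
        rng = np.random.default_rng(9)
        tree = simulate_tree(SimulationConfig(n_taxa=7, seed=9))
        states = rng.integers(0, 2, size=(7, 8)).astype(np.int8)
        m = matrix_from_array(tree.taxa, states)
        base = fitch_score(tree, m)
        perm = rng.permutation(7)
        m2 = m.restrict(taxa=[m.taxa[i] for i in perm])
        assert fitch_score(tree, m2) == base

    def test_taxon_mismatch_rejected(self, fixtures):
        m, truth = fixtures["perfect8"]
        with pytest.raises(ValidationError):
            fitch_score(truth.tree, m.restrict(taxa=m.taxa[:7]))


class TestParsimonySearch:
    def test_perfect_phylogeny_recovered(self, fixtures):
        m, truth = fixtures["perfect8"]
        result = parsimony_search(m, seed=0)
        assert tree_splits(result) == truth.true_splits
        assert result.score == m.n_characters

    def test_never_worse_than_start(self):
        rng = np.random.default_rng(4)
        tree = simulate_tree(SimulationConfig(n_taxa=6, seed=4))
        states = rng.integers(0, 2, size=(6, 12)).astype(np.int8)
        m = matrix_from_array(tree.taxa, states)
        start = bionj(mean_hamming(m))
        result = parsimony_search(m, start=start, seed=1)
        assert result.score <= fitch_score(start, m)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        tree = simulate_tree(SimulationConfig(n_taxa=7, seed=6))
        states = rng.integers(0, 2, size=(7, 10)).astype(np.int8)
        m = matrix_from_array(tree.taxa, states)
        r1 = parsimony_search(m, seed=42)
        r2 = parsimony_search(m, seed=42)
        assert tree_splits(r1) == tree_splits(r2)
        assert r1.score == r2.score

    @pytest.mark.slow
    def test_finds_global_optimum_usually(self):
        """NNI from BioNJ reaches the exhaustive optimum in most seeded runs."""
        rng = np.random.default_rng(0)
        hits = 0
        runs = 20
        tree = simulate_tree(SimulationConfig(n_taxa=7, seed=3))
        states = rng.integers(0, 2, size=(7, 15)).astype(np.int8)
        m = matrix_from_array(tree.taxa, states)
        best = min(fitch_score(t, m) for t in all_topologies(m.taxa))
        for seed in range(runs):
            result = parsimony_search(m, seed=seed)
            if result.score == best:
                hits += 1
        assert hits / runs >= 0.95


class TestTreeSplits:
    def test_four_taxon_tree_one_split(self):
        tree = simulate_tree(SimulationConfig(n_taxa=4, tree_shape="balanced", seed=0))
        assert len(tree_splits(tree)) == 1

    def test_binary_tree_split_count(self):
        tree = simulate_tree(SimulationConfig(n_taxa=8, seed=12))
        assert len(tree_splits(tree)) == 5  # n - 3

    def test_canonical_orientation(self):
        tree = simulate_tree(SimulationConfig(n_taxa=6, seed=2))
        for s in tree_splits(tree):
            assert 0 in s.side_a


class TestAllTopologies:
    def test_counts(self):
        assert len(list(all_topologies(list("abcde")))) == 15
        assert len(list(all_topologies([f"t{i}" for i in range(7)]))) == 945
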