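import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axanet.matrix import CellValue, CharacterDefinition, CharacterMatrix, ValidationError
from axanet.subsetting_distances import (
    ComputationError,
    SubsetDefinition,
    build_subset,
    distance_summary,
    exclude_sparse_taxa,
    load_subset_definitions,
    mean_hamming,
    missing_fraction,
    packaged_subset_definitions,
    variable_characters,
)

from conftest import random_matrix


def brute_force_mean_hamming(matrix):
    """Independent oracle: naive per-pair double loop over cells."""
    n = matrix.n_taxa
    out = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = 0
            mismatches = 0
            for a, b in zip(matrix.cells[i], matrix.cells[j]):
                if a.is_defined and b.is_defined:
                    comparable += 1
                    if a.state != b.state:
                        mismatches += 1
            counts[i, j] = comparable
            out[i, j] = mismatches / comparable if comparable else np.nan
    return out, counts


class TestMissingFraction:
    def test_fully_defined(self, toy_matrix):
        assert missing_fraction(toy_matrix, "tax1") == pytest.approx(0.25)
        full = toy_matrix.restrict(columns=[0, 1, 3])
        assert missing_fraction(full, "tax2") == 0.0

    def test_ambiguous_not_missing(self, toy_matrix):
        # tax2 has one ambiguous cell but no missing cell
        assert missing_fraction(toy_matrix, "tax2") == 0.0

    def test_boundary_retained(self):
        # 27 of 45 missing = exactly 0.6 -> retained under strict >
        chars = [CharacterDefinition(index=i + 1) for i in range(45)]
        row1 = [CellValue.missing()] * 27 + [CellValue.defined(0)] * 18
        row2 = [CellValue.defined(1)] * 45
        m = CharacterMatrix(["edge", "full"], chars, [row1, row2])
        assert missing_fraction(m, "edge") == pytest.approx(0.6)
        result = exclude_sparse_taxa(m, threshold=0.6)
        assert result.dropped_taxa == []

    def test_unknown_taxon(self, toy_matrix):
        with pytest.raises(KeyError):
            missing_fraction(toy_matrix, "nope")


class TestExcludeSparseTaxa:
    def test_threshold_one_keeps_all(self, fixtures):
        m, _ = fixtures["sparse"]
        assert exclude_sparse_taxa(m, threshold=1.0).dropped_taxa == []

    def test_sparse_taxon_dropped(self, fixtures):
        m, _ = fixtures["sparse"]
        result = exclude_sparse_taxa(m, threshold=0.6)
        assert result.dropped_taxa == [m.taxa[1]]
        assert result.matrix.n_taxa == m.n_taxa - 1

    def test_all_dropped_is_error(self):
        chars = [CharacterDefinition(index=1), CharacterDefinition(index=2)]
        rows = [[CellValue.missing(), CellValue.missing()]] * 2
        m = CharacterMatrix(["a", "b"], chars, rows)
        with pytest.raises(ComputationError):
            exclude_sparse_taxa(m, threshold=0.6)


class TestVariableCharacters:
    def test_constant_column_excluded(self):
        chars = [CharacterDefinition(index=1), CharacterDefinition(index=2)]
        rows = [
            [CellValue.defined(0), CellValue.defined(0)],
            [CellValue.defined(0), CellValue.defined(1)],
        ]
        m = CharacterMatrix(["a", "b"], chars, rows)
        assert variable_characters(m) == [1]

    def test_missing_does_not_block_variability(self):
        chars = [CharacterDefinition(index=1)]
        rows = [[CellValue.defined(0)], [CellValue.missing()], [CellValue.defined(1)]]
        m = CharacterMatrix(["a", "b", "c"], chars, rows)
        assert variable_characters(m) == [0]

    def test_ambiguous_does_not_establish_variability(self):
        chars = [CharacterDefinition(index=1)]
        rows = [[CellValue.defined(0)], [CellValue.ambiguous({0, 1})]]
        m = CharacterMatrix(["a", "b"], chars, rows)
        assert variable_characters(m) == []


class TestBuildSubset:
    def test_all_taxa_removes_only_invariants(self):
        chars = [CharacterDefinition(index=i + 1) for i in range(3)]
        rows = [
            [CellValue.defined(0), CellValue.defined(1), CellValue.defined(0)],
            [CellValue.defined(0), CellValue.defined(0), CellValue.defined(1)],
            [CellValue.defined(0), CellValue.defined(1), CellValue.defined(1)],
            [CellValue.defined(0), CellValue.defined(0), CellValue.defined(0)],
        ]
        m = CharacterMatrix(["a", "b", "c", "d"], chars, rows)
        sub = build_subset(m)
        assert sub.dropped_taxa == []
        assert sub.dropped_characters == [1]
        assert sub.matrix.n_characters == 2

    def test_subset_definition_prefixes(self, fixtures):
        m, _ = fixtures["perfect8"]
        defn = SubsetDefinition(name="first", prefixes=["t00"])
        sub = build_subset(m, defn)
        assert all(t.startswith("t00") for t in sub.matrix.taxa)

    def test_too_few_taxa(self, fixtures):
        m, _ = fixtures["perfect8"]
        defn = SubsetDefinition(name="one", taxa=[m.taxa[0]])
        with pytest.raises(ComputationError):
            build_subset(m, defn)

    def test_small_subset_warns(self, fixtures):
        m, _ = fixtures["perfect8"]
        defn = SubsetDefinition(name="three", taxa=m.taxa[:3])
        with pytest.warns(UserWarning, match="quartet"):
            build_subset(m, defn)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 8, 20)
        sub1 = build_subset(m)
        sub2 = build_subset(sub1.matrix)
        assert sub2.matrix.taxa == sub1.matrix.taxa
        assert sub2.matrix.cells == sub1.matrix.cells
        assert sub2.dropped_taxa == []
        assert sub2.dropped_characters == []


class TestMeanHamming:
    def test_identical_rows_zero(self):
        chars = [CharacterDefinition(index=i + 1) for i in range(4)]
        row = [CellValue.defined(s) for s in (0, 1, 2, 0)]
        m = CharacterMatrix(["a", "b"], chars, [list(row), list(row)])
        d = mean_hamming(m)
        assert d.get("a", "b") == 0.0
        assert d.comparable("a", "b") == 4

    def test_worked_fraction(self):
        # 6 mismatches over 14 comparable characters -> 0.4286 (prints as 0.42)
        chars = [CharacterDefinition(index=i + 1) for i in range(16)]
        row_a = [CellValue.defined(0)] * 14 + [CellValue.missing()] * 2
        row_b = (
            [CellValue.defined(1)] * 6
            + [CellValue.defined(0)] * 8
            + [CellValue.defined(0)] * 2
        )
        m = CharacterMatrix(["A", "B"], chars, [row_a, row_b])
        d = mean_hamming(m)
        assert d.comparable("A", "B") == 14
        assert d.get("A", "B") == pytest.approx(6 / 14)

    def test_ambiguous_cells_incomparable(self):
        chars = [CharacterDefinition(index=1), CharacterDefinition(index=2)]
        rows = [
            [CellValue.ambiguous({0, 1}), CellValue.defined(1)],
            [CellValue.defined(0), CellValue.defined(0)],
        ]
        m = CharacterMatrix(["a", "b"], chars, rows)
        d = mean_hamming(m)
        assert d.comparable("a", "b") == 1
        assert d.get("a", "b") == 1.0

    def test_no_comparable_pair_errors(self):
        chars = [CharacterDefinition(index=1), CharacterDefinition(index=2)]
        rows = [
            [CellValue.defined(0), CellValue.missing()],
            [CellValue.missing(), CellValue.defined(1)],
        ]
        m = CharacterMatrix(["a", "b"], chars, rows)
        with pytest.raises(ComputationError, match="'a' and 'b'"):
            mean_hamming(m)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 6, 10, missing_p=0.25, ambiguous_p=0.1)
        try:
            d = mean_hamming(m)
        except ComputationError:
            return  # degenerate draw; oracle would fail identically
        expected, counts = brute_force_mean_hamming(m)
        assert np.allclose(d.values, expected)
        assert np.array_equal(
            d.comparable_counts[~np.eye(6, dtype=bool)],
            counts[~np.eye(6, dtype=bool)],
        )

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, int(rng.integers(3, 10)), 12, missing_p=0.1)
        d = mean_hamming(m)
        assert np.all(d.values >= 0) and np.all(d.values <= 1)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)

    def test_invariant_removal_changes_denominator_only(self):
        rng = np.random.default_rng(17)
        m = random_matrix(rng, 7, 15, missing_p=0.1, ambiguous_p=0.0)
        sub = build_subset(m)
        d_sub = mean_hamming(sub.matrix)
        # mismatch counts agree with the full matrix (invariants never mismatch)
        d_full = mean_hamming(m)
        mm_full = d_full.values * d_full.comparable_counts
        mm_sub = d_sub.values * d_sub.comparable_counts
        assert np.allclose(mm_full, mm_sub)


class TestDistanceSummary:
    def test_all_zero(self):
        chars = [CharacterDefinition(index=1)]
        rows = [[CellValue.defined(0)]] * 3
        m = CharacterMatrix(["a", "b", "c"], chars, rows)
        s = distance_summary(mean_hamming(m))
        assert s.max_distance == 0.0
        assert s.n_zero_pairs == 3

    def test_max_pair_identified(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 6, 12, missing_p=0.0, ambiguous_p=0.0)
        d = mean_hamming(m)
        s = distance_summary(d)
        assert s.max_distance == pytest.approx(
            d.values[np.triu_indices(6, k=1)].max()
        )
        assert d.get(*s.max_pair) == pytest.approx(s.max_distance)


class TestSubsetConfig:
    def test_packaged_definitions_load(self):
        defs = packaged_subset_definitions()
        for name in (
            "millerocaulis",
            "thamnopteroideae",
            "osmundeae",
            "osmundoideae",
            "guaireaceae",
            "osmundacaulis",
            "osmundinae",
            "osmundaceae",
        ):
            assert name in defs
        assert "Millerocaulis stipabonettiorum" in defs["millerocaulis"].exclude

    def test_custom_file_and_resolution(self, tmp_path, fixtures):
        m, _ = fixtures["perfect8"]
        p = tmp_path / "subs.yml"
        p.write_text("front:\n  taxa: [t001, t002, t003, t004]\n")
        defs = load_subset_definitions(p)
        assert defs["front"].resolve(m) == ["t001", "t002", "t003", "t004"]

    def test_unresolvable_subset(self, fixtures):
        m, _ = fixtures["perfect8"]
        with pytest.raises(ValidationError):
            SubsetDefinition(name="ghost", taxa=["nope"]).resolve(m)
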