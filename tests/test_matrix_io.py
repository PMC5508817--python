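import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axanet.matrix import DistanceMatrix, ValidationError
from axanet.matrix_io import (
    ParseError,
    read_distance_matrix,
    read_nexus_matrix,
    read_splits_nexus,
    write_distance_matrix,
    write_nexus_matrix,
    write_splits_nexus,
)
from axanet.splits import CircularOrdering, Split, SplitSystem

from conftest import random_matrix


NEXUS_BASIC = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=3 NCHAR=4;
    FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="012";
    MATRIX
    tax1 01?2
    tax2 0(01)12
    tax3 11-?
    ;
END;
"""


class TestReadNexusMatrix:
    def test_basic_cells(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC)
        m = read_nexus_matrix(p)
        assert m.taxa == ["tax1", "tax2", "tax3"]
        row = m.row("tax1")
        assert [c.kind for c in row] == ["defined", "defined", "missing", "defined"]
        assert [sorted(c.states) for c in row] == [[0], [1], [], [2]]

    def test_multistate_cell(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC)
        m = read_nexus_matrix(p)
        cell = m.cell("tax2", 1)
        assert cell.kind == "ambiguous"
        assert cell.states == frozenset({0, 1})

    def test_gap_maps_to_missing(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC)
        m = read_nexus_matrix(p)
        assert m.cell("tax3", 2).is_missing
        assert m.cell("tax3", 3).is_missing

    def test_taxon_order_preserved(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC.replace("tax1", "zzz1"))
        m = read_nexus_matrix(p)
        assert m.taxa[0] == "zzz1"

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC.replace("tax2", "tax1"))
        with pytest.raises(ValidationError, match="duplicate"):
            read_nexus_matrix(p)

    def test_undeclared_symbol_names_taxon(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC.replace("11-?", "13-?"))
        with pytest.raises(ValidationError, match="tax3"):
            read_nexus_matrix(p)

    def test_malformed_block_names_line(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text("#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=2;\n")
        with pytest.raises(ParseError, match="line"):
            read_nexus_matrix(p)

    def test_missing_matrix_command(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text("#NEXUS\nBEGIN DATA;\nDIMENSIONS NCHAR=2;\nEND;\n")
        with pytest.raises(ParseError, match="MATRIX"):
            read_nexus_matrix(p)

    def test_strict_requires_header(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC.replace("#NEXUS\n", ""))
        with pytest.raises(ParseError):
            read_nexus_matrix(p, dialect="strict")
        # tolerant accepts it
        assert read_nexus_matrix(p, dialect="tolerant").n_taxa == 3

    def test_interleaved_rows(self, tmp_path):
        text = """#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=2 NCHAR=4;
    FORMAT MISSING=? GAP=- INTERLEAVE;
    MATRIX
    a 01
    b 10
    a 11
    b 0?
    ;
END;
"""
        p = tmp_path / "m.nex"
        p.write_text(text)
        m = read_nexus_matrix(p)
        assert [c.states for c in m.row("a")] == [
            frozenset({0}), frozenset({1}), frozenset({1}), frozenset({1})
        ]

    def test_underscore_label_normalized(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC.replace("tax1", "Genus_species"))
        m = read_nexus_matrix(p)
        assert "Genus species" in m.taxa

    def test_comments_stripped(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS_BASIC.replace("01?2", "01?2 [a note]"))
        m = read_nexus_matrix(p)
        assert m.n_characters == 4


class TestWriteNexusMatrix:
    def test_empty_taxa_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            from axanet.matrix import CharacterMatrix

            CharacterMatrix([], [], [])

    def test_round_trip_toy(self, toy_matrix, tmp_path):
        p = tmp_path / "rt.nex"
        write_nexus_matrix(toy_matrix, p)
        back = read_nexus_matrix(p)
        assert back.taxa == toy_matrix.taxa
        assert back.cells == toy_matrix.cells

    def test_ambiguous_notation_emitted(self, toy_matrix, tmp_path):
        p = tmp_path / "rt.nex"
        write_nexus_matrix(toy_matrix, p)
        assert "(01)" in p.read_text()

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_randomized(self, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, int(rng.integers(2, 8)), int(rng.integers(2, 12)))
        p = tmp_path_factory.mktemp("nex") / "rt.nex"
        write_nexus_matrix(m, p)
        back = read_nexus_matrix(p)
        assert back.taxa == m.taxa
        assert back.cells == m.cells


class TestDistanceIO:
    def test_two_taxon_phylip(self, tmp_path):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.5], [0.5, 0.0]]))
        p = tmp_path / "d.phy"
        write_distance_matrix(d, p, format="phylip_square")
        text = p.read_text()
        assert text.splitlines()[0].strip() == "2"
        back = read_distance_matrix(p, format="phylip_square")
        assert back.get("a", "b") == 0.5

    def test_zero_matrix(self, tmp_path):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        p = tmp_path / "d.phy"
        write_distance_matrix(d, p)
        back = read_distance_matrix(p)
        assert np.all(back.values == 0)

    @pytest.mark.parametrize("fmt", ["phylip_square", "nexus_distances"])
    def test_round_trip_random(self, fmt, tmp_path):
        rng = np.random.default_rng(42)
        a = rng.random((5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        a /= a.max()
        d = DistanceMatrix([f"t{i}" for i in range(5)], a)
        p = tmp_path / "d.txt"
        write_distance_matrix(d, p, format=fmt)
        back = read_distance_matrix(p, format=fmt)
        assert back.taxa == d.taxa
        assert np.abs(back.values - d.values).max() < 1e-6

    def test_unknown_format(self, tmp_path):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 0.1], [0.1, 0.0]]))
        with pytest.raises(ValueError, match="unknown"):
            write_distance_matrix(d, tmp_path / "x", format="tsv")


class TestSplitsIO:
    def test_trivial_splits_only(self, tmp_path):
        taxa = ["a", "b", "c", "d"]
        splits = [Split.of({i}, 4, 0.5) for i in range(4)]
        sys = SplitSystem(taxa=taxa, splits=splits,
                          circular_order=CircularOrdering((0, 1, 2, 3)))
        p = tmp_path / "s.nex"
        write_splits_nexus(sys, p)
        back = read_splits_nexus(p)
        assert len(back.splits) == 4
        assert all(s.is_trivial for s in back.splits)

    def test_tree_case_five_splits(self, tmp_path):
        # additive 4-taxon metric -> 4 trivial + 1 internal
        from axanet.neighbour_net import neighbour_net

        vals = np.array(
            [
                [0, 2, 4, 4],
                [2, 0, 4, 4],
                [4, 4, 0, 2],
                [4, 4, 2, 0],
            ],
            dtype=float,
        ) / 4.0
        d = DistanceMatrix(["a", "b", "c", "d"], vals)
        sys = neighbour_net(d)
        assert len(sys.splits) == 5
        p = tmp_path / "s.nex"
        write_splits_nexus(sys, p)
        back = read_splits_nexus(p)
        assert {s.key() for s in back.splits} == {s.key() for s in sys.splits}
        weights = {s.key(): s.weight for s in back.splits}
        for s in sys.splits:
            assert abs(weights[s.key()] - s.weight) < 1e-6

    def test_frequency_weights_in_unit_interval(self, tmp_path):
        taxa = ["a", "b", "c", "d", "e"]
        splits = [Split.of({0, 1}, 5, 0.8), Split.of({2, 3}, 5, 0.35)]
        sys = SplitSystem(taxa=taxa, splits=splits, kind="frequency")
        p = tmp_path / "s.nex"
        write_splits_nexus(sys, p)
        back = read_splits_nexus(p)
        assert all(0 <= s.weight <= 1 for s in back.splits)

    def test_unknown_taxon_index_rejected(self, tmp_path):
        taxa = ["a", "b", "c"]
        with pytest.raises(ValidationError):
            SplitSystem(taxa=taxa, splits=[Split.of({0, 3}, 5, 1.0)])


class TestNewick:
    def test_round_trip(self, tmp_path):
        from axanet.matrix_io import read_newick_tree, write_newick_tree
        from axanet.synthetic_data import SimulationConfig, simulate_tree
        from axanet.tree_inference import tree_splits

        tree = simulate_tree(SimulationConfig(n_taxa=7, seed=11))
        p = tmp_path / "t.nwk"
        write_newick_tree(tree, p)
        back = read_newick_tree(p, taxa=tree.taxa)
        assert tree_splits(back) == tree_splits(tree)
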