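"""Alignment, partition, tree, character and grouping parsing/writing."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloscreen.errors import (
    AlphabetError,
    DisjointnessError,
    DuplicateTaxonError,
    FrameError,
    LengthMismatchError,
    PartitionBoundsError,
    PartitionOverlapError,
    UnknownTaxonError,
)
from phyloscreen import seqio
from phyloscreen.seqio import (
    Alphabet,
    PartitionEntry,
    PartitionScheme,
    extract_codon_positions,
    read_alignment,
    read_grouping,
    read_partitions,
    write_alignment,
)

from conftest import aln_from_strings


class TestReadAlignment:
    def test_minimal_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACDE\n>s2\nACDF\n")
        aln = read_alignment(p, "fasta", Alphabet.AA)
        assert aln.n_taxa == 2 and aln.n_sites == 4
        assert aln.sequence("s2") == "ACDF"

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACDE\n>s2\nACDEF\n")
        with pytest.raises(LengthMismatchError):
            read_alignment(p, "fasta", Alphabet.AA)

    def test_duplicate_labels_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACDE\n>s1\nACDF\n")
        with pytest.raises(DuplicateTaxonError):
            read_alignment(p, "fasta", Alphabet.AA)

    def test_illegal_symbol_strict_vs_lenient(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nAC1E\n>s2\nACDF\n")
        with pytest.raises(AlphabetError):
            read_alignment(p, "fasta", Alphabet.AA, strict=True)
        aln = read_alignment(p, "fasta", Alphabet.AA, strict=False)
        assert aln.sequence("s1") == "AC?E"

    def test_phylip_parses_and_roundtrips_bytewise(self, tmp_path):
        p = tmp_path / "a.phy"
        p.write_text(" 3 6\nalpha  ACDEFG\nbeta   ACDEFH\ngamma  ACDEFI\n")
        aln = read_alignment(p, "phylip", Alphabet.AA)
        assert aln.n_taxa == 3 and aln.n_sites == 6
        out1 = tmp_path / "w1.phy"
        out2 = tmp_path / "w2.phy"
        write_alignment(aln, out1, "phylip")
        write_alignment(read_alignment(out1, "phylip", Alphabet.AA), out2, "phylip")
        assert out1.read_bytes() == out2.read_bytes()

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        n_taxa=st.integers(2, 6),
        n_sites=st.integers(1, 40),
        fmt=st.sampled_from(["fasta", "phylip"]),
        data=st.data(),
    )
    def test_write_read_identity_property(self, tmp_path_factory, n_taxa, n_sites,
                                          fmt, data):
        """write then read restores taxa, matrix, and alphabet exactly."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        symbols = list(Alphabet.AA.states) + ["-", "X"]
        rows = {
            f"tx{i}": "".join(rng.choice(symbols, size=n_sites))
            for i in range(n_taxa)
        }
        aln = aln_from_strings(rows, Alphabet.AA)
        path = tmp_path_factory.mktemp("rt") / f"a.{fmt}"
        write_alignment(aln, path, fmt)
        back = read_alignment(path, fmt, Alphabet.AA)
        assert back.taxa == aln.taxa
        assert (back.matrix == aln.matrix).all()


class TestPartitions:
    def test_single_entry(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text("WAG, p1 = 1-100\n")
        scheme = read_partitions(p)
        assert scheme.names() == ["p1"]
        assert scheme.entry("p1").ranges == ((0, 100),)
        assert scheme.entry("p1").model == "WAG"

    def test_codon_stride_dialect(self, tmp_path):
        """'1-99\\3' takes every third site starting at the range's first."""
        p = tmp_path / "p.txt"
        p.write_text("GTR, p2 = 1-99\\3\n")
        entry = read_partitions(p).entry("p2")
        assert entry.codon_stride == 3
        sites = entry.sites()
        assert sites[0] == 0 and sites[1] == 3 and len(sites) == 33

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text("WAG, p1 = 1-100\nWAG, p3 = 90-110\n")
        with pytest.raises(PartitionOverlapError):
            read_partitions(p)

    def test_bounds_checked_at_attach(self):
        scheme = PartitionScheme((PartitionEntry("p1", ((0, 100),)),))
        with pytest.raises(PartitionBoundsError):
            scheme.validate_against(50)

    def test_format_roundtrip(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text("WAG, p1 = 1-60\nGTR, p2 = 61-120\\3\n")
        scheme = read_partitions(p)
        p2 = tmp_path / "q.txt"
        seqio.write_partitions(scheme, p2)
        assert read_partitions(p2) == scheme


class TestCodonExtraction:
    def test_single_partition_position2(self):
        aln = aln_from_strings({"A": "ACGTACGTA", "B": "ACGTACGTA"}, Alphabet.NT)
        out = extract_codon_positions(aln, 2)
        assert out.n_sites == 3
        assert out.sequence("A") == "CAT"  # original 1-based sites 2, 5, 8

    def test_two_partitions_position3(self):
        scheme = PartitionScheme(
            (PartitionEntry("p1", ((0, 6),)), PartitionEntry("p2", ((6, 12),)))
        )
        aln = aln_from_strings(
            {"A": "ACGTAGCATGCA", "B": "ACGTAGCATGCA"}, Alphabet.NT, scheme
        )
        out = extract_codon_positions(aln, 3)
        # original 1-based sites {3, 6, 9, 12} -> "GG" + "TA"
        assert out.sequence("A") == "GGTA"
        assert [e.n_sites for e in out.effective_partitions()] == [2, 2]

    def test_frame_error(self):
        aln = aln_from_strings({"A": "ACGTACGT", "B": "ACGTACGT"}, Alphabet.NT)
        with pytest.raises(FrameError):
            extract_codon_positions(aln, 1)

    def test_aa_rejected(self):
        aln = aln_from_strings({"A": "ACDEFG", "B": "ACDEFG"}, Alphabet.AA)
        with pytest.raises(AlphabetError):
            extract_codon_positions(aln, 1)

    def test_positions_partition_site_set(self, partitioned_nt_aln):
        """Codon positions 1, 2, 3 tile the original sites exactly."""
        parts = [
            extract_codon_positions(partitioned_nt_aln, i) for i in (1, 2, 3)
        ]
        assert sum(p.n_sites for p in parts) == partitioned_nt_aln.n_sites
        # each original column appears in exactly one extraction
        joined = np.concatenate(
            [p.matrix for p in parts], axis=1
        )
        orig = partitioned_nt_aln.matrix
        assert sorted(map("".join, joined.T.tolist())) == sorted(
            map("".join, orig.T.tolist())
        )


class TestTreesCharactersGroups:
    def test_read_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
        tree = seqio.read_tree(p)
        assert len(tree.leaf_nodes()) == 4

    def test_character_matrix_roundtrip(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("taxon\tc1\tc2\nA\t0\t1\nB\t1\t?\nC\t0\t2\n")
        cm = seqio.read_character_matrix(p)
        assert cm.taxa == ["A", "B", "C"]
        assert cm.state_lists["c2"] == ("1", "2")
        out = tmp_path / "c2.tsv"
        seqio.write_character_matrix(cm, out)
        cm2 = seqio.read_character_matrix(out)
        assert (cm2.states == cm.states).all()

    def test_grouping_valid(self, tmp_path, two_state_quartet_aln):
        p = tmp_path / "g.tsv"
        p.write_text("# label=h1\ng1\tA\ng1\tB\ng2\tC\ng3\tD\ng4\tD2\n")
        aln = aln_from_strings(
            {"A": "AAAA", "B": "AAAA", "C": "AAAA", "D": "AAAA", "D2": "AAAA"}
        )
        g = read_grouping(p, aln)
        assert g.label == "h1" and g.groups[0] == ("A", "B")

    def test_grouping_unknown_taxon(self, tmp_path, two_state_quartet_aln):
        p = tmp_path / "g.tsv"
        p.write_text("g1\tA\ng2\tB\ng3\tC\ng4\tZ\n")
        with pytest.raises(UnknownTaxonError):
            read_grouping(p, two_state_quartet_aln)

    def test_grouping_overlap(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("g1\tA\ng2\tA\ng3\tC\ng4\tD\n")
        with pytest.raises(DisjointnessError):
            read_grouping(p)
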