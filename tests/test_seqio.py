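"""Sequence/alignment I/O, flank windows, and gapped position mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptmcrosstalk.seqio import (
    AlignmentError,
    FormatError,
    Msa,
    PositionError,
    ProteinRecord,
    extract_flank,
    map_position,
    read_alignment,
    read_fasta,
    unmap_column,
    write_fasta,
)


class TestReadFasta:
    @pytest.mark.parametrize(
        "text, expected",
        [
            (">p1\nMKT\n", [("p1", "MKT")]),
            (">a\nMK\n>b\nSTY\n", [("a", "MK"), ("b", "STY")]),
            (">a\nmk t\n", [("a", "MKT")]),  # case/space normalization
        ],
    )
    def test_parses_records(self, tmp_path, text, expected):
        p = tmp_path / "in.fasta"
        p.write_text(text)
        records = read_fasta(p)
        assert [(r.id, r.sequence) for r in records] == expected

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_headerless_file_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("MKT\n")
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(p)

    def test_illegal_residue_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nMK1T\n")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_rare_codes_fold_to_x(self, tmp_path):
        p = tmp_path / "u.fasta"
        p.write_text(">a\nMUK\n")
        assert read_fasta(p)[0].sequence == "MXK"

    def test_round_trip(self, tmp_path):
        records = [
            ProteinRecord(id="a", sequence="MKTAY", description="a first"),
            ProteinRecord(id="b", sequence="WW"),
        ]
        p = tmp_path / "out.fasta"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [(r.id, r.description, r.sequence) for r in back] == [
            (r.id, r.description, r.sequence) for r in records
        ]


class TestReadAlignment:
    def test_identical_rows_width(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMKT\n>y\nMKT\n")
        msa = read_alignment(p, "fasta")
        assert msa.width == 3
        assert msa.ref_id == "x"

    def test_gapped_rows(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMK-T\n>y\nMKST\n")
        msa = read_alignment(p, "fasta")
        assert msa.width == 4
        assert len(msa.ungapped("x")) == 3

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMKT\n>y\nMKST\n")
        with pytest.raises(AlignmentError):
            read_alignment(p, "fasta")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_alignment(tmp_path / "x", "stockholm")

    def test_clustal_block_concatenation(self, tmp_path):
        """A CLUSTAL file split into two blocks equals its single-block form."""
        two_block = (
            "CLUSTAL W (2.0) multiple sequence alignment\n\n"
            "x    MKTA-\n"
            "y    MKTAY\n\n"
            "x    WWC\n"
            "y    W-C\n"
        )
        one_block = (
            "CLUSTAL W (2.0) multiple sequence alignment\n\n"
            "x    MKTA-WWC\n"
            "y    MKTAYW-C\n"
        )
        p2, p1 = tmp_path / "two.aln", tmp_path / "one.aln"
        p2.write_text(two_block)
        p1.write_text(one_block)
        assert read_alignment(p2, "clustal").rows == read_alignment(p1, "clustal").rows

    def test_packaged_clustal_fixture(self, ortholog_msa):
        assert ortholog_msa.width == 673
        assert len(ortholog_msa.rows) == 5


class TestExtractFlank:
    def test_interior_window(self):
        rec = ProteinRecord(id="r", sequence="ACDEFGHIKLMNP")
        assert extract_flank(rec, 7, k=3) == "EFG[H]IKL"

    def test_boundary_truncation(self):
        rec = ProteinRecord(id="r", sequence="MKT")
        assert extract_flank(rec, 1, k=6) == "[M]KT"
        assert extract_flank(rec, 3, k=6) == "MK[T]"

    def test_out_of_range(self):
        rec = ProteinRecord(id="r", sequence="MKT")
        with pytest.raises(PositionError):
            extract_flank(rec, 4)

    @pytest.mark.parametrize(
        "pos, expected",
        [(264, "NKYTKS[R]GRAAKK"), (266, "YTKSRG[R]AAKKKA")],
    )
    def test_methylation_site_flanks(self, foxo3, pos, expected):
        """Flanks around the Arg264/Arg266 methylation sites match the curation."""
        assert extract_flank(foxo3, pos, k=6) == expected

    def test_printed_flank_table(self, foxo3):
        """Every curated methylation flank matches, at its own printed extent."""
        from ptmcrosstalk.fixtures import methyl_table

        for row in methyl_table().itertuples(index=False):
            left, center, right = row.flank.split("*")
            pos = int(row.position)
            got = extract_flank(foxo3, pos, k=8, left_mark="*", right_mark="*")
            gl, gc, gr = got.split("*")
            assert gc == center
            assert gl[len(gl) - len(left):] == left
            assert gr[: len(right)] == right


@st.composite
def gapped_row(draw):
    n = draw(st.integers(min_value=1, max_value=30))
    residues = draw(
        st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY-"), min_size=n, max_size=n)
    )
    if all(c == "-" for c in residues):
        residues[draw(st.integers(0, n - 1))] = "A"
    return "".join(residues)


class TestMapPosition:
    def test_simple(self):
        msa = Msa(rows=(("a", "MK-T"), ("b", "MKST")), ref_id="a")
        assert map_position(msa, "a", 3) == 4

    def test_identity_without_gaps(self):
        msa = Msa(rows=(("a", "MKTAY"), ("b", "MKTAW")), ref_id="a")
        for p in range(1, 6):
            assert map_position(msa, "a", p) == p

    def test_out_of_range(self):
        msa = Msa(rows=(("a", "MK-T"), ("b", "MKST")), ref_id="a")
        with pytest.raises(PositionError):
            map_position(msa, "a", 4)

    @settings(deadline=None, derandomize=True)
    @given(row=gapped_row())
    def test_agrees_with_brute_force_and_inverts(self, row):
        """map_position equals a brute-force non-gap scan; unmap inverts it."""
        other = "A" * len(row)
        msa = Msa(rows=(("q", row), ("o", other)), ref_id="q")
        seen = 0
        for col, ch in enumerate(row, start=1):
            if ch == "-":
                assert unmap_column(msa, "q", col) is None
                continue
            seen += 1
            assert map_position(msa, "q", seen) == col
            assert unmap_column(msa, "q", col) == seen
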