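"""Sequence and alignment I/O with 1-based residue addressing.

All coordinates throughout the package are 1-based and inclusive, matching
UniProt feature tables and the residue numbering used in the curated site
tables. The two containers here — :class:`ProteinRecord` and :class:`Msa` —
are thin, validated wrappers; parsing of FASTA and CLUSTAL files is delegated
to Biopython.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity/rare codes silently folded to X (with a logged warning).
_FOLD_TO_X = set("BZJUO")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file does not parse under the expected format."""


class PositionError(IndexError):
    """Raised when a 1-based residue position is out of range."""


class AlignmentError(ValueError):
    """Raised when alignment rows are inconsistent (ragged, missing ref)."""


def _clean_sequence(raw: str, *, context: str = "") -> str:
    """Upper-case, strip whitespace, fold rare residue codes to X."""
    seq = "".join(raw.split()).upper()
    folded = []
    for ch in seq:
        if ch in STANDARD_RESIDUES or ch == "X":
            folded.append(ch)
        elif ch in _FOLD_TO_X:
            logger.warning("non-standard residue %r in %s mapped to X", ch, context)
            folded.append("X")
        else:
            raise FormatError(f"illegal residue character {ch!r} in {context or 'sequence'}")
    return "".join(folded)


@dataclass(frozen=True)
class ProteinRecord:
    """An ungapped protein sequence with accession-style id.

    ``sequence`` holds upper-case one-letter codes over the 20 standard
    residues plus X; residue positions are addressed 1..len(sequence).
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_RESIDUES - {"X"}
        if bad:
            raise ValueError(f"record {self.id!r}: illegal residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        self._check_pos(pos)
        return self.sequence[pos - 1]

    def _check_pos(self, pos: int) -> None:
        if not 1 <= pos <= len(self.sequence):
            raise PositionError(
                f"position {pos} out of range 1..{len(self.sequence)} for {self.id!r}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Sequences are upper-cased, whitespace is stripped, and rare residue
    codes (B/Z/J/U/O) are folded to X. Input order is preserved.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with path.open() as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        first = text.lstrip().splitlines()[0][:30]
        raise FormatError(f"{path}: line 1: expected FASTA header, got {first!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: malformed header for record #{len(records) + 1}")
        seq = _clean_sequence(str(rec.seq), context=f"{path}:{rec.id}")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        # Biopython's description is the whole header; keep only the part
        # after the id so id/description round-trip independently.
        desc = rec.description
        if desc == rec.id:
            desc = ""
        elif desc.startswith(rec.id + " "):
            desc = desc[len(rec.id) + 1 :]
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f"{rec.id} {rec.description}" if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


@dataclass(frozen=True)
class Msa:
    """A protein multiple sequence alignment with a designated query row.

    ``rows`` is an ordered list of ``(id, gapped_sequence)``; all gapped
    sequences share the same length (the alignment width) and use '-' for
    gaps. ``ref_id`` names the query row whose ungapped coordinates anchor
    downstream per-residue analyses.
    """

    rows: tuple[tuple[str, str], ...]
    ref_id: str
    _col_of_pos: dict[str, tuple[int, ...]] = field(
        default=None, repr=False, compare=False, hash=False
    )

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no rows")
        width = len(self.rows[0][1])
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate row ids in alignment")
        for rid, gapped in self.rows:
            if len(gapped) != width:
                raise AlignmentError(
                    f"ragged alignment: row {rid!r} has length {len(gapped)}, expected {width}"
                )
            ungapped = gapped.replace(GAP, "")
            if not ungapped:
                raise AlignmentError(f"row {rid!r} is all gaps")
            _clean_sequence(ungapped, context=f"alignment row {rid}")
        if self.ref_id not in ids:
            raise AlignmentError(f"ref_id {self.ref_id!r} not among alignment rows")
        # per-row position→column index, built lazily is not worth it at this scale
        lut = {}
        for rid, gapped in self.rows:
            cols = tuple(i + 1 for i, ch in enumerate(gapped) if ch != GAP)
            lut[rid] = cols
        object.__setattr__(self, "_col_of_pos", lut)

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, row_id: str) -> str:
        for rid, gapped in self.rows:
            if rid == row_id:
                return gapped
        raise AlignmentError(f"row {row_id!r} not in alignment")

    def ungapped(self, row_id: str) -> ProteinRecord:
        """The row's sequence with gaps removed, as a :class:`ProteinRecord`."""
        return ProteinRecord(id=row_id, sequence=self.row(row_id).replace(GAP, ""))

    @property
    def ref_record(self) -> ProteinRecord:
        return self.ungapped(self.ref_id)


def read_alignment(path: str | Path, dialect: str = "clustal", ref_id: str | None = None) -> Msa:
    """Read a CLUSTAL (.aln) or aligned-FASTA alignment into an :class:`Msa`.

    ``dialect`` is ``"clustal"`` or ``"fasta"``. The query row defaults to
    the first row. CLUSTAL block concatenation is handled by the parser.
    """
    if dialect not in ("clustal", "fasta"):
        raise ValueError(f"unknown alignment dialect {dialect!r}; use 'clustal' or 'fasta'")
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), dialect)
    except ValueError as exc:
        raise AlignmentError(f"{path}: failed to parse as {dialect}: {exc}") from exc
    rows = tuple(
        (rec.id, _clean_gapped(str(rec.seq), context=f"{path}:{rec.id}")) for rec in aln
    )
    if ref_id is None:
        ref_id = rows[0][0]
    return Msa(rows=rows, ref_id=ref_id)


def _clean_gapped(raw: str, *, context: str) -> str:
    seq = "".join(raw.split()).upper().replace(".", GAP)
    out = []
    for ch in seq:
        if ch == GAP or ch in STANDARD_RESIDUES or ch == "X":
            out.append(ch)
        elif ch in _FOLD_TO_X:
            logger.warning("non-standard residue %r in %s mapped to X", ch, context)
            out.append("X")
        else:
            raise FormatError(f"illegal character {ch!r} in {context}")
    return "".join(out)


def write_alignment(msa: Msa, path: str | Path, dialect: str = "clustal") -> None:
    """Write an :class:`Msa` as CLUSTAL or aligned FASTA."""
    from Bio.Align import MultipleSeqAlignment

    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(gapped), id=rid, description="") for rid, gapped in msa.rows]
    )
    AlignIO.write(aln, str(path), dialect)


def extract_flank(
    record: ProteinRecord,
    pos: int,
    k: int = 6,
    left_mark: str = "[",
    right_mark: str = "]",
) -> str:
    """Flanking window around ``pos``: up to ``k`` residues each side, center marked.

    Truncates at the protein termini; e.g. position 1 yields ``[M]KT...``.
    The center marker defaults to square brackets; pass ``"*"``/``"*"`` to
    reproduce the asterisk style used in printed site tables.
    """
    record._check_pos(pos)
    if k < 0:
        raise ValueError("window half-width k must be >= 0")
    seq = record.sequence
    left = seq[max(0, pos - 1 - k) : pos - 1]
    right = seq[pos : pos + k]
    return f"{left}{left_mark}{seq[pos - 1]}{right_mark}{right}"


def map_position(msa: Msa, row_id: str, ungapped_pos: int) -> int:
    """Alignment column (1-based) holding the ``ungapped_pos``-th residue of a row."""
    cols = msa._col_of_pos.get(row_id)
    if cols is None:
        raise AlignmentError(f"row {row_id!r} not in alignment")
    if not 1 <= ungapped_pos <= len(cols):
        raise PositionError(
            f"ungapped position {ungapped_pos} out of range 1..{len(cols)} for row {row_id!r}"
        )
    return cols[ungapped_pos - 1]


def unmap_column(msa: Msa, row_id: str, column: int) -> int | None:
    """Inverse of :func:`map_position`: the row's ungapped position at ``column``.

    Returns ``None`` when the row has a gap in that column.
    """
    gapped = msa.row(row_id)
    if not 1 <= column <= msa.width:
        raise PositionError(f"column {column} out of range 1..{msa.width}")
    if gapped[column - 1] == GAP:
        return None
    return column - gapped[: column - 1].count(GAP)
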