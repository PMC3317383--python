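"""Consensus methylation calling and homology transfer of known sites.

Arg/Lys methylation predictors disagree enough that single-predictor output
is noisy; the standard remedy is consensus calling — keep a site iff at
least ``min_agree`` of the predictors call it (default 2 of 3, a majority).

Independently, experimentally verified sites on a homolog can be carried
over through a pairwise global (Needleman–Wunsch) alignment: a source site
maps to the aligned column in the target, and the transfer is accepted only
when the target carries the *identical* residue there (R→R, K→K). Both
routes are deliberately conservative: consensus suppresses single-predictor
false positives, residue-identity transfer refuses to extrapolate across
substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GAP, Msa, PositionError, ProteinRecord

METHYL_RESIDUES = ("R", "K")


@dataclass(frozen=True)
class MethylationCallSet:
    """One predictor's set of called Arg/Lys positions."""

    predictor: str
    calls: frozenset[tuple[int, str]]  # (position, residue)

    def __post_init__(self) -> None:
        for pos, res in self.calls:
            if res not in METHYL_RESIDUES:
                raise ValueError(
                    f"{self.predictor}: call at {pos} has residue {res!r}; must be R or K"
                )
            if pos < 1:
                raise ValueError(f"{self.predictor}: position {pos} must be >= 1")

    def validate_against(self, record: ProteinRecord) -> None:
        """Check every call's residue against the target sequence."""
        for pos, res in sorted(self.calls):
            actual = record.residue(pos)
            if actual != res:
                raise ValueError(
                    f"{self.predictor}: call {res}{pos} conflicts with sequence "
                    f"residue {actual} in {record.id}"
                )


def consensus_calls(
    callsets: Sequence[MethylationCallSet], min_agree: int = 2
) -> frozenset[tuple[int, str]]:
    """Sites called by at least ``min_agree`` of the predictors.

    ``min_agree=1`` is the union, ``min_agree=len(callsets)`` the
    intersection; output shrinks monotonically as ``min_agree`` grows.
    """
    if not callsets:
        raise ValueError("at least one call set is required")
    if not 1 <= min_agree <= len(callsets):
        raise ValueError(
            f"min_agree must be in 1..{len(callsets)} (number of call sets), got {min_agree}"
        )
    votes: dict[tuple[int, str], int] = {}
    for cs in callsets:
        for call in cs.calls:
            votes[call] = votes.get(call, 0) + 1
    return frozenset(call for call, n in votes.items() if n >= min_agree)


@dataclass(frozen=True)
class AlignParams:
    """Scoring for pairwise global alignment.

    Defaults: BLOSUM62 with gap open 10 and gap extend 0.5 (entered as
    negative penalties), the customary protein-alignment setting.
    ``matrix_name=None`` with explicit ``match``/``mismatch`` gives simple
    scoring for didactic examples.
    """

    matrix_name: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pair of rows over a global alignment of two sequences."""

    a_id: str
    b_id: str
    a_gapped: str
    b_gapped: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a_gapped) != len(self.b_gapped):
            raise ValueError("aligned rows must have equal length")

    def as_msa(self) -> Msa:
        return Msa(rows=((self.a_id, self.a_gapped), (self.b_id, self.b_gapped)), ref_id=self.a_id)


def align_global(
    a: ProteinRecord, b: ProteinRecord, params: AlignParams | None = None
) -> PairwiseAlignment:
    """Optimal Needleman–Wunsch global alignment of two protein sequences.

    Tie-breaking is deterministic: of the co-optimal alignments, the
    traceback preferring diagonal (match/mismatch) over a-row gaps over
    b-row gaps is returned.
    """
    params = params or AlignParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if params.matrix_name:
        aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    else:
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    alignments = aligner.align(a.sequence, b.sequence)
    best = alignments[0]  # Biopython's enumeration order is deterministic
    a_row, b_row = str(best[0]), str(best[1])
    return PairwiseAlignment(
        a_id=a.id, b_id=b.id, a_gapped=a_row, b_gapped=b_row, score=float(best.score)
    )


@dataclass(frozen=True)
class TransferResult:
    """Outcome of mapping one source site through the alignment."""

    src_position: int
    src_residue: str
    dst_position: int | None  # None when the site faces a gap
    dst_residue: str | None
    residue_match: bool
    aligned_column: int


def transfer_sites(
    src: ProteinRecord,
    dst: ProteinRecord,
    src_sites: Sequence[int],
    params: AlignParams | None = None,
    alignment: PairwiseAlignment | None = None,
) -> list[TransferResult]:
    """Map source-protein site positions onto a homolog via global alignment.

    Each source position maps to its alignment column; the result records
    the target position under that column (or ``None`` opposite a gap) and
    whether the target residue is identical. Only ``residue_match`` results
    are candidate transfers.
    """
    if alignment is None:
        alignment = align_global(src, dst, params)
    a_row, b_row = alignment.a_gapped, alignment.b_gapped
    # source ungapped position -> column index (0-based)
    col_of = [i for i, ch in enumerate(a_row) if ch != GAP]
    results = []
    for pos in sorted(src_sites):
        if not 1 <= pos <= len(col_of):
            raise PositionError(f"source position {pos} out of range 1..{len(col_of)}")
        col = col_of[pos - 1]
        src_res = a_row[col]
        dst_char = b_row[col]
        if dst_char == GAP:
            results.append(
                TransferResult(
                    src_position=pos,
                    src_residue=src_res,
                    dst_position=None,
                    dst_residue=None,
                    residue_match=False,
                    aligned_column=col + 1,
                )
            )
        else:
            dst_pos = col + 1 - b_row[:col].count(GAP)
            results.append(
                TransferResult(
                    src_position=pos,
                    src_residue=src_res,
                    dst_position=dst_pos,
                    dst_residue=dst_char,
                    residue_match=dst_char == src_res,
                    aligned_column=col + 1,
                )
            )
    return results


# ---------------------------------------------------------------------------
# TSV interchange


def read_callsets(path: str | Path) -> list[MethylationCallSet]:
    """Read per-predictor methylation calls (predictor, position, residue)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for predictor, group in df.groupby("predictor", sort=True):
        calls = frozenset(
            (int(row.position), str(row.residue).strip()) for row in group.itertuples(index=False)
        )
        out.append(MethylationCallSet(predictor=str(predictor), calls=calls))
    return out


def transfers_to_frame(results: Sequence[TransferResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "src_pos": r.src_position,
                "src_residue": r.src_residue,
                "dst_pos": r.dst_position,
                "dst_residue": r.dst_residue,
                "residue_match": r.residue_match,
                "aligned_column": r.aligned_column,
            }
            for r in results
        ],
        columns=["src_pos", "src_residue", "dst_pos", "dst_residue", "residue_match", "aligned_column"],
    )
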