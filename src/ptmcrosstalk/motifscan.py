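"""Kinase-motif scanning over 15-residue windows.

A kinase's substrate preference is modeled as a position weight matrix over
the window of seven residues on either side of a candidate phosphoacceptor
(positions -7..+7). A candidate window's raw score is the sum of per-position
weights; its rank is the fraction of a background score reservoir that beats
it strictly, so 0.0 is the best possible rank and small percentiles are
stringent matches (the convention of percentile-ranked motif scanners).
Candidate sites may additionally carry a surface-accessibility (SA) value;
hits simply transport it so downstream filters can apply the exposure rule.

Scores are raw sums (no length normalization). Sequence termini are padded
with X, which scores 0 at every matrix position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import ProteinRecord

WINDOW_HALF = 7
WINDOW_LEN = 2 * WINDOW_HALF + 1
RESIDUE_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_RES_INDEX = {r: i for i, r in enumerate(RESIDUE_ORDER)}


class NoScore(Exception):
    """Signal that a window's center residue is not targetable by the motif."""


@dataclass(frozen=True)
class KinaseMotif:
    """A 15x20 position weight matrix for one kinase.

    ``weights`` is indexed ``[position, residue]`` with positions -7..+7
    mapped to rows 0..14 and residues in :data:`RESIDUE_ORDER`. ``X`` (the
    terminal pad) always scores 0. Position 0 (row 7) should carry nonzero
    weight only for the targetable residues.
    """

    name: str
    target_residues: frozenset[str]
    weights: np.ndarray  # (15, 20) float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (WINDOW_LEN, 20):
            raise ValueError(f"motif {self.name!r}: weights must be 15x20, got {w.shape}")
        if not np.isfinite(w).all():
            raise ValueError(f"motif {self.name!r}: weights contain non-finite cells")
        bad = self.target_residues - set("STY")
        if bad:
            raise ValueError(f"motif {self.name!r}: target residues must be S/T/Y, got {bad}")
        object.__setattr__(self, "weights", w)

    def weight(self, offset: int, residue: str) -> float:
        """Weight of ``residue`` at window offset in -7..+7; X scores 0."""
        if residue == "X":
            return 0.0
        return float(self.weights[offset + WINDOW_HALF, _RES_INDEX[residue]])


@dataclass(frozen=True)
class KinaseHit:
    kinase: str
    position: int  # 1-based center on the scanned protein
    residue: str
    score: float
    percentile: float
    sa: float | None = None


def score_window(motif: KinaseMotif, window: str) -> float:
    """Raw motif score of a 15-residue window (sum of per-position weights)."""
    if len(window) != WINDOW_LEN:
        raise ValueError(f"window must be {WINDOW_LEN} residues, got {len(window)}")
    center = window[WINDOW_HALF]
    if center not in motif.target_residues:
        raise NoScore(f"center residue {center!r} not targetable by motif {motif.name!r}")
    return sum(motif.weight(off, res) for off, res in zip(range(-WINDOW_HALF, WINDOW_HALF + 1), window))


def window_at(record: ProteinRecord, pos: int) -> str:
    """The 15-residue window centered at ``pos``, X-padded at the termini."""
    record._check_pos(pos)
    seq = record.sequence
    chars = []
    for off in range(-WINDOW_HALF, WINDOW_HALF + 1):
        i = pos + off
        chars.append(seq[i - 1] if 1 <= i <= len(seq) else "X")
    return "".join(chars)


def background_percentile(score: float, background: Sequence[float]) -> float:
    """Fraction of background scores strictly better than ``score``.

    0.0 is the best attainable rank; ties resolve in the candidate's favor
    (only *strictly* greater background scores count against it).
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background reservoir is empty")
    return float(np.count_nonzero(bg > score) / bg.size)


def build_background(motif: KinaseMotif, references: Iterable[ProteinRecord]) -> np.ndarray:
    """Score reservoir: every targetable window in a reference sequence set.

    Deterministic given the reference set; intended to play the role of the
    'all potential vertebrate motifs' reservoir that percentile ranking is
    computed against.
    """
    scores = []
    for rec in references:
        for pos, res in enumerate(rec.sequence, start=1):
            if res in motif.target_residues:
                scores.append(score_window(motif, window_at(rec, pos)))
    if not scores:
        raise ValueError("reference set contains no targetable residues")
    return np.asarray(scores, dtype=float)


def scan_protein(
    record: ProteinRecord,
    motifs: Sequence[KinaseMotif],
    backgrounds: Mapping[str, Sequence[float]],
    sa_values: Mapping[int, float] | None = None,
    percentile_cutoff: float = 0.05,
) -> list[KinaseHit]:
    """Scan every targetable residue against each motif; keep stringent hits.

    A hit is emitted when the window's background percentile is at or below
    ``percentile_cutoff``. ``sa_values`` maps 1-based positions to surface
    accessibility; missing positions yield hits with ``sa=None``. Output is
    sorted by (position, kinase).
    """
    if not 0 <= percentile_cutoff <= 1:
        raise ValueError("percentile_cutoff must be in [0, 1]")
    sa_values = sa_values or {}
    hits: list[KinaseHit] = []
    for motif in motifs:
        bg = backgrounds[motif.name]
        for pos, res in enumerate(record.sequence, start=1):
            if res not in motif.target_residues:
                continue
            s = score_window(motif, window_at(record, pos))
            pct = background_percentile(s, bg)
            if pct <= percentile_cutoff:
                hits.append(
                    KinaseHit(
                        kinase=motif.name,
                        position=pos,
                        residue=res,
                        score=s,
                        percentile=pct,
                        sa=sa_values.get(pos),
                    )
                )
    hits.sort(key=lambda h: (h.position, h.kinase))
    return hits


# ---------------------------------------------------------------------------
# TSV interchange


def read_motif_tsv(path: str | Path) -> KinaseMotif:
    """Read a motif matrix TSV.

    Leading ``#key<TAB>value`` metadata lines carry ``name`` and ``targets``;
    the table body has an ``offset`` column (-7..7) and one column per
    residue in :data:`RESIDUE_ORDER`.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    df = df.set_index("offset").sort_index()
    if list(df.index) != list(range(-WINDOW_HALF, WINDOW_HALF + 1)):
        raise ValueError(f"{path}: motif table must cover offsets -7..7 exactly")
    missing = [r for r in RESIDUE_ORDER if r not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing residue columns {missing}")
    weights = df[list(RESIDUE_ORDER)].to_numpy(dtype=float)
    return KinaseMotif(
        name=meta.get("name", path.stem),
        target_residues=frozenset(meta.get("targets", "STY")),
        weights=weights,
    )


def write_motif_tsv(motif: KinaseMotif, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(motif.weights, columns=list(RESIDUE_ORDER))
    df.insert(0, "offset", range(-WINDOW_HALF, WINDOW_HALF + 1))
    with path.open("w") as fh:
        fh.write(f"#name\t{motif.name}\n")
        fh.write(f"#targets\t{''.join(sorted(motif.target_residues))}\n")
        df.to_csv(fh, sep="\t", index=False)


def hits_to_frame(hits: Sequence[KinaseHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kinase": h.kinase,
                "position": h.position,
                "residue": h.residue,
                "score": h.score,
                "percentile": h.percentile,
                "sa": h.sa,
            }
            for h in hits
        ],
        columns=["kinase", "position", "residue", "score", "percentile", "sa"],
    )
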