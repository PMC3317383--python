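"""Per-residue evolutionary conservation from an ortholog alignment.

Conservation is one of the three selection filters applied to predicted
modification sites: a residue supported by strict identity across the
aligned ortholog set is much more likely to sit in a functional motif than
one that drifts freely. The rule here is deliberately simple — the fraction
of non-query rows carrying the *identical* residue in the query residue's
alignment column, thresholded at ``min_fraction`` (default 1.0, i.e. all
orthologs must agree). Gaps count as mismatches: a deletion in an ortholog
is evidence against conservation. An optional residue-equivalence table
relaxes identity to group membership (e.g. treating S and T as exchangeable)
for users who want similarity-aware conservation; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .seqio import GAP, Msa, PositionError


@dataclass(frozen=True)
class ConservationProfile:
    """Per-position conservation flags and support for a query sequence.

    ``support[p-1]`` is the fraction of non-query rows whose residue in the
    column of query position ``p`` is identical to (or equivalent with) the
    query residue; ``flags[p-1]`` is ``support >= min_fraction``.
    """

    ref_id: str
    residues: str
    support: tuple[float, ...]
    flags: tuple[bool, ...]
    min_fraction: float

    def __len__(self) -> int:
        return len(self.flags)

    def is_conserved(self, pos: int) -> bool:
        if not 1 <= pos <= len(self.flags):
            raise PositionError(f"position {pos} out of range 1..{len(self.flags)}")
        return self.flags[pos - 1]

    def support_at(self, pos: int) -> float:
        if not 1 <= pos <= len(self.support):
            raise PositionError(f"position {pos} out of range 1..{len(self.support)}")
        return self.support[pos - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": range(1, len(self.flags) + 1),
                "ref_residue": list(self.residues),
                "support": self.support,
                "conserved": self.flags,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def conservation_profile(
    msa: Msa,
    min_fraction: float = 1.0,
    equivalences: Mapping[str, Sequence[str]] | None = None,
) -> ConservationProfile:
    """Score each query-row position for conservation across the other rows.

    Parameters
    ----------
    msa
        Alignment with the query identified by ``msa.ref_id``.
    min_fraction
        Minimum fraction of non-query rows that must match for a position to
        be flagged conserved; in (0, 1]. The default 1.0 demands identity in
        every ortholog.
    equivalences
        Optional mapping residue -> iterable of residues counted as matches
        (identity is always a match). By default only identity counts.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    others = [gapped for rid, gapped in msa.rows if rid != msa.ref_id]
    if not others:
        raise ValueError("conservation is undefined without ortholog rows")
    ref_gapped = msa.row(msa.ref_id)
    equiv = {k: frozenset(v) | {k} for k, v in (equivalences or {}).items()}

    residues = []
    support = []
    flags = []
    for col, ref_res in enumerate(ref_gapped):
        if ref_res == GAP:
            continue
        accepted = equiv.get(ref_res, frozenset({ref_res}))
        n_match = sum(1 for row in others if row[col] in accepted)
        frac = n_match / len(others)
        residues.append(ref_res)
        support.append(frac)
        flags.append(frac >= min_fraction)
    return ConservationProfile(
        ref_id=msa.ref_id,
        residues="".join(residues),
        support=tuple(support),
        flags=tuple(flags),
        min_fraction=min_fraction,
    )


def is_conserved(profile: ConservationProfile, pos: int) -> bool:
    """Conservation flag at 1-based query position ``pos``."""
    return profile.is_conserved(pos)
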