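"""Phosphorylation / O-GlcNAc crosstalk classification of Ser/Thr/Tyr sites.

This is the analytical core of the package. Each candidate residue carries
two predictor channels — a phosphorylation potential and (for Ser/Thr) an
O-GlcNAc potential — each compared against its own threshold. A site where
both channels clear their thresholds is a *positive Yin Yang site*: a single
hydroxyl that kinases and O-GlcNAc transferase compete for, hence a point of
reciprocal regulation. A conserved site where one channel clears its
threshold and the other falls *just short* (within a small margin epsilon)
is a *false-negative Yin Yang site* — the near-miss channel is treated as a
plausible predictor miss rather than a true negative, precisely because
evolutionary conservation argues the residue is functional.

Classification is mutually exclusive and exhaustive, with precedence
YY_POSITIVE > YY_FALSE_NEGATIVE > single-channel classes > NONE.

Three selection filters are then recorded per site: (i) presence in a
curated experimentally-verified (EV) phosphosite table, (ii) evolutionary
conservation across orthologs, (iii) structural accessibility — surface
accessibility SA >= 0.5 counts as exposed. Sites whose SA the upstream
predictor did not report are retained as positive predictions with
``accessible`` left unknown, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("above", "near", "below")


class Classification(str, Enum):
    NONE = "NONE"
    PHOSPHO_ONLY = "PHOSPHO_ONLY"
    GLYC_ONLY = "GLYC_ONLY"
    YY_POSITIVE = "YY_POSITIVE"
    YY_FALSE_NEGATIVE = "YY_FALSE_NEGATIVE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CrosstalkParams:
    """Thresholds and margins for site classification.

    ``phos_threshold`` — phosphorylation-potential cutoff (predictor scale
    0..1; 0.5 is the conventional neural-net operating point).
    ``sa_min`` — minimum surface accessibility counted as exposed (0.5).
    ``epsilon`` — the 'very close to threshold' margin used for the
    false-negative Yin Yang call, on the potential scale (default 0.1).
    ``min_fraction`` — conservation support threshold (see conservation
    module; default 1.0 = strict identity across all orthologs).
    """

    phos_threshold: float = 0.5
    sa_min: float = 0.5
    epsilon: float = 0.1
    min_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.phos_threshold < 1:
            raise ValueError("phos_threshold must be in (0, 1)")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SiteScore:
    """Predictor readout for one candidate Ser/Thr/Tyr residue.

    Each channel is either a numeric potential (compared against its
    threshold with margin epsilon) or a pre-binned category in
    {'above', 'near', 'below'}. Tyr residues have no O-GlcNAc channel
    (``glyc=None``). ``sa`` is the surface-accessibility value when the
    upstream scanner reported one.
    """

    position: int
    residue: str
    phos: float | str
    glyc: float | str | None
    phos_threshold: float = 0.5
    glyc_threshold: float = 0.5
    sa: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"site residue must be S/T/Y, got {self.residue!r}")
        if self.residue == "Y" and self.glyc is not None:
            raise ValueError("Tyr sites have no O-GlcNAc channel; glyc must be None")
        for label, value in (("phos", self.phos), ("glyc", self.glyc)):
            if isinstance(value, str) and value not in CATEGORIES:
                raise ValueError(f"{label} category must be one of {CATEGORIES}, got {value!r}")

    def phos_category(self, params: CrosstalkParams) -> str:
        return _categorize(self.phos, self.phos_threshold, params.epsilon)

    def glyc_category(self, params: CrosstalkParams) -> str | None:
        if self.glyc is None:
            return None
        return _categorize(self.glyc, self.glyc_threshold, params.epsilon)


def _categorize(value: float | str, threshold: float, epsilon: float) -> str:
    """Bin a potential: above (>= threshold), near (within epsilon below), below."""
    if isinstance(value, str):
        return value
    if value >= threshold:
        return "above"
    if threshold - value <= epsilon:
        return "near"
    return "below"


@dataclass(frozen=True)
class ExperimentalAnnotation:
    """One curated, experimentally verified phosphosite."""

    position: int
    residue: str
    kinases: tuple[str, ...] = ()
    source_tag: str = ""


@dataclass(frozen=True)
class SiteAnnotation:
    """A classified site with its three selection-filter flags."""

    site: SiteScore
    classification: Classification
    conserved: bool
    ev_support: bool = False
    accessible: bool | None = None  # None = SA unknown
    kinases: tuple[str, ...] = ()

    @property
    def position(self) -> int:
        return self.site.position

    @property
    def residue(self) -> str:
        return self.site.residue

    @property
    def accepted(self) -> bool:
        """Passes the reporting filter: conserved and not buried (unknown SA ok)."""
        return self.conserved and (self.accessible is not False)

    @property
    def phospho_positive(self) -> bool:
        """Phosphorylation channel above threshold (incl. the FN phospho arm)."""
        return self.classification in (
            Classification.PHOSPHO_ONLY,
            Classification.YY_POSITIVE,
        ) or (
            self.classification is Classification.YY_FALSE_NEGATIVE
            and _fn_strong_channel(self) == "phos"
        )

    @property
    def glyc_positive(self) -> bool:
        """O-GlcNAc channel above threshold (incl. the FN glyc arm)."""
        return self.classification in (
            Classification.GLYC_ONLY,
            Classification.YY_POSITIVE,
        ) or (
            self.classification is Classification.YY_FALSE_NEGATIVE
            and _fn_strong_channel(self) == "glyc"
        )


def _fn_strong_channel(ann: SiteAnnotation) -> str:
    """Which channel of a false-negative Yin Yang site is above threshold."""
    params = CrosstalkParams()
    return "phos" if ann.site.phos_category(params) == "above" else "glyc"


def classify_site(
    site: SiteScore, conserved: bool, params: CrosstalkParams | None = None
) -> Classification:
    """Classify one site from its two predictor channels.

    Let P/G be 'channel above threshold' and nearP/nearG 'within epsilon
    below threshold'. Then, in precedence order::

        YY_POSITIVE        if P and G
        YY_FALSE_NEGATIVE  if conserved and ((P and nearG) or (G and nearP))
        PHOSPHO_ONLY       if P
        GLYC_ONLY          if G
        NONE               otherwise

    Tyr sites have no O-GlcNAc channel, so only PHOSPHO_ONLY/NONE are
    reachable for them.
    """
    params = params or CrosstalkParams()
    p_cat = site.phos_category(params)
    g_cat = site.glyc_category(params)
    P = p_cat == "above"
    nearP = p_cat == "near"
    G = g_cat == "above"
    nearG = g_cat == "near"
    if P and G:
        return Classification.YY_POSITIVE
    if conserved and ((P and nearG) or (G and nearP)):
        return Classification.YY_FALSE_NEGATIVE
    if P:
        return Classification.PHOSPHO_ONLY
    if G:
        return Classification.GLYC_ONLY
    return Classification.NONE


def apply_selection_parameters(
    site: SiteScore,
    classification: Classification,
    conserved: bool,
    ev_db: Sequence[ExperimentalAnnotation],
    params: CrosstalkParams | None = None,
    kinases: Sequence[str] = (),
) -> SiteAnnotation:
    """Attach the three selection-filter flags to a classified site.

    EV matching is by position *and* residue; an EV entry at the site's
    position with a different residue letter indicates a curation error and
    raises rather than silently mismatching.
    """
    params = params or CrosstalkParams()
    ev_support = False
    ev_kinases: tuple[str, ...] = ()
    for ev in ev_db:
        if ev.position == site.position:
            if ev.residue != site.residue:
                raise ValueError(
                    f"EV table residue {ev.residue} at position {ev.position} "
                    f"conflicts with site residue {site.residue}"
                )
            ev_support = True
            ev_kinases = tuple(ev.kinases)
    accessible = None if site.sa is None else site.sa >= params.sa_min
    merged = tuple(dict.fromkeys((*kinases, *ev_kinases)))
    return SiteAnnotation(
        site=site,
        classification=classification,
        conserved=conserved,
        ev_support=ev_support,
        accessible=accessible,
        kinases=merged,
    )


def annotate_sites(
    sites: Sequence[SiteScore],
    conserved_positions: Iterable[int] | Mapping[int, bool],
    ev_db: Sequence[ExperimentalAnnotation] = (),
    params: CrosstalkParams | None = None,
    kinase_map: Mapping[int, Sequence[str]] | None = None,
) -> list[SiteAnnotation]:
    """Classify and filter a whole site table in one pass."""
    params = params or CrosstalkParams()
    if isinstance(conserved_positions, Mapping):
        is_cons = lambda p: bool(conserved_positions.get(p, False))  # noqa: E731
    else:
        cons_set = set(conserved_positions)
        is_cons = lambda p: p in cons_set  # noqa: E731
    kinase_map = kinase_map or {}
    out = []
    for site in sites:
        conserved = is_cons(site.position)
        cls = classify_site(site, conserved, params)
        out.append(
            apply_selection_parameters(
                site, cls, conserved, ev_db, params, kinases=kinase_map.get(site.position, ())
            )
        )
    return out


def summarize_classifications(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    """Residue-by-classification count table (rows S/T/Y, one column per class).

    Raises on duplicate positions; totals per residue equal the number of
    input sites of that residue by construction.
    """
    positions = [a.position for a in annotations]
    if len(positions) != len(set(positions)):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate site positions in annotation set: {dupes}")
    counts = pd.DataFrame(
        0, index=list("STY"), columns=[c.value for c in Classification], dtype=int
    )
    for a in annotations:
        counts.loc[a.residue, a.classification.value] += 1
    counts.index.name = "residue"
    return counts


def phospho_positive_counts(annotations: Sequence[SiteAnnotation]) -> dict[str, int]:
    """Per-residue counts of phosphorylation-positive sites (and 'total')."""
    out = {"S": 0, "T": 0, "Y": 0}
    for a in annotations:
        if a.phospho_positive:
            out[a.residue] += 1
    out["total"] = sum(out.values())
    return out


def glyc_positive_counts(annotations: Sequence[SiteAnnotation]) -> dict[str, int]:
    """Per-residue counts of O-GlcNAc-positive sites (and 'total')."""
    out = {"S": 0, "T": 0}
    for a in annotations:
        if a.residue != "Y" and a.glyc_positive:
            out[a.residue] += 1
    out["total"] = sum(out.values())
    return out


def kinase_crosstab(
    annotations: Sequence[SiteAnnotation],
    kinase_assignments: Mapping[int, Sequence[str]] | None = None,
) -> dict[str, dict]:
    """Group sites by assigned kinase.

    ``kinase_assignments`` maps position -> kinase names; when omitted, the
    kinases already attached to each annotation are used. Assignments at
    positions absent from the annotation set are warned about and dropped.
    Each kinase entry lists its sites sorted by position and the site with
    the maximum known SA (``None`` if no SA is known for any site).
    """
    by_pos = {a.position: a for a in annotations}
    pairs: list[tuple[str, SiteAnnotation]] = []
    if kinase_assignments is not None:
        for pos, kinases in kinase_assignments.items():
            ann = by_pos.get(pos)
            if ann is None:
                logger.warning("kinase assignment at non-site position %d excluded", pos)
                continue
            for k in kinases:
                pairs.append((k, ann))
    else:
        for ann in annotations:
            for k in ann.kinases:
                pairs.append((k, ann))
    table: dict[str, dict] = {}
    for kinase, ann in sorted(pairs, key=lambda t: (t[0], t[1].position)):
        entry = table.setdefault(kinase, {"sites": [], "max_sa_site": None})
        entry["sites"].append({"position": ann.position, "residue": ann.residue, "sa": ann.site.sa})
    for entry in table.values():
        with_sa = [s for s in entry["sites"] if s["sa"] is not None]
        if with_sa:
            entry["max_sa_site"] = max(with_sa, key=lambda s: s["sa"])
    return table


# ---------------------------------------------------------------------------
# TSV interchange

SITE_COLUMNS = [
    "position",
    "residue",
    "phos_potential_or_cat",
    "phos_threshold",
    "glyc_potential_or_cat",
    "glyc_threshold",
    "sa",
]


def _parse_channel(raw) -> float | str | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if s in ("", "-", "NA", "na"):
        return None
    if s in CATEGORIES:
        return s
    return float(s)


def read_site_table(path: str | Path) -> list[SiteScore]:
    """Read a per-residue site score TSV (``#`` lines are comments)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: site table missing columns {missing}")
    sites = []
    for row in df.itertuples(index=False):
        glyc = _parse_channel(row.glyc_potential_or_cat)
        phos = _parse_channel(row.phos_potential_or_cat)
        if phos is None:
            raise ValueError(f"{path}: position {row.position}: phos channel is required")
        sa = _parse_channel(row.sa)
        sites.append(
            SiteScore(
                position=int(row.position),
                residue=str(row.residue).strip(),
                phos=phos,
                glyc=glyc,
                phos_threshold=float(row.phos_threshold),
                glyc_threshold=float(row.glyc_threshold) if not pd.isna(row.glyc_threshold) else 0.5,
                sa=None if sa is None or isinstance(sa, str) else float(sa),
            )
        )
    return sites


def read_ev_table(path: str | Path) -> list[ExperimentalAnnotation]:
    """Read a curated EV phosphosite TSV (position, residue, kinases, source_tag)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        kin = getattr(row, "kinases", "") or ""
        kinases = tuple(k.strip() for k in str(kin).split(";") if k.strip() and str(kin) != "nan")
        out.append(
            ExperimentalAnnotation(
                position=int(row.position),
                residue=str(row.residue).strip(),
                kinases=kinases,
                source_tag=str(getattr(row, "source_tag", "") or ""),
            )
        )
    seen = {}
    for ev in out:
        if ev.position in seen:
            raise ValueError(f"{path}: duplicate EV position {ev.position}")
        seen[ev.position] = ev
    return out


def annotations_to_frame(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    """Flatten annotations into the site-table-plus-flags report layout."""
    rows = []
    for a in sorted(annotations, key=lambda x: x.position):
        rows.append(
            {
                "position": a.position,
                "residue": a.residue,
                "conserved": a.conserved,
                "ev": a.ev_support,
                "phos_potential_or_cat": a.site.phos,
                "phos_threshold": a.site.phos_threshold,
                "kinases": ";".join(a.kinases),
                "sa": a.site.sa,
                "glyc_potential_or_cat": "" if a.site.glyc is None else a.site.glyc,
                "glyc_threshold": a.site.glyc_threshold,
                "classification": a.classification.value,
                "accessible": {True: "yes", False: "no", None: "unknown"}[a.accessible],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position",
            "residue",
            "conserved",
            "ev",
            "phos_potential_or_cat",
            "phos_threshold",
            "kinases",
            "sa",
            "glyc_potential_or_cat",
            "glyc_threshold",
            "classification",
            "accessible",
        ],
    )
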