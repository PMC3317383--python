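"""Domain mapping, neighbor-crosstalk annotation, report writing, pipeline.

Outputs are plain TSV/JSON: a per-site table mirroring the classified site
annotations, a methylation table with flanking windows, a neighbor-pair
table for proximity crosstalk (e.g. an Arg methylation site close enough to
an AKT-motif Ser to mask it from its kinase), and a versioned summary JSON
holding every count the analysis produces. ``run_pipeline`` wires the whole
workflow: conservation -> classification -> selection filters ->
methylation consensus + homology transfer -> reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import crosstalk as ct
from . import methylation as meth
from .conservation import conservation_profile
from .seqio import Msa, PositionError, ProteinRecord, extract_flank, read_alignment, read_fasta

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DomainMap:
    """Named 1-based inclusive residue intervals; overlaps are permitted."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for name, start, end in self.entries:
            if not 1 <= start <= end:
                raise ValueError(f"domain {name!r}: invalid interval {start}..{end}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls(
            entries=tuple(
                (str(r.name_), int(r.start), int(r.end))
                for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
            )
        )


def assign_domains(pos: int, domains: DomainMap, protein_length: int | None = None) -> list[str]:
    """Names of all domains whose interval contains ``pos``, in map order."""
    if pos < 1 or (protein_length is not None and pos > protein_length):
        raise PositionError(f"position {pos} out of range")
    return [name for name, start, end in domains.entries if start <= pos <= end]


@dataclass(frozen=True)
class NeighborPair:
    """A cross-modification pair within the proximity radius."""

    methyl_position: int
    methyl_residue: str
    phospho_position: int
    phospho_residue: str
    distance: int


def neighbor_crosstalk(
    phospho_sites: Mapping[int, str] | Sequence[int],
    methyl_sites: Mapping[int, str] | Sequence[int],
    radius: int = 5,
) -> list[NeighborPair]:
    """All (methyl, phospho) pairs within ``radius`` residues of each other.

    Inputs are position->residue mappings (or bare position lists). Each
    cross-modification pair is reported once, sorted by (min position,
    distance). A methylated and a phosphorylated residue this close can
    sterically or electrostatically interfere with each other's writers,
    which is the proximity-crosstalk hypothesis this table surfaces.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not isinstance(phospho_sites, Mapping):
        phospho_sites = {p: "?" for p in phospho_sites}
    if not isinstance(methyl_sites, Mapping):
        methyl_sites = {p: "?" for p in methyl_sites}
    pairs = []
    for m_pos, m_res in methyl_sites.items():
        for p_pos, p_res in phospho_sites.items():
            d = abs(m_pos - p_pos)
            if m_pos != p_pos and d <= radius:
                pairs.append(
                    NeighborPair(
                        methyl_position=m_pos,
                        methyl_residue=m_res,
                        phospho_position=p_pos,
                        phospho_residue=p_res,
                        distance=d,
                    )
                )
    pairs.sort(key=lambda pr: (min(pr.methyl_position, pr.phospho_position), pr.distance))
    return pairs


# ---------------------------------------------------------------------------
# report writing


def _summary_dict(
    annotations: Sequence[ct.SiteAnnotation],
    consensus: frozenset[tuple[int, str]] | None = None,
    neighbors: Sequence[NeighborPair] = (),
    params: ct.CrosstalkParams | None = None,
) -> dict:
    counts = ct.summarize_classifications(annotations)
    fn_sites = sorted(
        f"{a.residue}{a.position}"
        for a in annotations
        if a.classification is ct.Classification.YY_FALSE_NEGATIVE
    )
    yy_sites = sorted(
        a.position for a in annotations if a.classification is ct.Classification.YY_POSITIVE
    )
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "n_sites": len(annotations),
        "classification_counts": {res: counts.loc[res].to_dict() for res in counts.index},
        "phospho_positive": ct.phospho_positive_counts(annotations),
        "glyc_positive": ct.glyc_positive_counts(annotations),
        "yy_positive_total": int(counts["YY_POSITIVE"].sum()),
        "yy_false_negative_sites": fn_sites,
        "yy_positive_positions": yy_sites,
        "ev_supported": sum(1 for a in annotations if a.ev_support),
        "n_neighbor_pairs": len(neighbors),
    }
    if consensus is not None:
        by_res = {"R": 0, "K": 0}
        for _, res in consensus:
            by_res[res] += 1
        summary["methylation_consensus"] = {
            "total": len(consensus),
            "R": by_res["R"],
            "K": by_res["K"],
            "sites": sorted(f"{r}{p}" for p, r in consensus),
        }
    if params is not None:
        summary["params"] = {
            "phos_threshold": params.phos_threshold,
            "sa_min": params.sa_min,
            "epsilon": params.epsilon,
            "min_fraction": params.min_fraction,
        }
    return summary


def write_reports(
    annotations: Sequence[ct.SiteAnnotation],
    out_dir: str | Path,
    consensus: frozenset[tuple[int, str]] | None = None,
    record: ProteinRecord | None = None,
    domains: DomainMap | None = None,
    neighbors: Sequence[NeighborPair] = (),
    transfers: Sequence[meth.TransferResult] = (),
    params: ct.CrosstalkParams | None = None,
    flank_k: int = 6,
) -> dict:
    """Write site_table.tsv, methyl_table.tsv, neighbors.tsv and summary.json.

    Returns the summary dict. Re-reading ``site_table.tsv`` with
    :func:`read_annotations` reproduces the annotation set exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ct.annotations_to_frame(annotations).to_csv(out / "site_table.tsv", sep="\t", index=False)

    methyl_rows = []
    for pos, res in sorted(consensus or ()):
        row = {"position": pos, "residue": res}
        if record is not None:
            row["flank"] = extract_flank(record, pos, k=flank_k, left_mark="*", right_mark="*")
        if domains is not None:
            row["domains"] = ";".join(assign_domains(pos, domains))
        methyl_rows.append(row)
    pd.DataFrame(methyl_rows, columns=["position", "residue", "flank", "domains"]).to_csv(
        out / "methyl_table.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [
            {
                "methyl_position": n.methyl_position,
                "methyl_residue": n.methyl_residue,
                "phospho_position": n.phospho_position,
                "phospho_residue": n.phospho_residue,
                "distance": n.distance,
            }
            for n in neighbors
        ],
        columns=["methyl_position", "methyl_residue", "phospho_position", "phospho_residue", "distance"],
    ).to_csv(out / "neighbors.tsv", sep="\t", index=False)

    if transfers:
        meth.transfers_to_frame(transfers).to_csv(out / "transfers.tsv", sep="\t", index=False)

    summary = _summary_dict(annotations, consensus, neighbors, params)
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def read_annotations(path: str | Path) -> list[ct.SiteAnnotation]:
    """Read back a site_table.tsv into :class:`SiteAnnotation` objects."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        phos = ct._parse_channel(row.phos_potential_or_cat)
        glyc = ct._parse_channel(row.glyc_potential_or_cat)
        sa = row.sa.strip() if isinstance(row.sa, str) else row.sa
        site = ct.SiteScore(
            position=int(row.position),
            residue=row.residue,
            phos=phos,
            glyc=glyc,
            phos_threshold=float(row.phos_threshold),
            glyc_threshold=float(row.glyc_threshold),
            sa=float(sa) if sa not in ("", None) else None,
        )
        out.append(
            ct.SiteAnnotation(
                site=site,
                classification=ct.Classification(row.classification),
                conserved=row.conserved == "True",
                ev_support=row.ev == "True",
                accessible={"yes": True, "no": False, "unknown": None}[row.accessible],
                kinases=tuple(k for k in row.kinases.split(";") if k),
            )
        )
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


class ConfigError(ValueError):
    """Raised for unknown or inconsistent pipeline configuration keys."""


_KNOWN_KEYS = {
    "query_fasta",
    "alignment",
    "alignment_dialect",
    "site_table",
    "ev_table",
    "kinase_table",
    "methyl_callsets",
    "min_agree",
    "domains",
    "transfer_src_fasta",
    "transfer_src_sites",
    "neighbor_radius",
    "out_dir",
    "params",
    "flank_k",
}
_PARAM_KEYS = {"phos_threshold", "sa_min", "epsilon", "min_fraction"}


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    bad_params = set(cfg.get("params", {}) or {}) - _PARAM_KEYS
    if bad_params:
        raise ConfigError(f"unknown params keys: {sorted(bad_params)}")
    return cfg


def read_kinase_table(path: str | Path) -> dict[int, tuple[str, ...]]:
    """Position -> kinase names, from a TSV with 'position' and 'kinases' columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        kinases = tuple(k.strip() for k in str(row.kinases).split(";") if k.strip())
        out[int(row.position)] = kinases
    return out


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow described by a config mapping or YAML path.

    Deterministic given the config and inputs. Returns the summary dict;
    raises ``FileNotFoundError`` naming the first missing input and
    :class:`ConfigError` for invalid keys.
    """
    if not isinstance(config, dict):
        base = Path(config).parent
        cfg = load_config(config)
    else:
        base = Path(".")
        cfg = dict(config)
        unknown = set(cfg) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    def _path(key: str) -> Path | None:
        raw = cfg.get(key)
        if raw is None:
            return None
        p = Path(raw)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise FileNotFoundError(f"config key {key!r}: missing input file {p}")
        return p

    params = ct.CrosstalkParams(**(cfg.get("params") or {}))
    out = Path(out_dir) if out_dir is not None else Path(cfg.get("out_dir", "ptm_reports"))

    record = None
    query_fasta = _path("query_fasta")
    if query_fasta is not None:
        record = read_fasta(query_fasta)[0]

    conserved: Mapping[int, bool] | frozenset = frozenset()
    aln_path = _path("alignment")
    if aln_path is not None:
        msa = read_alignment(aln_path, cfg.get("alignment_dialect", "clustal"))
        profile = conservation_profile(msa, min_fraction=params.min_fraction)
        conserved = {p: profile.is_conserved(p) for p in range(1, len(profile) + 1)}
        logger.info("conservation: %d/%d positions conserved", sum(profile.flags), len(profile))

    sites = ct.read_site_table(_path("site_table")) if cfg.get("site_table") else []
    ev_db = ct.read_ev_table(_path("ev_table")) if cfg.get("ev_table") else []
    kinase_map = read_kinase_table(_path("kinase_table")) if cfg.get("kinase_table") else {}

    annotations = ct.annotate_sites(sites, conserved, ev_db, params, kinase_map)

    consensus = None
    callsets_path = _path("methyl_callsets")
    if callsets_path is not None:
        callsets = meth.read_callsets(callsets_path)
        min_agree = int(cfg.get("min_agree", 2))
        consensus = meth.consensus_calls(callsets, min_agree=min_agree)
        if record is not None:
            for cs in callsets:
                cs.validate_against(record)

    transfers: list[meth.TransferResult] = []
    src_fasta = _path("transfer_src_fasta")
    if src_fasta is not None and record is not None:
        src = read_fasta(src_fasta)[0]
        src_sites = [int(p) for p in cfg.get("transfer_src_sites", [])]
        transfers = meth.transfer_sites(src, record, src_sites)

    domains = DomainMap.from_tsv(_path("domains")) if cfg.get("domains") else None

    neighbors: list[NeighborPair] = []
    if consensus:
        phospho = {a.position: a.residue for a in annotations if a.phospho_positive}
        methyl = {p: r for p, r in consensus}
        neighbors = neighbor_crosstalk(phospho, methyl, radius=int(cfg.get("neighbor_radius", 5)))

    logger.info(
        "pipeline: %d sites, params=%s, out=%s", len(annotations), params, out
    )
    return write_reports(
        annotations,
        out,
        consensus=consensus,
        record=record,
        domains=domains,
        neighbors=neighbors,
        transfers=transfers,
        params=params,
        flank_k=int(cfg.get("flank_k", 6)),
    )
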