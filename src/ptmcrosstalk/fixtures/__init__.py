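"""Packaged FoxO3 fixtures: curated site tables and synthetic stand-in sequences.

The per-residue prediction table, the experimentally-verified (EV)
phosphosite list, the kinase assignments, the methylation tables and the
domain map are transcriptions of the published FoxO3 curation (see each
file's header comments for the transcription changelog).

The sequence files are *synthetic stand-ins*, not database sequences: the
real UniProt/RefSeq entries are not redistributed here. Each stand-in is a
deterministic construction that reproduces every sequence-level constraint
the curated tables assert — protein length 673, the residue letter at every
annotated position, the printed flanking windows around each methylation
site verbatim, and the conservation pattern of the ortholog alignment —
over an otherwise arbitrary background. They are sufficient for exercising
and regression-testing every sequence-level operation in this package, but
they are not FoxO3's actual amino-acid sequence.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..crosstalk import ExperimentalAnnotation, SiteScore, read_ev_table, read_site_table
from ..methylation import MethylationCallSet, read_callsets
from ..report import DomainMap, read_kinase_table
from ..seqio import Msa, ProteinRecord, read_alignment, read_fasta


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture data file."""
    return Path(resources.files(__package__) / "data" / name)


def foxo3_record() -> ProteinRecord:
    """The 673-residue FoxO3 stand-in sequence (synthetic; see module docstring)."""
    return read_fasta(fixture_path("foxo3_human_synthetic.fasta"))[0]


def foxo1_record() -> ProteinRecord:
    """The mouse-FoxO1 stand-in homolog (synthetic; see module docstring)."""
    return read_fasta(fixture_path("foxo1_mouse_synthetic.fasta"))[0]


def ortholog_msa() -> Msa:
    """FoxO3 stand-in aligned with four synthetic ortholog rows (CLUSTAL)."""
    return read_alignment(fixture_path("foxo3_orthologs_synthetic.aln"), "clustal")


def site_scores() -> list[SiteScore]:
    """Curated per-residue phospho/O-GlcNAc prediction table (97 S/T/Y rows)."""
    return read_site_table(fixture_path("foxo3_site_scores.tsv"))


def ev_sites() -> list[ExperimentalAnnotation]:
    """The 21 experimentally verified phosphosites (20 Ser, 1 Thr)."""
    return read_ev_table(fixture_path("foxo3_ev_sites.tsv"))


def kinase_map() -> dict[int, tuple[str, ...]]:
    """Position -> predicted kinase assignments from the curated table."""
    return read_kinase_table(fixture_path("foxo3_kinases.tsv"))


def methyl_callsets() -> list[MethylationCallSet]:
    """Three per-predictor Arg/Lys methylation call sets (constructed fixture)."""
    return read_callsets(fixture_path("foxo3_methyl_callsets.tsv"))


def methyl_table():
    """The curated methylation site table (position, residue, printed flank)."""
    import pandas as pd

    return pd.read_csv(fixture_path("foxo3_methyl_table.tsv"), sep="\t", comment="#", dtype=str)


def domain_map() -> DomainMap:
    """FoxO3 domain coordinates (DBD, NLS, NES, transactivation domain)."""
    return DomainMap.from_tsv(fixture_path("foxo3_domains.tsv"))


def pipeline_config_path() -> Path:
    """YAML config that runs the packaged end-to-end FoxO3 analysis."""
    return fixture_path("foxo3_config.yaml")
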