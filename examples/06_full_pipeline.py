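"""Run the end-to-end pipeline on the packaged FoxO3 inputs.

Conservation -> classification -> selection filters -> methylation
consensus + homology transfer -> neighbor-proximity pairs -> TSV/JSON
reports in ./ptm_reports.
"""

from ptmcrosstalk.fixtures import pipeline_config_path
from ptmcrosstalk.report import run_pipeline

summary = run_pipeline(pipeline_config_path(), out_dir="ptm_reports")

print("phospho-positive:", summary["phospho_positive"])
print("O-GlcNAc-positive:", summary["glyc_positive"])
print("positive Yin Yang sites:", summary["yy_positive_total"])
print("false-negative Yin Yang sites:", summary["yy_false_negative_sites"])
print("methylation consensus:", summary["methylation_consensus"]["sites"])
print(f"neighbor pairs within 5 residues: {summary['n_neighbor_pairs']}")
print("reports written to ./ptm_reports (site_table.tsv, methyl_table.tsv, "
      "neighbors.tsv, transfers.tsv, summary.json)")
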