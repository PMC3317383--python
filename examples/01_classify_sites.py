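"""Classify the packaged FoxO3 site table into phospho/O-GlcNAc crosstalk classes.

Each Ser/Thr site carries two predictor channels; a site above both
thresholds is a positive Yin Yang site (one hydroxyl contested by kinases
and O-GlcNAc transferase), and a conserved site with one channel just below
threshold is a false-negative Yin Yang candidate.
"""

from ptmcrosstalk import fixtures as fx
from ptmcrosstalk.conservation import conservation_profile
from ptmcrosstalk.crosstalk import (
    Classification,
    annotate_sites,
    glyc_positive_counts,
    phospho_positive_counts,
    summarize_classifications,
)

profile = conservation_profile(fx.ortholog_msa(), min_fraction=1.0)
conserved = {p: profile.is_conserved(p) for p in range(1, len(profile) + 1)}
annotations = annotate_sites(fx.site_scores(), conserved, fx.ev_sites(), kinase_map=fx.kinase_map())

print("per-residue classification counts:")
print(summarize_classifications(annotations))
print("\nphosphorylation-positive:", phospho_positive_counts(annotations))
print("O-GlcNAc-positive:       ", glyc_positive_counts(annotations))
fn = [f"{a.residue}{a.position}" for a in annotations
      if a.classification is Classification.YY_FALSE_NEGATIVE]
print("false-negative Yin Yang sites (conserved, one channel near-threshold):", fn)
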