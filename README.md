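# ptmcrosstalk

Posttranslational modifications (PTMs) on a protein rarely act alone: a
serine hydroxyl can be phosphorylated by a kinase *or* O-GlcNAcylated by
O-GlcNAc transferase, and a methylated arginine a few residues away can
mask a kinase's target site. `ptmcrosstalk` is a Python library for calling
these crosstalk sites from per-residue predictor scores, with the human
transcription factor FoxO3 — a tumor suppressor whose phosphorylation by
AKT, ERK and IKK drives its inactivation in several cancers — packaged as
the worked, regression-tested analysis.

It is written for computational biologists who have per-residue predictor
output (phosphorylation potential, O-GlcNAc potential, surface
accessibility, methylation calls) and want a reproducible, testable
classification of crosstalk sites rather than a by-hand spreadsheet.

## The classification rule

For a Ser/Thr residue with phosphorylation potential *p* (threshold 0.5)
and O-GlcNAc potential *g* (predictor-specific threshold), with margin
ε (default 0.1) and a per-site conservation flag from an ortholog
alignment:

| condition | class |
|---|---|
| p ≥ θ_p and g ≥ θ_g | **positive Yin Yang site** |
| conserved and one channel ≥ its θ and the other within ε below | **false-negative Yin Yang site** |
| p ≥ θ_p only | phospho-only |
| g ≥ θ_g only | O-GlcNAc-only |
| otherwise | none |

Three selection filters are recorded per site: (i) presence in a curated
experimentally verified phosphosite table, (ii) strict-identity
conservation across the ortholog alignment, (iii) surface accessibility
SA ≥ 0.5 (sites without an SA value stay positive with accessibility
unknown). Around this core: a 15-position PSSM kinase-motif scanner with
percentile ranking against a background reservoir, 2-of-3 consensus
Arg/Lys methylation calling, Needleman–Wunsch homology transfer of known
sites (residue identity required), domain mapping, and neighbor-proximity
crosstalk pairs (default radius 5 residues).

## Worked example

```bash
python examples/01_classify_sites.py
```

prints, for the packaged FoxO3 curation:

```
         NONE  PHOSPHO_ONLY  GLYC_ONLY  YY_POSITIVE  YY_FALSE_NEGATIVE
residue
S           2            39         16           17                  3
T           1             6          6            2                  1
Y           0             4          0            0                  0

phosphorylation-positive: {'S': 59, 'T': 9, 'Y': 4, 'total': 72}
O-GlcNAc-positive:        {'S': 33, 'T': 8, 'total': 41}
false-negative Yin Yang sites (conserved, one channel near-threshold): ['S294', 'S425', 'S644', 'T32']
```

Read: 72 residues are phosphorylation-positive (59 Ser, 9 Thr, 4 Tyr); 41
are O-GlcNAc-positive; 19 of them (17 Ser, 2 Thr) clear both thresholds and
are positive Yin Yang sites; and four conserved residues — Thr32 (AKT
substrate), Ser294/Ser425 (ERK substrates) and Ser644 (IKK substrate) —
are false-negative Yin Yang candidates whose second channel falls just
short of threshold. `examples/04_methylation.py` adds the nine consensus
methylation sites (Arg 248/250/264/266, Lys 149/207/270/271/569) and maps
the two homolog methyl-arginines onto Arg248/Arg250, three and five
residues from the AKT target Ser253. The other examples cover
conservation profiling, motif scanning, synthetic planted-truth recovery,
and the end-to-end pipeline (also available as the `ptmcrosstalk` CLI:
`classify`, `methyl`, `scan`, `simulate`, `run`).

Note on the packaged sequences: the FASTA/alignment fixtures are
deterministic synthetic stand-ins (marked `_synthetic`) that reproduce the
curation's sequence-level constraints — length, annotated residue
identities, the printed flanking windows, the conservation pattern — not
the actual database sequences (see `docs/methods.md`).

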