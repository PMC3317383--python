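# Methods

## Overview

`ptmcrosstalk` classifies candidate posttranslational-modification sites on
a protein by combining per-residue predictor channels, evolutionary
conservation, and structural accessibility, and layers methylation
consensus calling and homology transfer on top. The package does not
recompute neural-network predictor scores (phosphorylation or O-GlcNAc
potentials, methylation calls): those are *inputs*, supplied as TSV tables,
either as raw potentials or as pre-binned categories
(`above`/`near`/`below`). What the package owns is everything downstream:
binning, classification, filtering, consensus, transfer, and reporting.

## Crosstalk classification

Each Ser/Thr site carries a phosphorylation channel (threshold
`phos_threshold`, default 0.5 — the customary operating point of
neural-network phosphosite predictors) and an O-GlcNAc channel with a
per-site threshold (upstream O-GlcNAc predictors use residue-specific
thresholds, so the threshold is a column, not a constant). Tyr sites have
no O-GlcNAc channel. A numeric potential is binned as

- `above`: potential ≥ threshold;
- `near`: within `epsilon` below threshold;
- `below`: otherwise.

`epsilon` (default 0.1 on the 0–1 potential scale) quantifies "very close
to threshold". The source curation never quantifies it; 0.1 was chosen
once as a visually sensible near-miss band on the predictor scale and is
configurable. The packaged regression tables store the curation's own
categories, so the packaged results do not depend on this default.

Classification, in precedence order (stated explicitly because the prose
rule "both channels high → Yin Yang; conserved and one just short →
false-negative" does not order the cases):

1. `YY_POSITIVE` — both channels `above`;
2. `YY_FALSE_NEGATIVE` — site conserved, one channel `above`, the other
   `near`;
3. `PHOSPHO_ONLY` / `GLYC_ONLY` — a single channel `above`;
4. `NONE` — otherwise.

The classes are mutually exclusive and exhaustive; a truth-table oracle
over all 18 categorical cells and an exact planted-recovery property over
100 seeds pin the rule down in the tests.

Selection filters recorded per site: `ev_support` (position+residue match
against a curated experimentally-verified table — a residue mismatch at a
matching position raises, as it can only be a curation error),
`conserved`, and `accessible` (surface accessibility ≥ `sa_min`, default
0.5). Sites with no SA value keep `accessible=unknown` and remain positive
predictions; dropping them would discard every site the upstream scanner
skipped.

## Conservation

Per query position, support is the fraction of non-query alignment rows
with the *identical* residue in that column; a gap counts as mismatch (a
deletion is evidence against conservation). The flag is
`support ≥ min_fraction` with default 1.0 — strict identity across all
orthologs, the most conservative notion of cross-species conservation; the
fraction is configurable, and an optional residue-equivalence table
(e.g. S≈T) can relax identity. Phylogeny-aware scores and column entropies
are out of scope.

## Kinase motif scanning

A kinase preference is a 15×20 weight matrix over the window of seven
residues each side of the acceptor. Window score is the raw sum of
per-position weights (no length normalization); termini are padded with X,
which scores 0 everywhere. Rank is the fraction of a background reservoir
*strictly* better than the candidate (ties favor the candidate), so 0.0 is
the best rank; the hit cutoff defaults to the 0.05 percentile and is
configurable, since scanner stringency is a user choice. The background
reservoir is built deterministically by scoring every targetable window of
a user-supplied reference FASTA. Published scanners' proprietary matrices
are not reproduced; the packaged FoxO3 kinase assignments are curated
data, and the scanner is validated on synthetic indicator motifs where the
planted optimum is known.

## Methylation consensus and homology transfer

A site is called iff at least `min_agree` of the predictor call sets
contain it. Default 2 of 3 — a majority: intersection-of-all is stricter
than multi-predictor "consensus" plausibly means, union is no consensus at
all. Homology transfer maps known sites through a pairwise global
(Needleman–Wunsch) alignment — BLOSUM62, gap open 10, extend 0.5, the
customary protein setting — and accepts a transfer only when the target
residue is identical (R→R, K→K). Sites opposite a gap transfer to nothing.
Alignment scores are validated against a brute-force dynamic-programming
oracle on short sequences.

## Reporting

`run_pipeline` wires conservation → classification → filters → methylation
→ neighbor pairs → reports, is deterministic given its YAML config, and
writes TSVs (tab-delimited, UTF-8, `.` decimal, no index column), a
round-trippable `site_table.tsv`, and a versioned `summary.json` whose
counts come from the same summarizer the library exposes (single source of
truth). The neighbor-pair radius defaults to 5 residues, which covers both
literature-discussed FoxO3 pairs (Lys207–Ser209 at distance 2,
Arg248/250–Ser253 at distances 5 and 3). Domain maps are data (TSV), not
code; the packaged FoxO3 map carries DBD 148–257, NLS 249–251 and 269–271
(kept as two separate entries named NLS), NES 386–396, TAD 258–673.

## Packaged FoxO3 fixtures

The per-residue table (97 S/T/Y rows), the 21-residue EV list, the kinase
assignments, the 9-site methylation table with printed flanking windows,
and the domain map are transcriptions of the published FoxO3 curation. The
source table is internally inconsistent in a few rows; the reconciliation
(documented row-by-row in the TSV header) resolves in favor of the
published per-residue totals: three Ser rows marked positive on both
channels but not marked Yin Yang have their phospho channel set `below`
(any other resolution changes the published Yin Yang or O-GlcNAc tallies),
and the three highest-numbered rows with no corroborating evidence are
likewise set `below` to match the published 59 S / 9 T / 4 Y totals. One
numeric discrepancy (Ser173 SA printed 3.6 in the table, 3.5 in prose)
follows the table. Which predictor produced which methylation call is not
published; the three packaged call sets are a constructed fixture whose
2-of-3 consensus equals the nine published sites, and are labelled as
such.

The FASTA and alignment files are **synthetic stand-ins** (suffix
`_synthetic`, deterministic construction in the fixture headers'
provenance): database sequences are not redistributed with the package.
Each stand-in satisfies every sequence-level constraint the curation
prints — length 673, the annotated residue letter at all 106 annotated
positions, all nine flanking windows verbatim, valid domain coordinates,
and an ortholog set whose strict-identity conservation matches the
curation's conservation column — over an arbitrary background drawn from
a reduced alphabet (no S/T/Y/R/K outside constrained positions, so every
annotated residue is bookkept). The homolog stand-in shares the
methylation-core region and differs by scattered substitutions and a
15-residue deletion. Consequences: results that depend only on annotated
positions, windows, conservation flags and alignment geometry are faithful;
anything depending on the real background composition (e.g. de novo motif
scanning over FoxO3) is not meaningful on these files and is exercised on
synthetic data instead.

## Synthetic data generators

Generators are pure functions of (parameters, seed) built on NumPy's
PCG64. `gen_orthologs` substitutes each position independently with
probability `sub_rate` (no indels by default so position bookkeeping is
trivial; an indel mode exists for exercising gapped mapping but is
excluded from truth-recovery tests). `gen_site_scores` draws potentials
uniformly inside class-consistent intervals kept ε/2 away from every
decision boundary, so planted-class recovery is exact by construction and
cannot flake on floating-point ties; false-negative Yin Yang sites are
planted only on conserved positions (their definition requires it).
`gen_callsets` includes each true site with probability `sensitivity` and
each eligible non-site with probability `fpr`, independently per
predictor; consensus recall is checked against the closed-form binomial
P(≥2 of 3). Defaults (4 orthologs, sub_rate 0.05, sensitivity 0.9, fpr
0.01, 3 predictors) mirror the packaged study's setting: a handful of
close orthologs and a small panel of reasonably sensitive predictors. The
generators deliberately omit rate heterogeneity, phylogenetic structure,
and realistic neural-network score distributions — passing tests show the
*logic* is exact under the stated model, not that upstream predictors are
accurate on real proteins.

## Problem sizes and numerical choices

All packaged analyses are desk-scale (a 673-residue protein, 97 sites, 5
alignment rows) and run in seconds. Property tests use proteins of 120–600
residues, 100 seeds for recovery fuzzing, 30–40 replicates for the
binomial calibration, and alignment-oracle checks exhaustively to length 3
and sampled to length 8 over a 3-letter alphabet — sizes chosen so the
whole suite stays fast while every branch of the logic is exercised.
Tie-breaking: percentile ties favor the candidate; co-optimal alignments
resolve by the alignment library's deterministic traceback order; sites
sort by (position, kinase) in scanner output. Degenerate inputs error
early and by name: empty FASTA, ragged alignments, single-row alignments
(conservation undefined), `min_agree` exceeding the call-set count,
positions out of range.
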