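# Methods

## Score categorization

Each coding-region predictor is consumed as a precomputed score and banded
into named categories; the binary deleterious call uses the tool's published
cutoff. Band edges are half-open so two-decimal category labels are
unambiguous:

| tool | scale | bands | deleterious call |
|---|---|---|---|
| SIFT | tolerance index ∈ [0, 1] | Intolerant [0, 0.05), PotentiallyIntolerant [0.05, 0.100], Borderline (0.100, 0.20], Tolerated (0.20, 1] | score < 0.05 |
| PolyPhen | PSIC score difference ≥ 0 | Benign [0, 1.00), Borderline [1.00, 1.25), PotentiallyDamaging [1.25, 1.50), PossiblyDamaging [1.50, 2.00), ProbablyDamaging [2.00, ∞) | score ≥ 1.5 (Possibly or Probably damaging) |
| I-Mutant | ΔΔG, kcal/mol | LargeDecrease (< −0.5), Neutral [−0.5, 0.5], LargeIncrease (> 0.5) | ΔΔG < −0.5 (large stability decrease) |
| ConSurf | grade 1–9 | Variable 1–4, Intermediate 5–6, Conserved 7–9 | — |

The published SIFT band labels leave (0.040, 0.050) unassigned at two-decimal
precision; that interval is folded into Intolerant so the category partition
agrees exactly with the 0.05 deleterious cutoff (totality and the
category/cutoff consistency are property-tested). Missing scores yield
missing calls and are never imputed: in practice the upstream web tools fail
independently per variant, and imputation would silently manufacture votes.

## Consensus ranking

The integrative rank is the deleterious-vote count over (SIFT, PolyPhen,
I-Mutant): 3 → Rank I, 2 → II, 1 → III, 0 → IV. The exact decision diagram
behind the original four-tier scheme is not recoverable from its published
description, so the rank rule is a configurable strategy: the default
`vote_count`, and a `weighted` variant that applies per-tool weights to the
same vote-fraction rule (fraction 1 → I, 0 → IV, ≥ ½ → II, else III), which
reduces to `vote_count` at equal weights. Variants with one or two missing
calls are ranked over their available calls by the same fraction rule but
reported in a separate partially-scored stratum, excluded from headline rank
percentages, since the reference cohort has all three predictions for every
variant.

Properties enforced by tests: flipping any call from tolerated to deleterious
never moves the rank toward IV; the rank depends only on the multiset of
calls; every fully-scored variant receives exactly one rank and per-rank
counts sum to the cohort size.

## Statistics

- `percent(k, n)` = 100·k/n rounded **half-away-from-zero** to one decimal
  (decimal arithmetic, not float). Round-half-even does not reproduce
  published percentage tables; half-away does for every internally
  consistent figure (25.0, 75.0, 69.6, 30.4, 50.0, 7.1, 21.4, 61.9).
- Spearman's ρ: tie-corrected (midranks), two-sided p via the t
  approximation (scipy). Inputs are raw score pairs, not categories. n < 3
  or a constant coordinate raises.
- Pearson's χ²: no continuity correction; df = (r−1)(c−1); a zero margin
  raises with instructions to collapse the empty row/column. Both statistics
  are cross-checked in the tests against brute-force oracles (explicit
  midrank computation with Pearson-on-ranks; an observed-vs-expected cell
  loop and the 2×2 closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))).
- Validated-fraction concordance = percent(validated, predicted-deleterious).
  The per-tool severity-split χ² in the pipeline report bins SIFT-deleterious
  variants at score 0 vs (0, 0.05) and PolyPhen at Probably vs Possibly
  damaging; when a bin is empty the χ² is reported as missing rather than
  computed on a degenerate table.

The reference study's printed ρ = −0.011 and p-values are not reproducible —
its raw per-variant scores were never published — and the package makes no
attempt to emulate them; the statistics layer is validated against oracles
instead.

## Regulatory evidence

A SNP may be annotated in more than one region class (the packaged table
contains one identifier under both mRNA and 3′ UTR), so evidence is merged
per identifier before multi-tool significance is assessed: splicing-element
calls (non-none wins), UTR motif sets (union), FastSNP risk (maximum),
effect text (concatenated). A SNP is multi-tool significant when it both
disrupts a splicing element and carries at least one UTR motif; on the
packaged table this flags seven SNPs — the six rows highlighted in the
source plus the duplicate-row SNP whose evidence only combines across
region classes. FastSNP risk ≥ 3 (of the 0–5 no/very-low/low/medium/high/
very-high scale) defines "high risk": the published hits used 3–4, and 5
(very high) is included because the scale is ordered. Unknown UTR motif
labels map to an `other` class instead of erroring, since the motif
vocabulary evolves.

## PTM sites and conservation

The registry keys sites by (modification, position); the same position may
carry different modifications, but duplicate (modification, position) pairs
are rejected. Residue identity is stored as printed by the source predictor
and deliberately **not** validated against modification chemistry (source
tables occasionally disagree with their surrounding text about the residue
at a position, e.g. a phosphosite printed as threonine where the text says
tyrosine; the table is authoritative for the fixture). Sumoylation site
type (consensus type I vs non-consensus type II) is recorded when known;
the packaged sites carry `none` because per-site attribution was never
published. Predictor score cutoffs (e.g. GPS 4.16, SUMOsp 2.64) are metadata
of the upstream predictions, not thresholds this package applies.

Alignments are read with Biopython (FASTA and Clustal dialects, format
sniffed from the first line; gap characters normalized to `-`).
`map_position_to_column` maps a 1-based ungapped reference position to its
1-based alignment column and is a tested bijection with its inverse. Column
conservation uses the ClustalW consensus convention: `identical` when all
residues agree, `gap` when any sequence has a gap (a deletion gap in one
ortholog disqualifies the site), otherwise `strong`/`weak` when all residues
fall in a single standard ClustalW strong/weak group, else `none`. The
groups are stored as data constants.

## Synthetic data

The generator's defaults are the study conditions: cohorts of 168 nsSNPs,
marginal deleterious rates (0.25, 0.696, 0.678), validated fractions among
tool-deleterious variants 26/42 (SIFT) and 79/117 (PolyPhen). Per-variant
indicators are drawn at those marginals, then each raw score is drawn
uniformly within the band its indicator implies (SIFT deleterious →
[0, 0.05); PolyPhen deleterious → [1.5, 3.5); I-Mutant deleterious →
[−3, −0.5)), so categorization round-trips to the intended call exactly.
Only the band matters downstream; no attempt is made to mimic the tools'
real score densities within bands.

Two dependence models are provided. `independent` draws each tool's
indicator separately. `latent_shared` mixes a shared uniform into each
tool's threshold draw with probability equal to the strength parameter (a
comonotone copula): marginals are preserved exactly for any strength, and
agreement between tools rises with strength. At strength 1 the three calls
are comonotone — identical whenever the marginals are equal (the form in
which the property is tested); with unequal marginals they are nested
rather than identical, which is the price of preserving marginals.

Validation labels are a single per-variant status, so they cannot satisfy
every tool's conditional validated fraction simultaneously (the
tool-deleterious sets overlap); `generate_validation_labels` therefore
calibrates to one explicit reference tool (default SIFT) and labels that
tool's deleterious variants validated with the configured conditional
probability.

`generate_exact_margin_cohort` assigns exactly the requested number of
deleterious calls per tool by independent seeded shuffling — the
deterministic fixture used wherever published margins must be hit exactly.
One global seed drives all generators through spawned substreams.
`simulate_rank_count_means` is a vectorized batch variant of
generate-then-rank (same Bernoulli draw, same vote-count rule, batched in
numpy); its agreement with the object path is itself a test. The headline
simulation (10,000 cohorts of 168) runs in about a second.

What the synthetic cohorts do **not** emulate: linkage between variants,
realistic within-band score distributions, per-tool missingness patterns,
and any correlation between deleteriousness and protein position. Tests
passing on synthetic cohorts therefore validate the pipeline's arithmetic
and invariants, not predictor accuracy on real variants.

## Numerical and degenerate-input choices

- Percentages use decimal arithmetic; all reported percentages are
  recomputed from counts at emit time, never cached.
- TSV exchange uses `.` for missing, distinct from zero through round trips;
  floats serialize via `repr` so write-then-read is the identity.
- The variant-table reader rejects duplicate identifiers within one file;
  the regulatory table permits them (same SNP, different region class) and
  resolves them by merging.
- Empty cohorts, all-missing call triples, zero contingency margins,
  constant correlation inputs and out-of-domain scores raise typed errors
  rather than returning sentinel values.

## Known limitations

- The consensus rank treats the three predictors symmetrically by default;
  if one tool is known to be better calibrated for a protein family, the
  weighted scheme must be configured explicitly.
- Validation labelling is calibrated per reference tool, so simulated
  cross-tool validated fractions other than the calibrating tool's are
  emergent, not controlled.
- Conservation symbols follow ClustalW groups; other consensus conventions
  (e.g. Gonnet-matrix thresholds) are not implemented.
- Protein-level coordinates only; genomic/VCF coordinates and raw predictor
  output dialects are out of scope.
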