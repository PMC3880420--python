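# Methods

`gardensage` reimplements, as a tested pipeline, the analysis used to
profile gene expression of the fungal cultivar *Leucocoprinus
gongylophorus* across the top, middle and bottom sections of an
*Acromyrmex echinatior* leaf-cutting-ant fungus garden with DeepSAGE
tag sequencing. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Tag model and extraction

Each mRNA contributes one mono-tag: the 4-bp anchoring-enzyme site
`CATG` followed by a 17-bp gene-specific sequence. Reads are expected to
begin with the anchor at position 0 (the libraries are sequenced from
the anchoring site); a scan window for a displaced anchor exists but is
off by default. The 3-bp library key sits in the downstream adaptor at a
configurable offset after the tag (default 0). Matching of anchor and
key is exact string equality — sequencing-error control is delegated to
the downstream frequency filters, not to fuzzy matching. Reads failing a
check are returned as typed rejections (`too_short`, `bad_anchor`,
`unknown_key`, `ambiguous_tag` for non-ACGT tag bases) and counted;
accepted + rejected always equals the input read count. Tags are stored
as the 17-base form without the shared `CATG`, the convention of
published tag tables; tag ids are assigned by lexicographic order of the
sequence so counting is independent of read order.

## Filtering and normalization

Processing order is fixed:

1. **Low-abundance cut** — drop tags whose summed raw count across *all*
   libraries is ≤ 10 (total 10 removed, 11 kept). The threshold is
   interpreted dataset-wide rather than per library; it is configurable.
2. **CPM normalization** — each library column is scaled to counts per
   million of its total; a zero-total library is a hard error naming the
   library.
3. **Reproducibility filter** — keep tags nonzero in ≥ 3 libraries with
   a grand total ≥ 22. By default this runs on the normalized matrix
   (the filter is described after normalization in the source protocol);
   a flag applies it to raw totals instead, since the original order is
   ambiguous.

Pure-culture libraries, when present in a count table, participate in
both filters and in the normalization denominators but are excluded from
the section tests. Both filters are idempotent and normalization
preserves within-library rank order; the test suite re-checks retained
sets against a brute-force oracle.

## Differential expression

Tests run on normalized (CPM) counts, untransformed — reported group
means are means of normalized tags and no log transform is applied.
For each tag:

- **Group summaries**: arithmetic mean per section with a two-sided
  t-interval, mean ± t₁₋α/2,n₋₁ · sd/√n, lower bound clipped at 0
  (counts cannot be negative).
- **Welch ANOVA** (primary test): heteroscedastic one-way F with weights
  wᵢ = nᵢ/sᵢ², small-sample denominator correction
  1 + 2(k−2)Λ/(k²−1) with Λ = Σ(1−wᵢ/W)²/(nᵢ−1), and
  Welch–Satterthwaite denominator df (k²−1)/(3Λ). Note that for k > 2
  this correction makes Welch's F systematically smaller than the
  classical F even under exactly equal variances; the two agree exactly
  only at k = 2 (the suite asserts both identities rather than a naive
  equivalence).
- **Kruskal–Wallis fallback**: used whenever some section's replicates
  are all zero (Welch's weights are undefined there); a zero-variance
  *nonzero* section also falls back, with a logged note. The H statistic
  is tie-corrected; p comes from the χ² approximation or, on request,
  from exact enumeration of every assignment of the pooled values to
  groups of the observed sizes. The enumeration is capped at 10⁶
  assignments (the 5/4/5 garden design needs 252,252), which extends
  beyond very small totals deliberately: the study's own design is the
  intended use case.
- **Fold change**: ratio of means, bottom/top. The point estimate is
  data-only (invariant to simulation settings). The interval is a
  percentile interval over simulated ratios: nonparametric bootstrap
  resampling replicates with replacement within each section (default,
  n_boot = 10 000), or a normal-theory parametric variant behind a
  flag — the original publication cites a simulation method without
  details, so the scheme here is this package's documented choice. A
  zero top mean yields an NA fold (rendered `NA`). Per-tag random
  streams are derived from (seed, tag id), so results are independent
  of tag order.

No multiple-testing correction is applied by default (raw P values are
reported, matching the source tables); Benjamini–Hochberg q-values are
available behind a flag. P values are stored at full precision;
rendering to 2 significant digits (scientific below 0.01) happens only
in the report view.

### Known calibration limits

The percentile bootstrap for a ratio of means at n = 5 per group
undercovers: measured coverage of the nominal 95% interval is ≈ 0.88
(0.90 for the parametric variant) under negative-binomial replicates
with dispersion 0.2. This is the familiar small-sample behaviour of
percentile intervals, not an implementation defect; the acceptance suite
reports the measured coverage honestly. Similarly, with dispersion 0.3
and n = 5 the ratio-of-means estimator has a coefficient of variation
near 35%, so a single dataset's fold estimate lands within 25% of an
8-fold truth only about half the time, and Welch power at p < 0.05 for
that effect is ≈ 0.75. These are properties of the study-scale design
itself and are reported as measured.

## Reproducing published per-tag statistics

The replicate-level count table behind the published per-tag statistics
is not redistributable with this package, but the printed per-section
summaries (mean, 95% t-CI, n = 5/4/5) fully determine both Welch's
ANOVA and the ratio-of-means fold. Module `published` therefore ships
the printed summary tables as TSV and builds **synthetic** replicate
vectors matching each printed (mean, upper CI bound, n) exactly —
n−1 values at m − s/√n and one at m + s(n−1)/√n, which has exactly the
target sample mean and sd and is nonnegative for every printed row. The
upper CI margin is used to invert the interval because printed lower
bounds are clipped at zero. Recomputed Welch P values agree with the
printed ones to within a few percent — the printed means and CI bounds
are integer-rounded, and that input rounding propagates — while section
means and folds reproduce at printed precision. Means matching is by
construction and is asserted only as a consistency check. The
housekeeping-gene validation (P = 0.80 / 1.0 / 0.12) prints means but no
dispersion, so it cannot be recomputed from available data;
`published.housekeeping_replicates` raises rather than fabricating
variances, and the corresponding acceptance check fails with an
explanatory message.

## Annotation

Tags are re-anchored to 21 bases and searched exactly against both
strands of the EST contigs (cDNA contigs have arbitrary orientation).
Each occurrence is extended by up to 50 bases per side; a fragment is
*complete* when both flanks exist (≥ 121 bp), and only complete
fragments are exported as BLASTX queries by default — running BLASTX
itself is out of scope, the pipeline exports the query FASTA. Fragments
are reported in forward-contig orientation with a strand flag;
coordinates are 0-based half-open. Multi-mapping tags are reported in
full and flagged ambiguous rather than collapsed.

## Peptide pattern recognition

The PPR stage is a reconstruction of the published alignment-free
approach (the original program is not distributed): for each labelled
protein family, every overlapping 5-mer over the standard 20-letter
alphabet is scored by member coverage and by enrichment (coverage in
class ÷ coverage outside class); peptides with coverage ≥ 0.5 and
enrichment ≥ 5 (both configurable; these defaults are this package's
stated choices) form the characteristic set. Queries are assigned to the
class with the strict majority of matched 5-mers; ties list all
candidate classes and are returned unclassified, since subgroup
ambiguity is meaningful. Windows containing `X` or gaps are skipped.

With the generator's one embedded copy per motif per member, an
embedded motif survives intact with probability (1 − rate)⁵, i.e. 0.59
at mutation rate 0.1 — right at the 0.5 coverage threshold — so
per-motif recovery from 20 members is ≈ 0.85 in expectation. Held-out
classification accuracy is far more robust (≥ 0.9) because a query only
needs *some* matched peptides to vote correctly.

## Synthetic-data generator

The generator emulates the study design: three sections (top, middle,
bottom) with 5/4/5 replicate libraries, each with a distinct 3-bp key;
replicate counts are negative-binomial with variance μ + φμ²
(φ = dispersion; φ = 0 degenerates to Poisson), the standard
overdispersed choice since the source states no count model. Designed
effect classes: flat housekeeping tags; 8-fold bottom-upregulated tags
at baseline 100 and dispersion 0.3 (the study-condition defaults used
throughout the calibration suites); one tag with fold 0 in the top
section (exercising the rank-test fallback); and low-level noise tags.
Library depths are emergent sums of tag counts — the source does not
report depths, so none are imposed. Contigs plant each tag behind a
`CATG` on a recorded strand with a deterministic fraction receiving full
50-base flanks; reads are CATG + tag + adaptor-with-key, shuffled by
seed. Protein families embed disjoint random 5-mer motifs in a uniform
amino-acid background (a neutral background for motif-detection tests)
with per-residue point mutations on the embedded copies.

Not emulated: base-call errors beyond optional uniform substitution,
ditag artifacts (the protocol omitted ditag formation), pure-culture
biology (those libraries are just extra columns), compositional or
batch effects, and any correlation structure between tags. Passing
round-trip and power suites therefore demonstrates correctness of the
bookkeeping and calibration of the statistics under the assumed noise
model — not robustness to real-library artifacts.

All generators are pure functions of (config, seed); acceptance-scale
problem sizes (60-tag round-trip matrices, 1000-simulation coverage
runs, 200-simulation power runs, 40-member protein families) are the
package's chosen defaults for routine verification.
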