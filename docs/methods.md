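# Methods

This note documents the models, parameter choices and numerical rules
behind `lncscape`, and what the synthetic cohorts do and do not emulate.

## Sample Set Enrichment Analysis

SSEA asks, per transcript, whether a labelled sample set concentrates at
one end of the expression-ranked sample list — a two-group
differential-expression test that makes no distributional assumption
about the expression values.

**Statistic.** Samples are sorted by expression, descending. Walking the
ranking, a member of the tested set adds \(|x|^p / \sum_{members}|x|^p\)
and a non-member subtracts \(1/(N-k)\) (k = set size). The enrichment
score (ES) is the signed running-sum value of maximal absolute
deviation, bounded in \([-1, 1]\), reaching \(\pm1\) exactly at perfect
separation. The weight exponent defaults to \(p = 1\) (the weighted
scheme); \(p = 0\) recovers the classic unweighted KS walk.

**Normalization.** Count matrices are scaled to counts per million
per sample before testing. The method tag is recorded; the choice is
pluggable because any monotone per-sample scaling leaves each
transcript's sample ranking unchanged except through the library-size
correction itself.

**Ties.** Count data tie frequently. Ranking ties are broken by a seeded
random key drawn once per transcript in canonical (sorted sample id)
order — deterministic by seed, unbiased, and invariant to the column
order of the input matrix. A transcript whose set members are all zero
under \(p>0\) falls back to equal member weights.

**Permutation null.** "Label shuffling" is implemented as uniform
re-draws of a same-size sample set. One membership matrix (default
1,000 permutations) is shared by all transcripts so the pooled FDR
compares like with like. The nominal p-value is sign-matched:
\(p = (1 + \#\{\text{same-sign null}, |null| \ge |ES|\}) /
(1 + \#\{\text{same-sign null}\})\), never zero. NES divides ES by the
mean magnitude of same-sign null ES. FDR Q follows the GSEA recipe: for
a positive NES*, the fraction of pooled positive null NES at or above
NES* divided by the fraction of observed positive NES at or above NES*,
clipped to [0, 1], mirrored for the negative side, and monotonized so
each transcript takes the minimum raw q over itself and all
weaker-|NES| transcripts of the same sign.

**Null-support guard.** At desk-scale cohorts (N ≈ 100–200) with the
tested set near half the cohort, the weighted null is strongly
right-skewed: a transcript whose expression concentrates in a few
samples can have almost no negative null ES, and dividing by the mean of
1–3 stray values produces absurd NES. `SseaParams.min_null_support`
(default 10) declares the NES (and q) missing below that count; the
nominal p keeps the documented "no same-sign nulls → p = 1, warning"
rule. Two practical consequences, verified empirically: down-regulation
has limited power in this regime, and the landscape therefore intersects
**up**-regulated sets (as the biology of ER-driven candidates requires
anyway); and an FDR threshold of 1e-5 — appropriate when ~58k
transcripts × 1,000 permutations are pooled — is below the resolution of
a desk-scale null, so the planted end-to-end runs operate at q < 0.05
while 1e-5 remains the pipeline default for full-size data.

## Expression metrics

* **Percentile metric** — nearest-rank: the value at 1-based index
  \(\lceil q \cdot n\rceil\) of the ascending sort, i.e. the measured
  value of an actual sample, not an interpolation. Default summary
  quantile 0.95; the DE pre-filter quantile is 0.975.
* **Expression filter** — keep a transcript iff its value at the filter
  quantile is **at least** 1 FPKM (inclusive).
* **FPKM ↔ fragments** — fragments = FPKM × (length/1000) ×
  (map mass/10⁶); exact inverses. For counts matrices the map mass is
  the column sum.
* **log2 fold over reference** — per transcript, log2 of
  (value + pseudocount) over (median of reference samples +
  pseudocount). Pseudocount 0.1 FPKM by default: FPKM matrices contain
  exact zeros; the value is configurable and recorded.

## Clustering and cluster labels

Hierarchical clustering uses dissimilarity \(d = 1 - r\) (Pearson) with
the Ward update applied through the Lance–Williams recurrence **to the
supplied dissimilarities as-is** — the historical R `hclust` "ward"
(ward.D) behaviour, chosen for fidelity to common practice on
correlation distances over metric purity (verified in the tests against
R's `hclust(method="ward.D")`). Minimum-distance ties break at the
lowest index pair; constant rows, whose correlation is undefined, get
distance 1 to everything. Heights are non-decreasing (Ward is
reducible).

The three lncRNA cluster labels are rule-based, standing in for what is
usually a visual call: a cluster is **Downregulated** when its median
tumor log2FC is negative; **Luminal** when its LumA/LumB median exceeds
the non-luminal tumor median by more than 1.0 log2 unit (our declared
margin); otherwise **Upregulated**. k = 3 is the default and
configurable.

## Candidates, binding and induction

Up-regulated DE sets from the two contrasts are intersected; candidates
are ranked by the 95th-percentile FPKM (ties broken by transcript id),
annotated with ER promoter binding and an estrogen-induction category:
**high** above 2.5-fold, **low** above 1.5-fold, strict inequalities.
Promoter windows anchor at unique TSS positions (transcripts sharing a
TSS collapse into one window), symmetric ±5 kb by default with an
upstream-only mode (5 kb) also exposed, clamped at coordinate 0. All
intervals are 0-based half-open; two intervals overlap iff
max(starts) < min(ends). Overlap is computed by a per-chromosome sweep
over sorted starts and is test-gated against an all-pairs oracle.

## Guilt-by-association

Spearman rho is Pearson correlation on mid-ranks (average ranks at
ties), computed for every protein-coding gene against the target over
the selected samples (e.g. ER-positive tumors), target excluded. The top
150 positive and negative genes form directed signatures. Overlap with a
concept gene set is tested one-sided (enrichment) via the
hypergeometric upper tail; the odds ratio gets a Haldane–Anscombe +0.5
on all cells iff any cell is zero, flagged in the output. The Fisher
universe is the set of genes measured in the matrix (concept sets are
truncated to it) — the universe used by the original analyses is not
derivable, so it is explicit and configurable here. Concept studies may
offer top 1/5/10% up/down variants; the variant with the greatest odds
ratio wins (ties: smaller p, then smaller percent). Two network presets
are shipped rather than reconciled, because both operating points are in
circulation: *methods* (OR > 6 positive / > 4 negative, p < 1e-6) and
*figure* (OR > 6, p < 1e-4); thresholds are strict. Preranked GSEA
reuses the same running-sum and null machinery with gene-membership
permutation (sample permutation is undefined for a preranked list).

## Survival

Samples are stratified by the target's FPKM: **high** above 10,
**low** below 1, both strict; the middle band is excluded from the test.
The Kaplan–Meier estimator uses the standard convention that subjects
censored at an event time remain at risk for that event; the two-group
log-rank statistic is \((\sum(O-E))^2/\sum V\) with the hypergeometric
variance and aggregate handling of ties, referred to \(\chi^2_1\). Both
are cross-checked against lifelines in the tests.

## Synthetic cohorts

The generator emulates a receptor-annotated breast RNA-seq cohort at
desk scale. Counts are gamma–Poisson (negative binomial) with
per-transcript dispersion (default 0.2, variance \(m + 0.2m^2\));
library sizes are log-uniform over (5×10⁵, 2×10⁶) and enter the mean as
\(lib_s/\text{median}(lib)\), exercising the normalization; baselines
are log-normal (σ = 1.2), rescaled so expected totals match the middle
of the library range, with 20% of lncRNAs damped ×10⁻³ to exercise the
expression filter. Defaults: 150 tumors + 50 normals, 1,000 transcripts
(half lncRNA), ER-positive fraction 0.75 with ER status correlated to
the luminal subtypes, PAM50 proportions LumA .35 / LumB .20 / Her2 .15 /
Basal .25 / Normal-like .05, fold change 4.

Planted structure: per-subtype marker blocks (25 transcripts each);
cancer-DE lncRNAs in three patterns — up in all tumors, down in all
tumors, up in luminal tumors only (fractions 0.4/0.3/0.3); ER-DE
lncRNAs either ER-restricted (modelled as depleted in ER-negative
tumors, so they are ER-specific rather than cancer-wide) or
basal-pattern; and an overlap subset carrying both the cancer and ER
effects. The first overlap member is the designated best candidate: a
near-silent baseline (~0.3 FPKM) and high expression across ER-positive
tumors, with the fold sized so its 95th-percentile expression tops every
other DE-up lncRNA. This bimodal, ER-restricted profile mirrors a top
ER-driven lncRNA and gives the 10/1 FPKM survival strata real
membership. The candidate also receives a promoter peak and a planted
3-fold induction; induction tables revert three quarters of the
induction under tamoxifen, with multiplicative log-normal noise.
Concept libraries draw each concept with an exact planted overlap
against the designated correlated set; ChIP decoy peaks sit ≥ 100 kb
from any TSS; survival times are exponential with the planted hazard
ratio on the high-expression group and independent uniform censoring
over (0, 120].

**What passing tests do not show.** The generator has no batch effects,
no isoform structure, no GC/length bias beyond the explicit length
factor, no correlated gene modules beyond the planted blocks, and
subtype identity lives entirely in the marker blocks — so clustering
recovery is evidence that the algorithm recovers planted block
structure, not that real cohorts separate this cleanly. Planted DE
recovery rates are likewise upper bounds relative to messy tissue data.

## Problem sizes and reproducibility

The bundled checks use: a 1,000 × 100 null cohort at 1,000 permutations
for calibration; 100 planted 4-fold transcripts among 1,000 at n = 200
for recovery; a 120-tumor 3-subtype cohort for clustering; 10 full
pipeline runs (200 permutations each) for candidate ranking; 20
concept-library draws in a 20,000-gene universe; and 100 + 400 survival
replicates at 400 and 120 samples. These sizes make the whole validation
run in about a minute while keeping every Monte-Carlo margin wide.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline fans a global seed out to fixed
per-stage seeds recorded in `manifest.json`, and repeated runs of the
same config are byte-identical (no timestamps in outputs, deterministic
float formatting via pandas).

## Known limitations

* Down-regulation detection is under-powered at desk scale (right-skewed
  weighted null, above); use the unweighted statistic or larger cohorts
  when the negative side matters.
* Only two-group contrasts; no covariate adjustment or multi-class
  testing, and survival is KM/log-rank only (no Cox model).
* The cluster labeller assumes the three planted archetypes; cohorts
  with different structure need a custom rule or manual labels.
* The Fisher universe choice materially affects odds ratios; results
  should always be read together with the recorded universe size.
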