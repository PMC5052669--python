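# lncscape

Analysis toolkit for building a **long noncoding RNA (lncRNA) expression
landscape** of a tumor cohort: which lncRNAs distinguish cancer from
normal tissue, which track estrogen-receptor (ER) status, how they
organize into subtype clusters, which candidates are directly
ER-regulated (promoter binding plus estrogen induction), what their most
correlated genes say about clinical behavior, and whether their
expression stratifies survival.

It is written for computational biologists working with bulk RNA-seq
cohorts (counts or FPKM) annotated with tumor/normal status, receptor
immunohistochemistry and PAM50 subtype labels, and it ships a synthetic
cohort generator with planted ground truth so every stage can be
validated without any external download.

## The statistics at the core

**Sample Set Enrichment Analysis (SSEA)** is a nonparametric
differential-expression test. For a transcript with expression
\(x_1, \dots, x_N\) and a labelled sample set \(S\) (e.g. the tumors),
samples are ranked by expression (descending) and a weighted
Kolmogorov–Smirnov running sum is formed: a member at rank *i*
contributes \(+|x_{(i)}|^p / \sum_{j \in S} |x_j|^p\), a non-member
\(-1/(N-|S|)\) (weight \(p = 1\)). The **enrichment score** ES is the
running-sum value of maximal absolute deviation; ES = +1 iff the set
occupies the top ranks exactly. Significance comes from random
re-drawings of the sample set (1,000 by default): a sign-matched nominal
permutation p-value, a **normalized enrichment score**
NES = ES / mean |same-sign null ES|, and **FDR Q values** that compare
each observed NES against the null NES of all transcripts pooled,
separately per sign.

Around the test, the toolkit implements the landscape workflow:
nearest-rank percentile expression metrics (the "value of the 95th
percentile sample") and an FPKM expression filter; log2 fold change over
the median of reference (normal) samples; hierarchical clustering with
Pearson-correlation distance and Ward linkage; intersection of
up-regulated DE sets and candidate prioritization by tissue expression,
ER promoter binding (BED peak vs TSS-window overlap, 0-based half-open)
and estrogen-induction category (> 1.5-fold "low", > 2.5-fold "high");
Spearman-correlation signatures (top 150 positive/negative) tested
against concept gene sets with a one-sided Fisher's exact test and
exported as an odds-ratio network; weighted preranked GSEA; and
Kaplan–Meier survival with a log-rank test between > 10 FPKM and
< 1 FPKM expression groups.

## Worked example

```python
import lncscape as L

# a synthetic cohort: 150 tumors + 50 normals, 1,000 transcripts,
# 60 planted cancer-DE lncRNAs, 40 ER-DE lncRNAs, NB dispersion 0.2
cfg = L.CohortConfig(seed=1)
matrix, models, annotations, truth = L.simulate_cohort(cfg)

tumors = L.SampleSet("tumor_vs_normal",
                     annotations.index[annotations.cohort == "tumor"])
res = L.SSEA(matrix, tumors,
             L.SseaParams(n_permutations=1000, seed=2),
             percentile_matrix=matrix.to_fpkm(),
             fdr_cutoff=0.05).fit()
print(res.summary())
```

```
Sample Set Enrichment Analysis
==============================
sample set:        tumor_vs_normal (150 of 200 samples)
transcripts:       1000
permutations:      1000 (seed 2)
weight exponent:   1.0
significant:       57 (FDR<0.05, percentile_0.975 >= 1)
  up in set (+):   54
  down in set (-): 3
```

The 57 significant transcripts at q < 0.05 are dominated by the planted
effects: the cancer-up and luminal-pattern lncRNAs plus the subtype
marker blocks (up in a subset of tumors), with the strongest rows at
ES = 1.0, q = 0. Down-regulation carries less power at this cohort size
(see `docs/methods.md` on the right-skewed weighted null). The same `fit()` interface drives the ER-positive
versus ER-negative contrast on the tumor subset; intersecting the two
up-regulated sets and ranking by the 95th-percentile FPKM, ER binding
and induction reproduces the candidate table — on the planted cohort the
generator's designated best candidate comes out at rank 1.

The whole workflow runs from one config:

```bash
lncscape simulate --outdir cohort --seed 1
lncscape run --config run.yaml     # filter -> SSEA x2 -> clusters ->
                                   # intersection -> candidates ->
                                   # concept network -> survival
lncscape report --run-dir cohort/run
```

Every run writes a `manifest.json` with per-stage seeds and output
checksums; re-running the same config reproduces every file byte for
byte.

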