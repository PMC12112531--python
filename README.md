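# cortiseq

Bulk RNA-seq analysis of the hippocampal transcriptome under prolonged
corticosterone treatment — a reusable, tested re-implementation of the full
downstream pipeline: global expression profiling, negative-binomial
differential testing with batch adjustment, cross-timepoint replicability,
cell-type specificity scoring, transcript-budget accounting, Cluster-3.0-style
hierarchical clustering, and comparison against referential glucocorticoid and
stress gene lists.

The pipeline consumes gene × sample count matrices (e.g. featureCounts
output); read QC, trimming, alignment and feature counting are out of scope.
A first-class synthetic-data module generates count matrices, cell-type
atlases and referential lists with the statistical structure the analysis
assumes, together with ground truth, so every stage can be tested by
parameter recovery.

## The statistics at the core

**Expression tiers.** Expression is measured in counts per million,
CPM<sub>gs</sub> = y<sub>gs</sub> / N<sub>s</sub> × 10⁶, and genes are placed
on their mean CPM into six decade tiers: residual (<0.1), low (0.1–1), lower
medium (1–10), upper medium (10–100), high (100–1000), top (≥1000). Tier
summaries report gene counts and each tier's share of all transcripts.

**Filtering and testing.** Genes are kept when CPM ≥ (min_count / median
library size) × 10⁶ in at least as many samples as the smallest group.
Between-sample normalization is the trimmed mean of M-values (TMM).
Counts are modelled as negative binomial with a common dispersion φ
(Var = μ + φμ²). Two-group comparisons use a conditional exact test on
library-equalized group sums; the pooled comparison (all corticosterone vs
all control samples) fits per-gene NB log-linear models
log μ = offset + β₀ + β_trt·T + β_batch and tests β_trt by likelihood ratio,
absorbing per-timepoint batch shifts. P-values are Benjamini–Hochberg
adjusted.

**Cell-expression specificity.** For a gene and a cell category (immune,
vascular, neurons, …), the score is max(in-category expression) /
max(out-of-category expression) over an atlas of normalized per-cell-type
expression, with zero denominators replaced by 0.0001; the best category is
kept and scores binned as [1,2), [2,3), ≥3.

**Transcript budget.** For each differentially expressed gene,
Δ = mean treated − mean control raw counts; gains (up genes) and losses
(down genes) are summed and expressed as % of the mean control per-sample
total, with a Mann–Whitney U test on per-sample totals.

**Clustering.** Gene profiles are divided by their row maximum (range
[0, 1]), then clustered agglomeratively with complete linkage on
1 − uncentered correlation, Σxy/√(Σx²·Σy²), and written as CDT/GTR files
loadable in Java TreeView.

## Worked example

```python
import cortiseq as cs
from cortiseq.simulate import SimConfig

cfg = SimConfig(n_genes=4000, de_fraction=0.05, nb_dispersion=0.1, seed=7)
cm, truth = cs.simulate_counts(cfg)          # 6 groups x 8 samples
cpm = cs.compute_cpm(cm)
print(cs.tier_summary(cpm).round(2))

filt = cs.filter_by_expression(cm, min_count=10)
sub = cm.counts.loc[filt.kept]
sets = []
for tp in (5, 14, 28):
    cols = cm.metadata.index[cm.metadata["timepoint"] == tp]
    res = cs.nb_exact_test(sub[cols], cm.metadata.loc[cols, "treatment"],
                           pair=("control", "cort"), comparison=f"{tp}d")
    sets.append(cs.significant_set(res))
pooled = cs.nb_glm_batch_test(sub, cm.metadata["treatment"],
                              cm.metadata["timepoint"])
rep = cs.replicable_genes(sets)
r, p = cs.fc_vs_expression_correlation(pooled)
```

Output (seed 7):

```
              n_genes  pct_genes  pct_transcripts
residual          729      20.46             0.00
low               974      27.34             0.04
lower_medium      869      24.39             0.31
upper_medium      505      14.17             1.73
high              306       8.59            10.66
top               180       5.05            87.26
filter: kept 1097, removed 2903, threshold 10.44 CPM
5 d: 50 / 14 d: 45 / 28 d: 52 significant genes (adj p < 0.05)
pooled+batch: 58 significant genes
replicable (>=2 timepoints, same direction): 48 | all three: 34
|log2FC| vs log10 CPM: r = -0.85, p = 2.5e-17
```

A minority of genes carries nearly all transcripts (the top two tiers hold
13.6% of genes but 97.9% of transcripts); the filter threshold is the
min-count formula evaluated at the simulation's median library (~1 M reads,
hence ~10 CPM; at a 30 M study-scale library the same formula gives
0.33 CPM). Most significant genes replicate across treatment durations with
a consistent direction, and the fold-change magnitude falls with expression
level (r < 0) — the planted effect rule |log2FC| = a − b·log10 CPM recovered
from the analysis side.

There is also a small CLI for the batch-style steps:

```bash
cortiseq simulate --config cfg.yaml --out sim/ --seed 3
cortiseq dge --counts sim/counts.tsv --meta sim/metadata.tsv --mode exact --out de.tsv
```

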