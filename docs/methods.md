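# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, and what the synthetic data does and does not
emulate.

## Synthetic count data

`simulate_counts` draws a gene × sample integer matrix emulating a six-group
bulk RNA-seq design (control vs corticosterone at 5, 14 and 28 days of
treatment, 8 samples per group by default):

- **Mean expression.** Each gene's true mean CPM is drawn from a mixture
  over the six expression tiers (weights configurable; defaults
  0.455/0.2503/0.15/0.084/0.0543/0.0064 from residual to top), log-uniform
  within a tier. Tier supports are one decade each, with residual extending
  down to 10⁻³ CPM and top up to 10⁴ CPM. The drawn vector is renormalized
  to sum to 10⁶ so that empirical CPM estimates true CPM directly; the
  default weights put the expected raw sum near 10⁶ at the default 20,000
  genes, so the renormalization is mild and tier proportions stay within
  multinomial sampling error of the weights.
- **Counting noise.** Counts are negative binomial with mean
  lib_s · CPM_g/10⁶ · 2^(effects) and a single dispersion φ
  (Var = μ + φμ², default φ = 0.1), sampled as a gamma–Poisson mixture;
  φ < 10⁻⁸ degrades to Poisson. Library sizes are lognormal with desk-scale
  mean 10⁶ reads (CV 0.3). The filter-threshold formula scales with the
  median library, so analyses behave as they would at the study scale of
  30 M reads.
- **Treatment effects.** A fraction of genes (default 2%) receives
  |log2FC| = a − b·log10(CPM), truncated at 0 (defaults a = 2, b = 0.5),
  with random sign, applied to all corticosterone samples at every
  timepoint (persistent effects). The rule makes effect size shrink with
  expression level; the linear-in-log form is a modeling choice, not a
  claim about the real generative mechanism.
- **Batch effects.** Per timepoint, a random 5% of genes receive an
  additive N(0, sd²) log2 offset applied to *all* samples of that timepoint,
  mirroring systematic differences between sacrifice batches without
  modeling their cause. Because the offsets hit both treatment arms, they
  do not bias the pooled control-vs-treated contrast; they inflate the
  pooled exact test's false-positive rate through a variance mismatch
  (unequal per-batch scale factors shrink the effective sample size of the
  pooled group sums), which the per-gene batch covariate in the GLM absorbs.
- **Marker modules.** Module genes share a per-sample lognormal latent
  factor (loading = sd of the shared log-normal deviate), producing the
  correlated expression expected of functionally coupled genes.

Not emulated: gene length and GC biases, count correlations beyond the
planted modules, sample outliers, tagwise dispersion, and any cell-level
structure. Passing tests therefore demonstrate correctness of the analysis
machinery under the stated NB model, not robustness to every artifact of
real libraries.

`simulate_atlas` plants category-specific genes whose in-category maximum is
exactly `specificity_level` times their out-of-category maximum on a
near-uniform background. `simulate_reference_list` draws per-member up-report
counts k ~ Binomial(n, p) with n uniform in a configurable range and assigns
evidence tiers (core: same-direction reports ≥ 4; extended: exactly 3).

## Duplicate-symbol merging

Symbols attached to several stable gene ids are merged (counts summed per
sample) only when every copy has the same biotype; copies of differing
biotype (e.g. a protein-coding gene sharing its symbol with a transcribed
processed pseudogene) stay separate. The merged entry keeps the
lexicographically smallest id; the full id list goes to the merge report.
Biotype equality is exact string equality — composite biotypes such as TEC
merge only with themselves. A gene is flagged "predicted" when its
annotation description contains "predicted gene" (case-insensitive).

## Tiers, transcript shares and marker QC

Mean expression is the arithmetic mean of per-sample CPM across all samples.
Tier intervals are left-closed/right-open ([0.1, 1), …, [1000, ∞)): the
boundary conventions are a consistent-partition choice, since verbal
descriptions like ">1000" leave membership of the endpoints open. A tier's
transcript share is the summed mean CPM of its genes over the summed mean
CPM of all detected genes (CPM > 0 in ≥ 1 sample) — a mean-CPM convention;
with unequal library sizes this differs slightly from a raw-count share.

Marker QC computes all pairwise Pearson correlations within each marker set
across samples. Classification thresholds (high: every pair r ≥ 0.6;
none: every pair |r| < 0.4 or p > 0.05; loose: in between) are configurable
defaults, since observed correlations, not cutoffs, are what the underlying
validation logic reports.

## Filtering, TMM, dispersion

The CPM cut-off is min_count / median(library) × 10⁶ and a gene must reach
it in at least n_min samples, n_min = smallest group size, boundary
inclusive. TMM follows the published defaults: reference sample = upper
quartile closest to the mean upper quartile; per sample, log2 ratios M and
abundances A over genes positive in both sample and reference; double
rank-trimming (30% per tail on M, 5% on A); inverse-asymptotic-variance
weights (N−y)/(Ny) summed over the pair; factors rescaled to geometric
mean 1.

The common dispersion is a method-of-moments ratio of sums: counts are
scaled to the geometric-mean effective library, and
φ̂ = Σ (n_j−1)(v_gj − m_gj) / Σ (n_j−1) m_gj² over genes g and groups j,
floored at 10⁻⁶. The estimator is dominated by well-measured high-count
genes and recovers φ within a few percent under the generator's model;
library-size estimation error adds a small positive bias of order
(mean lib ratio − 1)/(φ·μ), negligible for filtered genes.

## NB exact test

Counts are rescaled to the geometric mean of the TMM-effective library
sizes and rounded half-to-even. With common dispersion φ, the sum of n iid
NB(μ, φ) is NB(nμ, φ/n); conditional on the two-group total s, the
two-sided p-value is the sum of the probabilities of all splits no more
probable than the observed one (with a 1+10⁻¹² relative tolerance for the
equality comparison). This is the standard conditional construction; the
quantile-adjustment used by edgeR's implementation is *not* replicated
bit-for-bit — equivalence is asserted statistically (type-I error within
[0.03, 0.07] on null simulations, power on planted effects), never against
edgeR outputs. log2 fold changes use a prior count of 0.125 per group to
avoid infinities; all-zero genes report p = 1, logFC = 0 rather than an
error. The reported expression covariate is log10 of mean CPM with the same
prior, keeping it finite.

## Batch-adjusted pooled test

Per gene, log μ = offset + β₀ + β_trt T + Σ β_b batch_b with offset = log
effective library size, fitted by iteratively reweighted least squares
vectorized across genes (working weight μ/(1+φμ), convergence at max |Δβ| <
10⁻⁸, linear predictor clipped to ±50, ridge 10⁻¹⁰ on the normal
equations). The treatment coefficient is tested by a 1-df likelihood-ratio
chi-square against the reduced model. Designs where treatment is in the
column span of batch (rank test) are rejected as aliased. The fit matches
statsmodels' NB GLM with fixed alpha to ~10⁻⁶ in p on test instances. Only
a common dispersion is supported — sufficient here; φ is injectable so
simulations can use the true value.

## Multiple testing and significance

Benjamini–Hochberg step-up FDR (via statsmodels), significance at adjusted
p < 0.05 throughout. BH is order-preserving but *not* idempotent on its own
output in general (re-adjusting multiplies by n/rank again); constant
vectors are fixed points, and the tests assert exactly that.

## Replicability

A gene is replicable when significant at ≥ 2 treatment durations with the
same direction at every *significant* duration (non-significant timepoints
are ignored). Tiers: significant in all three vs exactly two. Venn regions
are exclusive membership-pattern counts, so they sum to the union size.
The |log2FC|-vs-expression relationship is the Pearson correlation between
|log2FC| and log10 mean CPM over significant genes; at least 3 significant
genes and nonzero variance are required.

## Cell-expression specificity

Score = max(in-category) / max(out-of-category), zero denominators replaced
by 0.0001. The category map must cover every atlas cell type, removing any
ambiguity about unmapped cell types. The score is computed for every
category and the best kept; exact ties are broken by category order in the
map and flagged. Bins [1,2), [2,3), [3,∞) follow the conventional "1.99 /
2.99" phrasing; a best score below 1 is impossible with a total map and is
asserted as such. Genes absent from the atlas (after optional synonym
lookup) are ND records, counted in the ND fraction rather than raised.

## Transcript budget

Computed on raw counts, not CPM: per DE gene Δ = mean treated − mean
control count; gains sum Δ over up-genes, losses sum |Δ| over down-genes,
percentages are relative to the mean control per-sample total. Group-size
imbalance is permitted. The Mann–Whitney U statistic is min(U₁, U₂) from
midranks; the exact two-sided p doubles the lower tail of the U null
distribution (DP over rank arrangements) when both samples have ≤ 12
observations and no ties; otherwise a normal approximation with midrank tie
correction and 0.5 continuity correction is used (degenerate all-tied data
give p = 1). The exact-enumeration route makes the test variant auditable.

## Clustering

Gene rows are divided by their maximum (all-zero rows flagged and left at
zero — they carry no pattern and must be dropped before clustering, which
rejects them by name). Similarity is the uncentered correlation
Σxy/√(Σx²Σy²) with equal weights; distance 1 − similarity; complete
linkage. Merge order is deterministic: among equally similar pairs, the one
whose clusters contain the smallest original row indices merges first, and
the child with the smaller minimum leaf index is written first. Leaf order
is the plain left-first traversal (no optimal leaf ordering). CDT files
carry GID/ORF/NAME/GWEIGHT columns and an EWEIGHT row, rows in leaf order;
GTR files one `NODEkX child child similarity` line per merge; values are
written at full precision so read-back is exact.

The per-gene "join similarity" used in node summaries is the similarity of
the first ancestor whose other branch contains another gene of the queried
subset — under complete linkage the highest-similarity node connecting the
gene within the subset. A subset singleton falls back to the gene's first
merge with anything. This is one defensible construction of a per-gene
cluster-cohesion figure; the summary procedure behind such figures is
generally underdocumented in clustering software.

## Referential comparison

Reference lists are flat tables (symbol, n_up, n_down, tier, list); synonym
maps are flat old→current tables, validated against chains and conflicting
entries, and applied idempotently (unknown symbols pass through but are
listed as unresolved). Direction preference: stress rule — a direction wins
with ≥ 75% of reports (boundary inclusive); glucocorticoid rule — a
direction wins when reported ≥ 3× more often than the other. Overlap
reports per replicability tier give member counts, percentage of the tier
(one decimal) and consistency against the preferential labels.

## Problem sizes and test conditions

Simulation-based tests run at desk scale: 10⁶-read libraries, 400–5,000
genes, 8 samples per group. Calibration of both NB tests uses 5,000-gene
null simulations (8 vs 8 per group, φ = 0.1) with tier weights
(0, 0, 0.2, 0.5, 0.3, 0), i.e. genes between 1 and 1000 CPM, so the
filtered set spans the count range the statistical analysis operates on.
Effect-rule recovery uses 50 replicates of 1,500-gene experiments; budget
recovery uses 2-fold-or-larger effects at ≥ 50 CPM where NB sampling error
permits a 10% aggregate tolerance. Clustering oracle equivalence covers 100
random 8-gene instances against an O(n³) re-agglomerator.

## Known limitations

- The NB stand-ins are calibrated against their own model, not validated
  against edgeR outputs; tagwise/trended dispersion and quasi-likelihood
  tests are not implemented.
- The mean-CPM transcript-share convention differs from a raw-count share
  when libraries are unequal.
- Specificity synonym handling requires a supplied map; no live database
  lookups anywhere.
- Figures (tier bar charts, Venn diagrams, heat maps) are not rendered;
  every stage returns tables meant for downstream plotting.
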