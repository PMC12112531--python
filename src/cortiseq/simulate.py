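"""Synthetic bulk RNA-seq data with the statistical structure the pipeline
assumes, plus ground truth for parameter-recovery tests.

The generator emulates a six-group hippocampal design (control vs
corticosterone at three treatment durations, 8 samples per group): per-gene
mean expression drawn from a mixture over six CPM tiers spanning five orders
of magnitude, negative-binomial counting noise with a common dispersion
(var = mu + phi * mu^2), planted treatment effects whose |log2 fold change|
shrinks linearly with log10 mean CPM, per-timepoint batch offsets hitting a
random subset of genes, and marker modules whose genes share a per-sample
lognormal latent factor (producing the correlated expression used in QC).

Library sizes are lognormal around a desk-scale default of 1e6 reads; the
expression-filter threshold formula scales with the median library size, so
analyses behave the same as at the study's 30 M depth.

Also provided: planted cell-type atlases for specificity scoring and
referential gene lists with binomial up/down report tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CountMatrix

__all__ = [
    "GroupSpec",
    "MarkerModule",
    "SimConfig",
    "SimTruth",
    "default_config",
    "simulate_counts",
    "simulate_atlas",
    "simulate_reference_list",
    "write_simulation",
]

_TIER_LOG10_BOUNDS = (
    (-3.0, -1.0),  # residual: 0.001–0.1 CPM
    (-1.0, 0.0),  # low
    (0.0, 1.0),  # lower medium
    (1.0, 2.0),  # upper medium
    (2.0, 3.0),  # high
    (3.0, 4.0),  # top: 1000–10000 CPM
)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    treatment: str  # "control" or "cort"
    timepoint: int  # days of treatment: 5, 14 or 28
    n_samples: int = 8


@dataclass(frozen=True)
class MarkerModule:
    """Genes sharing a per-sample lognormal latent factor."""

    label: str
    n_genes: int
    loading: float  # sd of the shared log-normal factor (natural-log scale)


@dataclass
class SimConfig:
    """Generative settings for :func:`simulate_counts`.

    ``tier_weights`` is the mixture over the six expression tiers (residual …
    top) from which each gene's true mean CPM is drawn (log-uniform within
    the tier).  ``de_effect_rule = (a, b)`` plants |log2FC| = a - b*log10(CPM)
    truncated at zero, so effects shrink with expression level.
    ``batch_shift_sd`` is the sd of an additive log2 offset applied, per
    timepoint, to a random ``batch_gene_fraction`` of genes in every sample
    of that timepoint.
    """

    n_genes: int = 20000
    groups: Sequence[GroupSpec] = field(
        default_factory=lambda: tuple(
            GroupSpec(f"{t}_{d}", t, d)
            for d in (5, 14, 28)
            for t in ("control", "cort")
        )
    )
    lib_size_mean: float = 1e6
    lib_size_cv: float = 0.3
    tier_weights: Sequence[float] = (0.455, 0.2503, 0.15, 0.084, 0.0543, 0.0064)
    nb_dispersion: float = 0.1
    de_fraction: float = 0.02
    de_effect_rule: tuple[float, float] = (2.0, 0.5)
    batch_shift_sd: float = 0.0
    batch_gene_fraction: float = 0.05
    marker_modules: Sequence[MarkerModule] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be > 0")
        if not self.groups:
            raise ConfigError("groups must be non-empty")
        for g in self.groups:
            if g.n_samples <= 0:
                raise ConfigError(f"groups[{g.label}].n_samples must be > 0")
            if g.treatment not in ("control", "cort"):
                raise ConfigError(f"groups[{g.label}].treatment must be control|cort")
        if self.lib_size_mean <= 0:
            raise ConfigError("lib_size_mean must be > 0")
        if self.lib_size_cv < 0:
            raise ConfigError("lib_size_cv must be >= 0")
        w = np.asarray(self.tier_weights, dtype=float)
        if len(w) != 6 or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ConfigError("tier_weights must be 6 non-negative values summing to 1")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigError("de_fraction must be in [0, 1]")
        if not 0 <= self.batch_gene_fraction <= 1:
            raise ConfigError("batch_gene_fraction must be in [0, 1]")
        if self.batch_shift_sd < 0:
            raise ConfigError("batch_shift_sd must be >= 0")
        n_module = sum(m.n_genes for m in self.marker_modules)
        if n_module + int(round(self.de_fraction * self.n_genes)) > self.n_genes:
            raise ConfigError("marker_modules plus DE genes exceed n_genes")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated count matrix.

    ``genes``: per-gene true mean CPM, true log2FC under treatment, DE
    indicator, tier, module membership.  ``samples``: per-sample drawn
    library size, group, treatment, timepoint.  ``batch_offsets``: gene ×
    timepoint additive log2 offsets (sparse, mostly zero).
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    batch_offsets: pd.DataFrame


def default_config(**overrides) -> SimConfig:
    """A study-shaped default configuration, optionally overridden."""
    return replace(SimConfig(), **overrides)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Draw a count matrix under ``config``; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ng = config.n_genes

    gene_ids = pd.Index([f"G{i:06d}" for i in range(ng)], name="gene_id")

    # true mean CPM: tier mixture, log-uniform within tier
    tier_idx = rng.choice(6, size=ng, p=np.asarray(config.tier_weights, float))
    lo = np.array([_TIER_LOG10_BOUNDS[t][0] for t in tier_idx])
    hi = np.array([_TIER_LOG10_BOUNDS[t][1] for t in tier_idx])
    log10_cpm = rng.uniform(lo, hi)
    true_cpm = 10.0**log10_cpm
    # renormalize abundances so true CPM sums to 1e6: empirical CPM then
    # estimates true CPM directly.  Default tier weights put the expected
    # raw sum near 1e6 at the default n_genes, keeping the adjustment mild.
    true_cpm *= 1e6 / true_cpm.sum()
    log10_cpm = np.log10(true_cpm)

    # marker modules claim genes first, then DE genes from the remainder
    module = np.array([""] * ng, dtype=object)
    pool = rng.permutation(ng)
    pos = 0
    module_members: dict[str, np.ndarray] = {}
    for m in config.marker_modules:
        idx = pool[pos : pos + m.n_genes]
        module[idx] = m.label
        module_members[m.label] = idx
        pos += m.n_genes

    n_de = int(round(config.de_fraction * ng))
    de_idx = pool[pos : pos + n_de]
    a, b = config.de_effect_rule
    log2fc = np.zeros(ng)
    if n_de:
        mag = np.maximum(0.0, a - b * log10_cpm[de_idx])
        sign = rng.choice([-1.0, 1.0], size=n_de)
        log2fc[de_idx] = sign * mag
    is_de = log2fc != 0.0

    # samples
    sample_rows = []
    for g in config.groups:
        for i in range(g.n_samples):
            sample_rows.append(
                {
                    "sample_id": f"{g.label}_s{i + 1}",
                    "group": g.label,
                    "treatment": g.treatment,
                    "timepoint": g.timepoint,
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    ns = len(samples)

    if config.lib_size_cv > 0:
        sigma2 = np.log1p(config.lib_size_cv**2)
        mu_ln = np.log(config.lib_size_mean) - sigma2 / 2
        lib = rng.lognormal(mu_ln, np.sqrt(sigma2), size=ns)
    else:
        lib = np.full(ns, float(config.lib_size_mean))

    # per-timepoint batch offsets on a random gene subset (log2, all samples
    # of that timepoint, both treatments)
    timepoints = sorted({g.timepoint for g in config.groups})
    batch = pd.DataFrame(0.0, index=gene_ids, columns=timepoints)
    if config.batch_shift_sd > 0 and config.batch_gene_fraction > 0:
        n_hit = int(round(config.batch_gene_fraction * ng))
        for tp in timepoints:
            hit = rng.choice(ng, size=n_hit, replace=False)
            batch.iloc[hit, batch.columns.get_loc(tp)] = rng.normal(
                0.0, config.batch_shift_sd, size=n_hit
            )

    # per-sample log2 effect matrix
    effect = np.zeros((ng, ns))
    is_cort = (samples["treatment"] == "cort").to_numpy()
    effect[:, is_cort] += log2fc[:, None]
    tp_arr = samples["timepoint"].to_numpy()
    for tp in timepoints:
        effect[:, tp_arr == tp] += batch[tp].to_numpy()[:, None]

    # shared lognormal latent factors per module (natural-log scale)
    log_latent = np.zeros((ng, ns))
    for m in config.marker_modules:
        z = rng.normal(0.0, 1.0, size=ns)
        log_latent[module_members[m.label], :] = m.loading * z[None, :]

    mu = (
        lib[None, :]
        * (true_cpm[:, None] / 1e6)
        * np.exp2(effect)
        * np.exp(log_latent)
    )

    phi = config.nb_dispersion
    if phi < 1e-8:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / phi
        counts = rng.poisson(rng.gamma(shape, phi * mu))

    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=gene_ids, columns=samples.index
    )
    genes = pd.DataFrame(
        {
            "true_cpm": true_cpm,
            "true_log2fc": log2fc,
            "is_de": is_de,
            "tier_index": tier_idx,
            "module": module,
        },
        index=gene_ids,
    )
    sample_truth = samples.copy()
    sample_truth["true_lib_size"] = lib
    truth = SimTruth(genes=genes, samples=sample_truth, batch_offsets=batch)
    return CountMatrix(counts_df, samples), truth


def simulate_atlas(
    n_genes: int,
    categories: Sequence[str] | Mapping[str, Sequence[str]],
    n_specific_per_category: int,
    specificity_level: float,
    seed: int,
    cell_types_per_category: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A gene × cell-type atlas with planted category-specific genes.

    ``categories`` is either a mapping category → cell types or a list of
    category labels (then ``cell_types_per_category`` cell types are created
    per category).  Planted genes get an in-category maximum exactly
    ``specificity_level`` times their out-of-category maximum; background
    genes are near-uniform across cell types.

    Returns ``(atlas, truth)``; truth maps each planted gene to its category.
    """
    if not categories:
        raise ConfigError("categories must be non-empty")
    if specificity_level < 1:
        raise ConfigError("specificity_level must be >= 1")
    if isinstance(categories, Mapping):
        catmap = {c: list(cts) for c, cts in categories.items()}
    else:
        catmap = {
            c: [f"{c}_ct{i + 1}" for i in range(cell_types_per_category)]
            for c in categories
        }
    cell_types = [ct for cts in catmap.values() for ct in cts]
    ct_category = {ct: c for c, cts in catmap.items() for ct in cts}

    cats = list(catmap)
    n_planted = n_specific_per_category * len(cats)
    if n_planted > n_genes:
        raise ConfigError("planted genes exceed n_genes")

    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.5, 1.5, size=(n_genes, len(cell_types)))
    genes = [f"Atl{i:05d}" for i in range(n_genes)]
    atlas = pd.DataFrame(vals, index=genes, columns=cell_types)

    truth_rows = []
    gi = 0
    for cat in cats:
        in_cols = catmap[cat]
        out_cols = [ct for ct in cell_types if ct_category[ct] != cat]
        for _ in range(n_specific_per_category):
            g = genes[gi]
            out_vals = rng.uniform(0.2, 1.0, size=len(out_cols))
            atlas.loc[g, out_cols] = out_vals
            in_vals = rng.uniform(0.1, 0.9, size=len(in_cols)) * (
                specificity_level * out_vals.max()
            )
            in_vals[rng.integers(len(in_cols))] = specificity_level * out_vals.max()
            atlas.loc[g, in_cols] = in_vals
            truth_rows.append({"gene": g, "category": cat})
            gi += 1
    truth = pd.DataFrame(truth_rows, columns=["gene", "category"])
    return atlas, truth


def simulate_reference_list(
    gene_pool: Sequence[str],
    n_members: int,
    direction_probability: float,
    n_reports_range: tuple[int, int] = (3, 8),
    seed: int = 0,
    label: str = "reference",
) -> pd.DataFrame:
    """A referential gene list with binomial up/down report tallies.

    Each member receives ``n`` reports (uniform in ``n_reports_range``) of
    which ``k ~ Binomial(n, direction_probability)`` are up-reports.  The
    evidence tier is core when the same-direction tally reaches 4, extended
    at exactly 3, other below.
    """
    if not 0 <= direction_probability <= 1:
        raise ConfigError("direction_probability must be in [0, 1]")
    if n_members > len(gene_pool):
        raise ConfigError("n_members exceeds gene pool size")
    lo, hi = n_reports_range
    if lo < 1 or hi < lo:
        raise ConfigError("n_reports_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    members = rng.choice(np.asarray(gene_pool, dtype=object), size=n_members, replace=False)
    n = rng.integers(lo, hi + 1, size=n_members)
    k = rng.binomial(n, direction_probability)
    consistent = np.maximum(k, n - k)
    tier = np.where(consistent >= 4, "core", np.where(consistent == 3, "extended", "other"))
    return pd.DataFrame(
        {
            "symbol": members,
            "n_up": k,
            "n_down": n - k,
            "tier": tier,
            "list": label,
        }
    )


def write_simulation(cm: CountMatrix, truth: SimTruth, outdir) -> None:
    """Write counts, metadata and truth tables as TSV under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(out / "counts.tsv", sep="\t")
    cm.metadata.to_csv(out / "metadata.tsv", sep="\t")
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    truth.samples.to_csv(out / "truth_samples.tsv", sep="\t")
    truth.batch_offsets.to_csv(out / "truth_batch_offsets.tsv", sep="\t")
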