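"""Expression filtering, TMM normalization and negative-binomial testing.

A minimal, self-contained differential-expression stage for bulk RNA-seq
count matrices:

* the CPM filter threshold is ``min_count / median_library_size * 1e6``; a
  gene is kept when its CPM reaches that threshold in at least as many
  samples as the smallest experimental group;
* between-sample normalization is the trimmed mean of M-values (TMM): for
  each sample, log2 count ratios (M) against a reference sample are doubly
  trimmed (30% on M, 5% on the average abundance A) and combined with
  inverse-variance precision weights;
* two-group testing conditions on the per-gene total of library-equalized
  counts: with a common dispersion phi (var = mu + phi * mu^2), each group
  sum is negative binomial, and the two-sided exact p-value sums all
  conditional outcomes no more probable than the observed one;
* the pooled, batch-adjusted comparison fits a per-gene NB log-linear model
  (treatment + batch) by iteratively reweighted least squares and tests the
  treatment coefficient with a likelihood-ratio chi-square;
* p-values are adjusted by the Benjamini–Hochberg step-up FDR procedure.

The common dispersion is estimated by the method of moments pooled across
genes within groups, or can be supplied directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .io import CountMatrix

__all__ = [
    "filter_threshold",
    "filter_by_expression",
    "FilterResult",
    "tmm_factors",
    "effective_library_sizes",
    "estimate_common_dispersion",
    "nb_exact_test",
    "nb_glm_batch_test",
    "adjust_bh",
]

PRIOR_COUNT = 0.125  # per-group prior added to means before log2 fold change
DISPERSION_FLOOR = 1e-6

DE_COLUMNS = [
    "logFC",
    "log10CPM",
    "pvalue",
    "adj_pvalue",
    "direction",
    "comparison",
]


def _as_counts_df(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


# ---------------------------------------------------------------- filtering


def filter_threshold(min_count: float, median_lib_size: float) -> float:
    """CPM cutoff implied by a minimum count at the median library size."""
    if min_count <= 0 or median_lib_size <= 0:
        raise ConfigError("min_count and median_lib_size must be > 0")
    return min_count / median_lib_size * 1e6


class FilterResult:
    """Outcome of :func:`filter_by_expression`."""

    def __init__(self, kept: pd.Index, removed: pd.Index, threshold_cpm: float, n_min: int):
        self.kept = kept
        self.removed = removed
        self.threshold_cpm = threshold_cpm
        self.n_min = n_min

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FilterResult(kept={len(self.kept)}, removed={len(self.removed)}, "
            f"threshold={self.threshold_cpm:.4g} CPM, n_min={self.n_min})"
        )


def filter_by_expression(counts, groups=None, min_count: float = 10) -> FilterResult:
    """Keep genes with CPM >= threshold in at least ``n_min`` samples.

    ``n_min`` is the smallest group size; the threshold is
    :func:`filter_threshold` evaluated at the median library size.
    """
    df = _as_counts_df(counts)
    if groups is None:
        if not isinstance(counts, CountMatrix):
            raise ConfigError("groups required when counts is a bare DataFrame")
        groups = counts.groups()
    groups = pd.Series(np.asarray(groups, dtype=object), index=df.columns)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ConfigError("filtering needs >= 2 groups")
    n_min = int(sizes.min())
    lib = df.sum(axis=0)
    thr = filter_threshold(min_count, float(np.median(lib)))
    cpm = df / lib * 1e6
    keep = (cpm >= thr).sum(axis=1) >= n_min
    return FilterResult(df.index[keep], df.index[~keep], thr, n_min)


# ---------------------------------------------------------------- TMM


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference sample."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise DataError("sample shares no expressed genes with the reference")
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = len(m)
    lo_m = int(np.floor(n * logratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * sum_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts, ref_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the across-sample mean upper quartile, unless given.
    """
    df = _as_counts_df(counts)
    if df.shape[1] < 2:
        raise DataError("TMM needs >= 2 samples")
    lib = df.sum(axis=0).to_numpy(dtype=float)
    if (lib == 0).any():
        raise DataError("TMM requires nonzero library sizes")
    X = df.to_numpy(dtype=float)
    if ref_sample is None:
        uq = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = int(df.columns.get_loc(ref_sample))
    factors = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
        else:
            factors[j] = _tmm_pair_factor(X[:, j], X[:, ref_idx], lib[j], lib[ref_idx])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="tmm_factor")


def effective_library_sizes(counts, factors: pd.Series | None = None) -> pd.Series:
    """Raw library totals times TMM factors."""
    df = _as_counts_df(counts)
    lib = df.sum(axis=0).astype(float)
    if factors is None:
        factors = tmm_factors(df)
    return lib * factors


# ------------------------------------------------------- dispersion


def _equalize(df: pd.DataFrame, eff_lib: pd.Series) -> tuple[np.ndarray, float]:
    """Rescale counts to the geometric mean effective library (unrounded)."""
    common = float(np.exp(np.mean(np.log(eff_lib.to_numpy(dtype=float)))))
    z = df.to_numpy(dtype=float) * (common / eff_lib.to_numpy(dtype=float))[None, :]
    return z, common


def estimate_common_dispersion(counts, groups, factors: pd.Series | None = None) -> float:
    """Method-of-moments common NB dispersion (var = mu + phi * mu^2).

    Per gene and group, sample mean m and variance v of library-equalized
    counts give phi-information via v - m = phi * m^2; a ratio-of-sums pooled
    over all genes and groups (df-weighted) yields the common estimate,
    floored at 1e-6.
    """
    df = _as_counts_df(counts)
    groups = pd.Series(np.asarray(groups, dtype=object), index=df.columns)
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise DataError("dispersion estimation needs a group with >= 2 samples")
    eff = effective_library_sizes(df, factors)
    z, _ = _equalize(df, eff)
    num = 0.0
    den = 0.0
    for label in sizes.index:
        cols = np.asarray(groups == label)
        n = int(cols.sum())
        if n < 2:
            continue
        zg = z[:, cols]
        m = zg.mean(axis=1)
        v = zg.var(axis=1, ddof=1)
        w = n - 1
        num += w * float(np.sum(v - m))
        den += w * float(np.sum(m**2))
    if den <= 0:
        return DISPERSION_FLOOR
    return max(DISPERSION_FLOOR, num / den)


# ------------------------------------------------------- exact test


def _nb_logpmf(k: np.ndarray, mean: float, phi_eff: float) -> np.ndarray:
    """log pmf of NB with given mean and dispersion (var = m + phi m^2)."""
    if mean <= 0:
        out = np.full_like(k, -np.inf, dtype=float)
        out[k == 0] = 0.0
        return out
    r = 1.0 / phi_eff
    logp = np.log(r) - np.log(r + mean)  # log p, p = r/(r+mean)
    log1mp = np.log(mean) - np.log(r + mean)
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1) + r * logp + k * log1mp


def _exact_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact NB p-value for equal group means.

    Group sums of n iid NB(mu, phi) are NB(n*mu, phi/n).  Conditional on the
    total s = s1 + s2, the p-value sums the probabilities of all splits no
    more probable than the observed one.
    """
    s = s1 + s2
    if s == 0:
        return 1.0
    mu = s / (n1 + n2)
    k = np.arange(s + 1)
    lp = _nb_logpmf(k, n1 * mu, phi / n1) + _nb_logpmf(k[::-1], n2 * mu, phi / n2)
    lp -= lp.max()
    p = np.exp(lp)
    p /= p.sum()
    obs = p[s1]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-12)].sum()))


def _finalize_table(
    genes: pd.Index,
    logfc: np.ndarray,
    log10cpm: np.ndarray,
    pvals: np.ndarray,
    comparison: str,
) -> pd.DataFrame:
    adj = adjust_bh(pvals)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "log10CPM": log10cpm,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "direction": np.where(logfc >= 0, "up", "down"),
            "comparison": comparison,
        },
        index=genes,
    )


def nb_exact_test(
    counts,
    groups,
    pair: tuple[str, str] | None = None,
    dispersion: float | None = None,
    factors: pd.Series | None = None,
    comparison: str | None = None,
) -> pd.DataFrame:
    """Two-group exact NB test on library-equalized counts.

    ``pair = (reference, treated)``: log2FC is treated over reference with a
    prior count of 0.125 per group.  Counts are rescaled to the geometric
    mean of the effective library sizes (TMM-scaled totals) and rounded
    half-to-even before conditioning.  Genes with zero counts everywhere get
    p = 1 and logFC = 0.
    """
    df = _as_counts_df(counts)
    groups = pd.Series(np.asarray(groups, dtype=object), index=df.columns)
    levels = list(dict.fromkeys(groups))
    if pair is None:
        if len(levels) != 2:
            raise ConfigError(f"exact test needs exactly 2 groups, got {levels}")
        pair = (levels[0], levels[1])
    ref_label, trt_label = pair
    cols1 = groups == ref_label
    cols2 = groups == trt_label
    if not cols1.any() or not cols2.any():
        raise ConfigError(f"group labels {pair} not found in groups")
    sub = df.loc[:, cols1 | cols2]
    sub_groups = groups[cols1 | cols2]

    if factors is None:
        factors = tmm_factors(sub)
    eff = effective_library_sizes(sub, factors)
    if dispersion is None:
        dispersion = estimate_common_dispersion(sub, sub_groups, factors)
    phi = max(float(dispersion), 1e-8)

    z, common = _equalize(sub, eff)
    pseudo = np.rint(z).astype(np.int64)  # numpy rounds half to even
    g1 = np.asarray(sub_groups == ref_label)
    g2 = np.asarray(sub_groups == trt_label)
    n1, n2 = int(g1.sum()), int(g2.sum())
    s1 = pseudo[:, g1].sum(axis=1)
    s2 = pseudo[:, g2].sum(axis=1)

    pvals = np.ones(len(sub))
    for i in range(len(sub)):
        if s1[i] + s2[i] > 0:
            pvals[i] = _exact_pvalue(int(s1[i]), int(s2[i]), n1, n2, phi)

    m1 = s1 / n1
    m2 = s2 / n2
    logfc = np.log2((m2 + PRIOR_COUNT) / (m1 + PRIOR_COUNT))
    logfc[(s1 + s2) == 0] = 0.0
    mean_cpm = (s1 + s2) / (n1 + n2) / common * 1e6
    log10cpm = np.log10(mean_cpm + 2 * PRIOR_COUNT / common * 1e6)
    return _finalize_table(
        sub.index, logfc, log10cpm, pvals, comparison or f"{trt_label}_vs_{ref_label}"
    )


# ------------------------------------------------------- NB GLM (batch)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples; y, mu: genes × samples."""
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-10)
    return np.sum(
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + r * (np.log(r) - np.log(r + mu))
        + y * (np.log(mu) - np.log(r + mu)),
        axis=1,
    )


def _fit_nb_glm(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float,
    tol: float = 1e-8, max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS fit of per-gene NB log-linear models.

    y: genes × samples; X: samples × p (shared design); offset: log effective
    library sizes.  Returns (beta: genes × p, loglik per gene).
    """
    G, S = y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    # initialize intercept from mean rate
    rate = np.log(np.maximum(y.mean(axis=1), 0.1)) - offset.mean()
    beta[:, 0] = rate
    eta = beta @ X.T + offset[None, :]
    for _ in range(max_iter):
        eta = np.clip(eta, -50.0, 50.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)  # IRLS working weights for log link
        zresp = (eta - offset[None, :]) + (y - mu) / np.maximum(mu, 1e-10)
        A = np.einsum("jp,gj,jq->gpq", X, w, X)
        b = np.einsum("jp,gj,gj->gp", X, w, zresp)
        A += 1e-10 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        eta = beta @ X.T + offset[None, :]
        if delta < tol:
            break
    mu = np.exp(np.clip(eta, -50.0, 50.0))
    return beta, _nb_loglik(y, mu, phi)


def nb_glm_batch_test(
    counts,
    treatment,
    batch,
    dispersion: float | None = None,
    factors: pd.Series | None = None,
    comparison: str = "pooled",
) -> pd.DataFrame:
    """Pooled NB log-linear test of treatment with batch adjustment.

    Fits per gene ``log mu = offset + intercept + treatment + batch`` by IRLS
    (offset = log effective library size) and performs a one-df
    likelihood-ratio test on the treatment coefficient.  Raises on designs
    where treatment is aliased with batch.
    """
    df = _as_counts_df(counts)
    treatment = pd.Series(np.asarray(treatment, dtype=object), index=df.columns)
    batch = pd.Series(np.asarray(batch, dtype=object), index=df.columns)
    t_levels = list(dict.fromkeys(treatment))
    if len(t_levels) != 2:
        raise ConfigError(f"treatment must have exactly 2 levels, got {t_levels}")
    b_levels = list(dict.fromkeys(batch))

    t_col = (treatment == t_levels[1]).to_numpy(dtype=float)
    b_cols = [(batch == lvl).to_numpy(dtype=float) for lvl in b_levels[1:]]
    X_red = np.column_stack([np.ones(df.shape[1])] + b_cols)
    X_full = np.column_stack([X_red, t_col])
    if np.linalg.matrix_rank(X_full) <= np.linalg.matrix_rank(X_red):
        raise ConfigError(
            "treatment is aliased with batch: every treatment level occurs in "
            "a single batch, so the effects cannot be separated"
        )

    if factors is None:
        factors = tmm_factors(df)
    eff = effective_library_sizes(df, factors).to_numpy(dtype=float)
    if dispersion is None:
        dispersion = estimate_common_dispersion(df, treatment, factors)
    phi = max(float(dispersion), 1e-8)

    y = df.to_numpy(dtype=float)
    offset = np.log(eff)
    beta_full, ll_full = _fit_nb_glm(y, X_full, offset, phi)
    _, ll_red = _fit_nb_glm(y, X_red, offset, phi)
    lr = np.maximum(0.0, 2.0 * (ll_full - ll_red))
    pvals = stats.chi2.sf(lr, df=1)

    logfc = beta_full[:, -1] / np.log(2.0)
    all_zero = y.sum(axis=1) == 0
    pvals[all_zero] = 1.0
    logfc[all_zero] = 0.0
    common = float(np.exp(np.mean(np.log(eff))))
    mean_cpm = (y / eff[None, :] * 1e6).mean(axis=1)
    log10cpm = np.log10(mean_cpm + 2 * PRIOR_COUNT / common * 1e6)
    return _finalize_table(df.index, logfc, log10cpm, pvals, comparison)


# ------------------------------------------------------- FDR


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
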