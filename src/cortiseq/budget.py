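"""Transcript-budget accounting: the net effect of treatment on total
transcriptomic activity.

For each differentially expressed gene the difference in mean raw counts
between treated and control samples is a gain (up-regulated genes) or a loss
(down-regulated genes).  Summing gains and losses gives the net change in
the transcript budget, expressed as a percentage of the mean control total.
Per-sample totals are compared with the Mann–Whitney U test: exact two-sided
p (doubling the smaller tail of U = min(U1, U2)) for samples of at most 12
without ties, normal approximation with midrank tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import CountMatrix

__all__ = [
    "BudgetReport",
    "total_counts_per_sample",
    "budget_from_de",
    "mann_whitney_u",
]


def total_counts_per_sample(counts) -> pd.Series:
    """Per-sample total transcripts (column sums of raw counts)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    return df.sum(axis=0)


@dataclass
class BudgetReport:
    gained: float  # summed mean-count increase over up-regulated genes
    lost: float  # summed |mean-count decrease| over down-regulated genes
    net: float  # gained - lost
    control_mean_total: float
    pct_gained: float
    pct_lost: float
    pct_net: float
    u_statistic: float
    p_value: float
    n_up: int
    n_down: int


def budget_from_de(
    counts,
    de: pd.DataFrame,
    control_ids: Sequence[str],
    treated_ids: Sequence[str],
) -> BudgetReport:
    """Transcript budget of a DE gene set, on raw counts.

    ``de`` must carry a ``direction`` column over the genes to account
    (typically the significant genes of one comparison).  Per gene,
    delta = mean treated count - mean control count; gains sum delta over up
    genes and losses sum |delta| over down genes.  Percentages are relative
    to the mean control per-sample total.  The U test compares per-sample
    totals of the two groups.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if len(de) == 0:
        totals = total_counts_per_sample(df)
        ctrl_tot = totals[list(control_ids)]
        u, p = mann_whitney_u(ctrl_tot.to_numpy(), totals[list(treated_ids)].to_numpy())
        m = float(ctrl_tot.mean())
        return BudgetReport(0.0, 0.0, 0.0, m, 0.0, 0.0, 0.0, u, p, 0, 0)
    if not len(control_ids) or not len(treated_ids):
        raise DataError("control and treated sample sets must be non-empty")
    missing = de.index.difference(df.index)
    if len(missing):
        raise DataError(f"DE genes absent from counts: {sorted(missing)[:10]}")

    ctrl = df.loc[de.index, list(control_ids)].mean(axis=1)
    trt = df.loc[de.index, list(treated_ids)].mean(axis=1)
    delta = trt - ctrl
    up = de["direction"] == "up"
    down = de["direction"] == "down"
    gained = float(delta[up].sum())
    lost = float(delta[down].abs().sum())
    net = gained - lost

    totals = total_counts_per_sample(df)
    ctrl_totals = totals[list(control_ids)].to_numpy(dtype=float)
    trt_totals = totals[list(treated_ids)].to_numpy(dtype=float)
    control_mean_total = float(ctrl_totals.mean())
    u, p = mann_whitney_u(ctrl_totals, trt_totals)
    pct = lambda x: 100.0 * x / control_mean_total  # noqa: E731
    return BudgetReport(
        gained,
        lost,
        net,
        control_mean_total,
        pct(gained),
        pct(lost),
        pct(net),
        u,
        p,
        int(up.sum()),
        int(down.sum()),
    )


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements yielding each U value (no ties).

    Standard recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u).
    Returns an array of length n1*n2 + 1 summing to C(n1+n2, n1).
    """
    if n1 == 0 or n2 == 0:
        return np.ones(1, dtype=float)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = np.zeros(n1 * n2 + 1)
    out[n2 : n2 + len(a)] += a
    out[: len(b)] += b
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U with two-sided p.

    U = min(U1, U2) from midranks.  Exact p (double the smaller tail) when
    both samples have <= 12 observations and the pooled data are tie-free;
    otherwise a normal approximation with tie correction and 0.5 continuity
    correction.  Identical degenerate samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n1 <= 12 and n2 <= 12:
        counts = _u_counts(n1, n2)
        total = counts.sum()
        tail = counts[: int(u) + 1].sum() / total
        return float(u), float(min(1.0, 2.0 * tail))

    n = n1 + n2
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u), 1.0
    z = (u - n1 * n2 / 2.0 + 0.5) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.cdf(z)
    return float(u), float(min(1.0, p))
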