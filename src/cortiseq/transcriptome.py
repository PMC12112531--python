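"""Global transcriptome profiling: CPM, expression tiers, transcript shares
and marker-based correlation QC.

Expression is measured in counts per million (CPM): each sample's counts
scaled by its library total.  Genes are then placed into six tiers spanning
one order of magnitude each — residual (<0.1 CPM), low (0.1–1), lower medium
(1–10), upper medium (10–100), high (100–1000) and top (≥1000) — on the
arithmetic mean of their per-sample CPM.  Tier summaries report how many
genes fall in each tier and what share of all transcripts those genes carry,
optionally split by biotype.  Marker-set QC checks that genes with known
functional/anatomical relationships are correlated across samples while
unrelated genes are not, a dataset-level sanity check for bulk brain RNA-seq.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import CountMatrix

__all__ = [
    "TIERS",
    "TIER_NAMES",
    "MarkerSet",
    "QCThresholds",
    "compute_cpm",
    "categorize_gene",
    "categorize",
    "tier_summary",
    "detected_genes",
    "marker_correlation_qc",
]

#: Ordered CPM tiers as (name, lo, hi) with left-closed/right-open intervals.
TIERS: tuple[tuple[str, float, float], ...] = (
    ("residual", 0.0, 0.1),
    ("low", 0.1, 1.0),
    ("lower_medium", 1.0, 10.0),
    ("upper_medium", 10.0, 100.0),
    ("high", 100.0, 1000.0),
    ("top", 1000.0, np.inf),
)
TIER_NAMES: tuple[str, ...] = tuple(t[0] for t in TIERS)
_TIER_EDGES = np.array([t[2] for t in TIERS])  # upper bounds; last is inf


def compute_cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``counts / library_total * 1e6`` per sample."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = df.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise DataError(f"zero library total for sample(s): {list(zero)}")
    return df / lib * 1e6


def categorize_gene(mean_cpm: float) -> str:
    """Expression tier containing ``mean_cpm`` (left-closed intervals)."""
    if mean_cpm < 0 or not np.isfinite(mean_cpm):
        raise DataError(f"mean CPM must be finite and >= 0, got {mean_cpm}")
    idx = int(np.searchsorted(_TIER_EDGES[:-1], mean_cpm, side="right"))
    return TIER_NAMES[idx]


def categorize(mean_cpm: pd.Series) -> pd.Series:
    """Vectorized tier assignment; see :func:`categorize_gene`."""
    arr = np.asarray(mean_cpm, dtype=float)
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise DataError("mean CPM must be finite and >= 0")
    idx = np.searchsorted(_TIER_EDGES[:-1], arr, side="right")
    return pd.Series(
        pd.Categorical.from_codes(idx, categories=list(TIER_NAMES), ordered=True),
        index=mean_cpm.index if isinstance(mean_cpm, pd.Series) else None,
    )


def detected_genes(cpm: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """Split genes into detected (CPM > 0 in ≥1 sample) and undetected."""
    detected = (cpm > 0).any(axis=1)
    return cpm.index[detected], cpm.index[~detected]


# biotype buckets reported in tier summaries; "predicted" cuts across them
_BIOTYPE_BUCKETS = ("protein_coding", "pseudogene", "lncRNA")


def tier_summary(cpm: pd.DataFrame, ann: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-tier gene counts, gene percentages and transcript shares.

    Mean expression is the arithmetic mean of per-sample CPM; only detected
    genes (CPM > 0 somewhere) enter the summary.  The transcript share of a
    tier is the summed mean CPM of its genes as a percentage of the summed
    mean CPM of all detected genes.  With annotation supplied, per-tier
    biotype composition is added (protein-coding / pseudogene / lncRNA /
    other, plus the cross-cutting predicted-gene percentage, which may overlap
    the biotype buckets and therefore need not sum to 100).
    """
    if cpm.shape[0] == 0 or cpm.shape[1] == 0:
        raise DataError("empty CPM matrix")
    det, _ = detected_genes(cpm)
    mean_cpm = cpm.loc[det].mean(axis=1)
    tiers = categorize(mean_cpm)
    n_total = len(det)
    total_expr = float(mean_cpm.sum())

    rows = []
    for name in TIER_NAMES:
        in_tier = tiers == name
        genes = mean_cpm[np.asarray(in_tier)]
        row = {
            "tier": name,
            "n_genes": int(in_tier.sum()),
            "pct_genes": 100.0 * in_tier.sum() / n_total,
            "pct_transcripts": 100.0 * float(genes.sum()) / total_expr,
        }
        if ann is not None:
            sub = ann.loc[genes.index]
            n = max(len(sub), 1)
            bt = sub["biotype"]
            row["pct_protein_coding"] = 100.0 * (bt == "protein_coding").sum() / n
            row["pct_pseudogene"] = 100.0 * bt.str.contains("pseudogene").sum() / n
            row["pct_lncRNA"] = 100.0 * (bt == "lncRNA").sum() / n
            row["pct_other"] = 100.0 * (
                ~((bt == "protein_coding") | bt.str.contains("pseudogene") | (bt == "lncRNA"))
            ).sum() / n
            if "is_predicted" in sub.columns:
                row["pct_predicted"] = 100.0 * sub["is_predicted"].sum() / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("tier")


@dataclass
class MarkerSet:
    """A labelled set of marker genes with an expected correlation pattern.

    ``expected_relationship`` is one of ``high`` (tight functional coupling,
    e.g. hemoglobin subunits), ``loose`` or ``none`` (functionally unrelated).
    """

    label: str
    genes: Sequence[str]
    expected_relationship: str = "high"

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise DataError(f"marker set '{self.label}' needs >= 2 genes")
        if self.expected_relationship not in ("high", "loose", "none"):
            raise DataError(
                f"marker set '{self.label}': unknown expected relationship "
                f"'{self.expected_relationship}'"
            )


@dataclass
class QCThresholds:
    """Pass/fail cutoffs for marker-correlation QC.

    ``high``: every pairwise r must reach ``high_r``.  ``none``: every pair
    must have |r| < ``none_r`` or p > ``alpha``.  ``loose``: mean pairwise r
    in [``none_r``, ``high_r``).
    """

    high_r: float = 0.6
    none_r: float = 0.4
    alpha: float = 0.05


@dataclass
class MarkerQCResult:
    label: str
    expected_relationship: str
    pairs: pd.DataFrame = field(repr=False)
    missing: list[str] = field(default_factory=list)
    passed: bool = True


def marker_correlation_qc(
    cpm: pd.DataFrame,
    marker_sets: Sequence[MarkerSet],
    thresholds: QCThresholds | None = None,
) -> list[MarkerQCResult]:
    """Pairwise Pearson correlation QC over marker gene sets.

    For every set, all pairwise Pearson r (across samples) and two-sided p
    are computed and the set is classified pass/fail against its expected
    relationship.  Markers absent from the matrix are reported, not fatal.
    """
    th = thresholds or QCThresholds()
    if cpm.shape[1] < 3:
        raise DataError("marker QC needs >= 3 samples")
    results = []
    for ms in marker_sets:
        present = [g for g in ms.genes if g in cpm.index]
        missing = [g for g in ms.genes if g not in cpm.index]
        pair_rows = []
        for a, b in combinations(present, 2):
            r, p = stats.pearsonr(cpm.loc[a], cpm.loc[b])
            pair_rows.append({"gene_a": a, "gene_b": b, "r": r, "p": p})
        pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "r", "p"])
        if len(pairs) == 0:
            passed = False
        elif ms.expected_relationship == "high":
            passed = bool((pairs["r"] >= th.high_r).all())
        elif ms.expected_relationship == "none":
            passed = bool(((pairs["r"].abs() < th.none_r) | (pairs["p"] > th.alpha)).all())
        else:  # loose
            mean_r = float(pairs["r"].mean())
            passed = th.none_r <= mean_r < th.high_r or bool(
                ((pairs["r"] < th.high_r) & (pairs["p"] <= th.alpha)).any()
            )
        results.append(
            MarkerQCResult(ms.label, ms.expected_relationship, pairs, missing, passed)
        )
    return results
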