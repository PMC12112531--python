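"""Cross-timepoint replicability: Venn overlaps, direction-consistent
replicable gene sets, and the fold-change-vs-expression relationship.

A gene is *replicable* when it reaches significance (adj p < alpha) at two
or more treatment durations with the same direction of change at every
significant duration.  The magnitude/expression relationship is the Pearson
correlation between |log2FC| and log10 mean CPM over significant genes; a
negative r means highly expressed genes respond with proportionally smaller
fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .transcriptome import categorize

__all__ = [
    "ComparisonSet",
    "significant_set",
    "venn_counts",
    "replicable_genes",
    "fc_vs_expression_correlation",
]


@dataclass
class ComparisonSet:
    """Significant genes of one comparison with their directions."""

    label: str
    directions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {d for d in self.directions.values()} - {"up", "down"}
        if bad:
            raise DataError(f"invalid directions in '{self.label}': {sorted(bad)}")

    @property
    def genes(self) -> set[str]:
        return set(self.directions)


def significant_set(de: pd.DataFrame, alpha: float = 0.05, label: str | None = None) -> ComparisonSet:
    """Significant genes (adj p < alpha) of a DE table as a ComparisonSet."""
    sig = de[de["adj_pvalue"] < alpha]
    lab = label or (str(de["comparison"].iloc[0]) if len(de) else "comparison")
    return ComparisonSet(lab, dict(zip(sig.index, sig["direction"])))


def venn_counts(sets: Sequence[ComparisonSet]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for every intersection of 2–4 sets.

    Keys are sorted label tuples; a gene is counted in exactly the region of
    the sets that contain it, so region counts sum to the union size.
    """
    if not 2 <= len(sets) <= 4:
        raise DataError("venn_counts supports 2 to 4 sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise DataError(f"duplicate set labels: {labels}")
    membership: dict[str, set[str]] = {}
    for s in sets:
        for g in s.genes:
            membership.setdefault(g, set()).add(s.label)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            counts[tuple(sorted(combo))] = 0
    for g, labs in membership.items():
        counts[tuple(sorted(labs))] += 1
    return counts


def replicable_genes(timepoint_sets: Sequence[ComparisonSet]) -> pd.DataFrame:
    """Genes significant at >= 2 timepoints with a consistent direction.

    Only significant occurrences are compared: a gene significant at two
    durations in the same direction qualifies even if untested or
    non-significant elsewhere; any conflict among significant directions
    excludes the gene.  The tier is ``all_three`` when the gene is
    significant in every provided set (three sets given), else
    ``exactly_two``.
    """
    if len(timepoint_sets) < 2:
        raise DataError("replicable_genes needs >= 2 timepoint sets")
    occurrences: dict[str, list[str]] = {}
    for s in timepoint_sets:
        for g, d in s.directions.items():
            occurrences.setdefault(g, []).append(d)
    rows = []
    n_sets = len(timepoint_sets)
    for g, dirs in occurrences.items():
        if len(dirs) < 2 or len(set(dirs)) != 1:
            continue
        tier = "all_three" if (len(dirs) == n_sets and n_sets == 3) else "exactly_two"
        if len(dirs) == n_sets and n_sets != 3:
            tier = "all"
        rows.append(
            {"gene": g, "n_significant": len(dirs), "direction": dirs[0], "tier": tier}
        )
    out = pd.DataFrame(rows, columns=["gene", "n_significant", "direction", "tier"])
    return out.set_index("gene").sort_index()


def tier_breakdown(replicable: pd.DataFrame, mean_cpm: pd.Series) -> pd.Series:
    """Expression-tier counts of the replicable genes (on pooled mean CPM)."""
    present = replicable.index.intersection(mean_cpm.index)
    return categorize(mean_cpm.loc[present]).value_counts().sort_index()


def fc_vs_expression_correlation(
    de: pd.DataFrame, alpha: float = 0.05
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of |log2FC| vs log10 mean CPM.

    Computed over significant genes (adj p < alpha).
    """
    sig = de[de["adj_pvalue"] < alpha]
    if len(sig) < 3:
        raise DataError(f"need >= 3 significant genes, got {len(sig)}")
    x = sig["logFC"].abs().to_numpy()
    y = sig["log10CPM"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance in |logFC| or log10CPM")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
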