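"""Cell-expression specificity against a brain cell-type atlas.

The specificity of a gene for a cell category (e.g. immune cells, vascular
cells, neurons) is the ratio of its highest normalized expression among the
category's cell types to its highest expression in any cell type of the
remaining categories; zero denominators are replaced by 0.0001.  The score
is computed for every category and the best (category, score) kept per gene.
A score of 1 means at least two categories reach the gene's maximum; a score
of, say, 156.7 means the gene's peak expression in its best category is
156.7-fold above its peak anywhere else.  Scores are binned as [1, 2),
[2, 3) and >= 3; genes absent from the atlas are reported as ND.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "ZERO_SUB",
    "specificity_score",
    "score_all",
    "specificity_bins",
]

ZERO_SUB = 0.0001  # substituted for a zero out-of-category maximum

BIN_LABELS = ("[1,2)", "[2,3)", ">=3", "ND")


def _categories_in_order(catmap: Mapping[str, str]) -> list[str]:
    return list(dict.fromkeys(catmap.values()))


def specificity_score(
    gene_row: Mapping[str, float] | pd.Series,
    category: str,
    catmap: Mapping[str, str],
    zero_sub: float = ZERO_SUB,
) -> float:
    """max(in-category expression) / max(out-of-category expression).

    ``gene_row`` maps cell type -> normalized expression; ``catmap`` maps
    every cell type to its category.  An out-of-category maximum of 0 is
    replaced by ``zero_sub``.
    """
    row = pd.Series(gene_row, dtype=float)
    unmapped = row.index.difference(list(catmap))
    if len(unmapped):
        raise DataError(f"cell types missing from category map: {sorted(unmapped)}")
    in_mask = np.array([catmap[ct] == category for ct in row.index])
    if not in_mask.any():
        raise DataError(f"category '{category}' has no cell types")
    vals = row.to_numpy()
    if (vals < 0).any():
        raise DataError("atlas expression values must be >= 0")
    in_max = float(vals[in_mask].max())
    out = vals[~in_mask]
    out_max = float(out.max()) if len(out) else 0.0
    if out_max == 0.0:
        out_max = zero_sub
    return in_max / out_max


def _bin_label(score: float) -> str:
    if score >= 3:
        return ">=3"
    if score >= 2:
        return "[2,3)"
    if score >= 1:
        return "[1,2)"
    return "<1"


def score_all(
    genes: Sequence[str],
    atlas: pd.DataFrame,
    catmap: Mapping[str, str],
    synonyms: Mapping[str, str] | None = None,
    zero_sub: float = ZERO_SUB,
) -> pd.DataFrame:
    """Best-category specificity for each queried gene.

    The score is computed for every category and the highest kept; ties are
    broken by category order in ``catmap`` and flagged.  Genes absent from
    the atlas (after optional synonym lookup) yield ND records.

    Returns a DataFrame indexed by the queried symbol with columns
    ``best_category``, ``score``, ``bin``, ``tie``, ``atlas_symbol``.
    """
    if not catmap:
        raise DataError("empty category map")
    cats = _categories_in_order(catmap)
    rows = []
    for g in genes:
        lookup = g
        if lookup not in atlas.index and synonyms and g in synonyms:
            lookup = synonyms[g]
        if lookup not in atlas.index:
            rows.append(
                {
                    "gene": g,
                    "best_category": None,
                    "score": np.nan,
                    "bin": "ND",
                    "tie": False,
                    "atlas_symbol": None,
                }
            )
            continue
        row = atlas.loc[lookup]
        scores = [specificity_score(row, c, catmap, zero_sub) for c in cats]
        best = max(scores)
        winners = [c for c, s in zip(cats, scores) if s == best]
        rows.append(
            {
                "gene": g,
                "best_category": winners[0],
                "score": best,
                "bin": _bin_label(best),
                "tie": len(winners) > 1,
                "atlas_symbol": lookup,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def specificity_bins(
    records: pd.DataFrame, directions: Mapping[str, str] | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Bin fractions over {[1,2), [2,3), >=3, ND} plus high-specificity detail.

    Returns ``(fractions, high_table)``: fractions of all records per bin,
    and per-category counts of genes scoring >= 3 (split by DE direction when
    ``directions`` is given).
    """
    if len(records) == 0:
        raise DataError("no specificity records")
    frac = records["bin"].value_counts() / len(records)
    fractions = pd.Series({b: float(frac.get(b, 0.0)) for b in BIN_LABELS})
    below = records.index[(records["bin"] == "<1")]
    if len(below):  # best-over-categories score below 1 would be inconsistent
        raise DataError(f"best specificity score < 1 for genes: {list(below)[:5]}")

    high = records[records["bin"] == ">=3"]
    if directions is not None:
        rows = []
        for cat, block in high.groupby("best_category"):
            dirs = pd.Series([directions.get(g, "unknown") for g in block.index])
            rows.append(
                {
                    "category": cat,
                    "n": len(block),
                    "n_up": int((dirs == "up").sum()),
                    "n_down": int((dirs == "down").sum()),
                }
            )
        high_table = pd.DataFrame(rows, columns=["category", "n", "n_up", "n_down"])
    else:
        high_table = (
            high.groupby("best_category").size().rename("n").reset_index()
        ).rename(columns={"best_category": "category"})
    return fractions, high_table
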