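"""Comparison of DE results with referential gene lists.

Referential lists (glucocorticoid-responsive core/extended sets, stress
duration categories, PTSD) arrive as flat tables of gene symbols with
per-gene up/down report tallies.  Obsolete symbols are updated through a
synonym map before comparison.  A member's preferential direction follows
one of two published rules: the *stress* rule labels a gene up (down) when
at least 75% of reports agree on that direction; the *glucocorticoid* rule
labels it up (down) when that direction was reported at least three times
more frequently than the other.  Overlaps with the DE results are reported
per replicability tier along with direction consistency against the
preferential labels.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .errors import DataError

__all__ = [
    "read_synonym_map",
    "update_symbols",
    "direction_preference",
    "overlap_with_reference",
]


def read_synonym_map(path) -> dict[str, str]:
    """Read an old-symbol → current-symbol TSV (columns old, current)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _validate_map(dict(zip(df.iloc[:, 0], df.iloc[:, 1])), df)


def _validate_map(mapping: Mapping[str, str], df: pd.DataFrame | None = None) -> dict[str, str]:
    if df is not None and df.iloc[:, 0].duplicated().any():
        dups = df.iloc[:, 0][df.iloc[:, 0].duplicated()].tolist()
        raise DataError(f"conflicting synonym entries for: {dups}")
    for old, new in mapping.items():
        if new in mapping and mapping[new] != new:
            raise DataError(f"synonym map has a chain/cycle through '{new}'")
    return dict(mapping)


def update_symbols(
    symbols, synonym_map: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    """Replace obsolete symbols; returns (updated, unresolved).

    Symbols that are map keys are replaced; symbols appearing as current
    symbols (map values) pass through as fixed points; anything unknown to
    the map passes through unchanged but is listed as unresolved.
    """
    mapping = _validate_map(synonym_map)
    current = set(mapping.values())
    updated, unresolved = [], []
    for s in symbols:
        if s in mapping:
            updated.append(mapping[s])
        else:
            updated.append(s)
            if s not in current:
                unresolved.append(s)
    return updated, unresolved


def direction_preference(
    n_up: int, n_down: int, rule: str = "stress", threshold: float = 0.75
) -> str:
    """Preferential direction of a referential gene: 'up', 'down' or 'none'.

    stress rule: a direction wins with >= ``threshold`` of all reports
    (boundary inclusive).  glucocorticoid rule: a direction wins when
    reported at least three times more frequently than the other.
    """
    if n_up < 0 or n_down < 0:
        raise DataError("report tallies must be >= 0")
    if n_up == 0 and n_down == 0:
        raise DataError("both report tallies are zero")
    if rule == "stress":
        frac_up = n_up / (n_up + n_down)
        if frac_up >= threshold:
            return "up"
        if 1 - frac_up >= threshold:
            return "down"
        return "none"
    if rule == "glucocorticoid":
        if n_up >= 3 * n_down and n_up > 0:
            return "up"
        if n_down >= 3 * n_up and n_down > 0:
            return "down"
        return "none"
    raise DataError(f"unknown direction rule '{rule}'")


def overlap_with_reference(
    de_by_tier: Mapping[str, Mapping[str, str]],
    reference: pd.DataFrame,
    rule: str = "stress",
) -> pd.DataFrame:
    """Overlap of tiered DE genes with a referential list.

    ``de_by_tier`` maps a replicability tier label (e.g. all_three,
    exactly_two, one_timepoint, pooled_only) to {symbol: direction} of its
    genes.  ``reference`` is a table with columns symbol, n_up, n_down (one
    row per member; symbols already updated on both sides).  Per tier the
    report gives the member overlap count, its percentage of the tier, and
    how many overlapping genes match the member's preferential direction.
    """
    for col in ("symbol", "n_up", "n_down"):
        if col not in reference.columns:
            raise DataError(f"reference list lacks column '{col}'")
    members = reference.set_index("symbol")
    pref = {}
    for sym, row in members.iterrows():
        if row["n_up"] == 0 and row["n_down"] == 0:
            pref[sym] = "none"
        else:
            pref[sym] = direction_preference(int(row["n_up"]), int(row["n_down"]), rule)

    rows = []
    for tier, directions in de_by_tier.items():
        overlap = [g for g in directions if g in members.index]
        consistent = sum(
            1 for g in overlap if pref[g] != "none" and directions[g] == pref[g]
        )
        labelled = sum(1 for g in overlap if pref[g] != "none")
        n_tier = len(directions)
        rows.append(
            {
                "tier": tier,
                "n_tier": n_tier,
                "n_overlap": len(overlap),
                "pct_overlap": round(100.0 * len(overlap) / n_tier, 1) if n_tier else 0.0,
                "n_with_preference": labelled,
                "n_consistent": consistent,
            }
        )
    return pd.DataFrame(rows).set_index("tier")
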