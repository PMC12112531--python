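"""Count-matrix and gene-annotation IO, plus duplicate-symbol merging.

Count matrices arrive as plain TSV (genes in rows, first column the stable
gene id, header row of sample ids) together with a sample-metadata TSV
carrying at least ``treatment`` and ``timepoint`` per sample.  Annotation is a
flat table (gene_id, symbol, biotype, description); genes whose Ensembl
description marks them as predicted are flagged on load.

Gene symbols mapped to several stable ids are collapsed into a single entry
with per-sample summed counts *only* when every copy shares the same biotype;
copies with differing biotypes (e.g. a protein-coding gene and a transcribed
processed pseudogene sharing a symbol) are deliberately kept apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "read_annotation",
    "annotate_predicted",
    "merge_duplicate_symbols",
]

_META_REQUIRED = ("treatment", "timepoint")


@dataclass
class CountMatrix:
    """Genes × samples integer counts with per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids (unique),
        columns = sample ids.
    metadata
        DataFrame indexed by sample id covering every column of ``counts``,
        with at least ``treatment`` and ``timepoint`` columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise DataError(f"duplicated gene ids in count matrix: {dup}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
                raise DataError("count matrix contains non-integer values")
            self.counts = c = c.astype(np.int64)
            vals = c.to_numpy()
        if (vals < 0).any():
            raise DataError("count matrix contains negative values")
        missing = c.columns.difference(self.metadata.index)
        if len(missing):
            raise DataError(f"samples missing from metadata: {sorted(missing)}")
        for col in _META_REQUIRED:
            if col not in self.metadata.columns:
                raise DataError(f"metadata lacks required column '{col}'")
        # align metadata to column order, dropping unused rows
        self.metadata = self.metadata.loc[c.columns]

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def library_sizes(self) -> pd.Series:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    def groups(self) -> pd.Series:
        """Group label per sample: ``<treatment>_<timepoint>``."""
        m = self.metadata
        return m["treatment"].astype(str) + "_" + m["timepoint"].astype(str)


def read_counts(path, metadata_path) -> CountMatrix:
    """Read a genes × samples count TSV plus its sample-metadata TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, path, metadata_path) -> None:
    """Write a :class:`CountMatrix` back to TSV (inverse of :func:`read_counts`)."""
    cm.counts.to_csv(path, sep="\t")
    cm.metadata.to_csv(metadata_path, sep="\t")


def annotate_predicted(description: pd.Series) -> pd.Series:
    """Flag genes whose annotation description marks them as predicted.

    The rule is a case-insensitive substring match on "predicted gene", the
    wording Ensembl uses in its gene descriptions.
    """
    return (
        description.fillna("").str.contains("predicted gene", case=False).astype(bool)
    )


def read_annotation(path) -> pd.DataFrame:
    """Read a flat annotation TSV (gene_id, symbol, biotype, description).

    Returns a DataFrame indexed by gene_id with an ``is_predicted`` column
    derived from the description.
    """
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    for col in ("symbol", "biotype"):
        if col not in ann.columns:
            raise DataError(f"annotation lacks required column '{col}'")
    if ann.index.has_duplicates:
        raise DataError("annotation has duplicated gene ids")
    if "description" not in ann.columns:
        ann["description"] = ""
    ann["is_predicted"] = annotate_predicted(ann["description"])
    return ann


def merge_duplicate_symbols(
    cm: CountMatrix, ann: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Collapse same-symbol/same-biotype gene copies into single entries.

    Symbols attached to more than one gene id are merged — counts summed per
    sample — only when all copies share one biotype; copies of differing
    biotype stay separate.  The merged entry keeps the lexicographically
    smallest gene id.

    Returns ``(merged_counts, merged_annotation, report)`` where the report
    lists one row per merge: symbol, biotype, surviving id and all merged ids.
    """
    counts = cm.counts
    missing = counts.index.difference(ann.index)
    if len(missing):
        raise DataError(f"genes absent from annotation: {sorted(missing)[:10]}")
    sub = ann.loc[counts.index]

    merges: list[dict] = []
    drop: list[str] = []
    new_rows: dict[str, np.ndarray] = {}
    grouped = sub.groupby([sub["symbol"], sub["biotype"]], sort=False)
    for (symbol, biotype), block in grouped:
        if len(block) < 2:
            continue
        ids = sorted(block.index)
        primary = ids[0]
        new_rows[primary] = counts.loc[ids].sum(axis=0).to_numpy()
        drop.extend(ids[1:])
        merges.append(
            {
                "symbol": symbol,
                "biotype": biotype,
                "primary_id": primary,
                "merged_ids": ",".join(ids),
                "n_merged": len(ids),
            }
        )

    out = counts.drop(index=drop).copy()
    for primary, row in new_rows.items():
        out.loc[primary] = row
    merged_ann = sub.drop(index=drop)
    report = pd.DataFrame(
        merges, columns=["symbol", "biotype", "primary_id", "merged_ids", "n_merged"]
    )
    return CountMatrix(out, cm.metadata), merged_ann, report
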