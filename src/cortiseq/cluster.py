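"""Hierarchical clustering of gene expression patterns, Cluster-3.0 style.

Each gene's CPM profile is first divided by its own maximum (max-ratio
transform) so every profile lies in [0, 1] and peaks at 1; genes are then
clustered agglomeratively with complete linkage on the distance
1 - uncentered correlation, where the uncentered correlation of two profiles
is sum(x*y) / sqrt(sum(x^2) * sum(y^2)) — correlation about zero, the
similarity Java TreeView expects.  The merge tree is written as the CDT/GTR
file pair (clustered data table + gene dendrogram with per-node
similarities) loadable in Java TreeView.

Merge order is deterministic: among equally similar pairs the one whose
clusters contain the smallest original leaf indices merges first.  Under
complete linkage, node similarities never increase from leaves to root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "ClusterTree",
    "max_ratio_transform",
    "uncentered_correlation",
    "hcluster_complete",
    "write_cdt_gtr",
    "read_cdt",
    "read_gtr",
    "node_correlation_summary",
]


def max_ratio_transform(cpm: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Divide every row by its maximum; returns (transformed, all-zero rows).

    All-zero rows are left at zero and flagged (second return value) rather
    than producing NaNs; they carry no pattern to cluster.
    """
    vals = cpm.to_numpy(dtype=float)
    if (vals < 0).any():
        raise DataError("max-ratio transform requires non-negative values")
    row_max = vals.max(axis=1)
    zero = row_max == 0
    scale = np.where(zero, 1.0, row_max)
    out = pd.DataFrame(vals / scale[:, None], index=cpm.index, columns=cpm.columns)
    return out, cpm.index[zero]


def uncentered_correlation(x, y) -> float:
    """sum(x*y) / sqrt(sum(x^2) * sum(y^2)); undefined for a zero vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise DataError("vectors must be 1-D, non-empty and of equal length")
    sx = float(np.dot(x, x))
    sy = float(np.dot(y, y))
    if sx == 0.0 or sy == 0.0:
        raise DataError("uncentered correlation undefined for a zero vector")
    return float(np.dot(x, y) / np.sqrt(sx * sy))


@dataclass
class ClusterTree:
    """Binary gene merge tree.

    Leaves are numbered 0..n-1 in the input row order; the k-th merge (0
    based) creates internal node ``n + k``.  ``merges`` holds
    ``(left, right, similarity)`` per internal node, where similarity is the
    complete-linkage uncentered correlation at which the children joined.
    """

    n_leaves: int
    leaf_ids: list[str]
    merges: list[tuple[int, int, float]] = field(repr=False)

    def leaf_order(self) -> list[int]:
        """Leaf indices in dendrogram order (left child first)."""
        n = self.n_leaves
        order: list[int] = []
        root = n + len(self.merges) - 1

        stack = [root]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                left, right, _ = self.merges[node - n]
                stack.append(right)
                stack.append(left)
        return order

    def node_similarities(self) -> np.ndarray:
        return np.array([s for _, _, s in self.merges])


def hcluster_complete(matrix: pd.DataFrame) -> ClusterTree:
    """Complete-linkage agglomeration on 1 - uncentered correlation.

    Rows are genes.  Any all-zero row makes the similarity undefined and is
    an error naming the offending genes (drop them first; see
    :func:`max_ratio_transform`).  Ties in the best similarity are broken by
    the smallest original leaf index contained in the candidate clusters.
    """
    n = matrix.shape[0]
    if n < 2:
        raise DataError("clustering needs >= 2 genes")
    X = matrix.to_numpy(dtype=float)
    norms = np.sqrt((X**2).sum(axis=1))
    bad = norms == 0
    if bad.any():
        raise DataError(
            f"uncentered correlation undefined for all-zero genes: "
            f"{list(matrix.index[bad])[:10]}"
        )
    Xn = X / norms[:, None]
    S = np.clip(Xn @ Xn.T, -1.0, 1.0)

    NEG = -np.inf
    sim = S.copy()
    np.fill_diagonal(sim, NEG)
    active = np.ones(n, dtype=bool)
    node_id = np.arange(n)  # current node id sitting at each matrix slot
    min_leaf = np.arange(n)  # smallest original leaf index per slot
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], sim, NEG)
        best = masked.max()
        ii, jj = np.where(masked == best)
        # tie-break: lexicographically smallest (min_leaf_a, min_leaf_b)
        cand = [
            (min(min_leaf[i], min_leaf[j]), max(min_leaf[i], min_leaf[j]), i, j)
            for i, j in zip(ii, jj)
            if i < j
        ]
        _, _, i, j = min(cand)
        a, b = (i, j) if min_leaf[i] <= min_leaf[j] else (j, i)
        merges.append((int(node_id[a]), int(node_id[b]), float(S_pair(sim, i, j))))
        # complete linkage: similarity to the new cluster is the minimum
        new_sim = np.minimum(sim[i], sim[j])
        sim[i, :] = new_sim
        sim[:, i] = new_sim
        sim[i, i] = NEG
        active[j] = False
        node_id[i] = n + step
        min_leaf[i] = min(min_leaf[i], min_leaf[j])
    return ClusterTree(n, list(matrix.index), merges)


def S_pair(sim: np.ndarray, i: int, j: int) -> float:
    return sim[i, j]


# ------------------------------------------------------- CDT / GTR files


def _node_name(idx: int, n_leaves: int) -> str:
    return f"GENE{idx}X" if idx < n_leaves else f"NODE{idx - n_leaves + 1}X"


def _parse_node(name: str, n_leaves: int) -> int:
    if name.startswith("GENE"):
        return int(name[4:-1])
    if name.startswith("NODE"):
        return n_leaves + int(name[4:-1]) - 1
    raise DataError(f"unrecognized dendrogram node name '{name}'")


def write_cdt_gtr(
    matrix: pd.DataFrame,
    tree: ClusterTree,
    annotation: pd.DataFrame | None = None,
    out_prefix: str | Path = "cluster",
) -> tuple[Path, Path]:
    """Write the clustered table (.cdt) and gene tree (.gtr) for TreeView.

    CDT rows follow the dendrogram leaf order with GID/ORF/NAME/GWEIGHT
    columns; GTR holds one ``NODEkX  child  child  similarity`` line per
    internal node.  Values are written at full precision so a read-back
    reproduces the matrix exactly.
    """
    if list(matrix.index) != tree.leaf_ids:
        raise DataError("tree was not built on this matrix's genes")
    prefix = Path(out_prefix)
    cdt_path = prefix.with_suffix(".cdt")
    gtr_path = prefix.with_suffix(".gtr")

    n = tree.n_leaves
    with open(gtr_path, "w") as fh:
        for k, (left, right, s) in enumerate(tree.merges):
            fh.write(
                f"NODE{k + 1}X\t{_node_name(left, n)}\t{_node_name(right, n)}\t{s!r}\n"
            )

    symbols = {}
    if annotation is not None and "symbol" in annotation.columns:
        symbols = annotation["symbol"].to_dict()
    with open(cdt_path, "w") as fh:
        cols = "\t".join(str(c) for c in matrix.columns)
        fh.write(f"GID\tORF\tNAME\tGWEIGHT\t{cols}\n")
        fh.write("EWEIGHT\t\t\t" + "\t1" * matrix.shape[1] + "\n")
        vals = matrix.to_numpy(dtype=float)
        for leaf in tree.leaf_order():
            gid = matrix.index[leaf]
            name = symbols.get(gid, gid)
            row = "\t".join(repr(float(v)) for v in vals[leaf])
            fh.write(f"GENE{leaf}X\t{gid}\t{name}\t1\t{row}\n")
    return cdt_path, gtr_path


def read_cdt(path) -> pd.DataFrame:
    """Parse a CDT written by :func:`write_cdt_gtr` (rows in leaf order)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[4:]
        rows = {}
        gids = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "EWEIGHT":
                continue
            gids.append(parts[0])
            rows[parts[1]] = [float(v) for v in parts[4:]]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.attrs["gene_ids"] = gids
    return df


def read_gtr(path, n_leaves: int) -> list[tuple[int, int, float]]:
    """Parse a GTR file back into merge tuples."""
    merges = []
    with open(path) as fh:
        for line in fh:
            _, left, right, s = line.rstrip("\n").split("\t")
            merges.append((_parse_node(left, n_leaves), _parse_node(right, n_leaves), float(s)))
    return merges


# ------------------------------------------------------- node summaries


def node_correlation_summary(
    tree: ClusterTree, subset: Sequence[str], threshold: float
) -> tuple[float, pd.Series]:
    """Fraction of subset genes joining other subset genes at >= threshold.

    Per gene, the join similarity is that of the first ancestor node whose
    other branch contains another subset gene — under complete linkage the
    highest-similarity node on the gene's root path that connects it within
    the subset.  A gene with no subset partner (singleton subset) falls back
    to its first merge with anything.  Returns the fraction of subset genes
    with join similarity >= threshold, plus the per-gene similarities.
    """
    subset = list(subset)
    if not subset:
        raise DataError("empty gene subset")
    pos = {g: i for i, g in enumerate(tree.leaf_ids)}
    missing = [g for g in subset if g not in pos]
    if missing:
        raise DataError(f"subset genes not in tree: {missing[:10]}")
    n = tree.n_leaves
    parent: dict[int, int] = {}
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    for k, (left, right, _) in enumerate(tree.merges):
        node = n + k
        parent[left] = node
        parent[right] = node
        members[node] = members[left] | members[right]

    subset_idx = {pos[g] for g in subset}
    sims = {}
    for g in subset:
        leaf = pos[g]
        cur = leaf
        join_sim = None
        first_parent_sim = None
        while cur in parent:
            pnode = parent[cur]
            left, right, s = tree.merges[pnode - n]
            if first_parent_sim is None:
                first_parent_sim = s
            sibling = right if left == cur else left
            if members[sibling] & subset_idx:
                join_sim = s
                break
            cur = pnode
        sims[g] = join_sim if join_sim is not None else first_parent_sim
    series = pd.Series(sims)
    return float((series >= threshold).mean()), series
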