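"""Unsupervised hierarchical clustering of methylation/expression profiles.

Reproduces the Cluster-3.0-style workflow: array (column) mean centering,
Pearson "correlation (centered)" dissimilarity d = 1 - r, and unweighted
average-linkage (UPGMA) agglomeration.  Results can be written as
TreeView-compatible .cdt/.gtr/.atr files and as a plain JSON dendrogram.

The UPGMA implementation is hand-rolled because the merge tie-break is part
of the contract here (ties go to the lexicographically smallest pair of
cluster ids, ids assigned in creation order); library implementations do not
guarantee a specific tie order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import InputError


def mean_center_arrays(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each array's (column's) mean; rows are untouched.

    A constant column becomes all zeros (allowed; downstream correlation on
    such a column is then undefined and raises there).
    """
    return matrix - matrix.mean(axis=0)


def centered_correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """d = 1 - Pearson r, in [0, 2]. Zero-variance input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise InputError("vectors must share a length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise InputError("correlation distance undefined for zero-variance vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(1.0 - r, 0.0, 2.0))


def pairwise_correlation_distance(matrix: pd.DataFrame) -> np.ndarray:
    """Row-by-row centered-correlation dissimilarity matrix."""
    values = matrix.to_numpy(dtype=float)
    if (values.std(axis=1) == 0).any():
        bad = matrix.index[values.std(axis=1) == 0][:5].tolist()
        raise InputError(f"zero-variance rows (e.g. {bad}) have no correlation distance")
    r = np.corrcoef(values)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """UPGMA merge tree.

    ``merges``: one (node_a, node_b, height) per merge; leaves are ids
    0..n-1, the k-th merge creates id n+k.  ``leaf_order`` is the
    left-to-right leaf permutation from tree traversal.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int

    @property
    def leaf_order(self) -> list[int]:
        children = {
            self.n_leaves + k: (a, b) for k, (a, b, _) in enumerate(self.merges)
        }
        order: list[int] = []

        def walk(node: int) -> None:
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = children[node]
                walk(a)
                walk(b)

        walk(self.n_leaves + len(self.merges) - 1) if self.merges else order.append(0)
        return order

    def cophenetic_matrix(self) -> np.ndarray:
        """Pairwise merge heights between leaves (for oracle comparisons)."""
        members: dict[int, list[int]] = {i: [i] for i in range(self.n_leaves)}
        coph = np.zeros((self.n_leaves, self.n_leaves))
        for k, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    coph[i, j] = coph[j, i] = h
            members[self.n_leaves + k] = members.pop(a) + members.pop(b)
        return coph

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_leaves": self.n_leaves,
                "merges": [[a, b, h] for a, b, h in self.merges],
                "leaf_order": self.leaf_order,
            },
            indent=1,
            sort_keys=True,
        )


def average_linkage(dissimilarity: np.ndarray) -> Dendrogram:
    """UPGMA agglomeration of a symmetric zero-diagonal dissimilarity matrix.

    Cluster distance is the unweighted mean over all cross pairs of original
    items (maintained by the Lance-Williams size-weighted update).  Ties are
    broken toward the lexicographically smallest (id_a, id_b) pair.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("dissimilarity must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise InputError("dissimilarity must be symmetric with zero diagonal")
    n = d.shape[0]
    if n < 2:
        raise InputError("need at least 2 items")

    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((a, b, h))
        new = next_id
        next_id += 1
        active.discard(a)
        active.discard(b)
        for k in sorted(active):
            da = dist.pop((min(a, k), max(a, k)))
            db = dist.pop((min(b, k), max(b, k)))
            dist[(k, new)] = (size[a] * da + size[b] * db) / (size[a] + size[b])
        del dist[(a, b)]
        size[new] = size.pop(a) + size.pop(b)
        active.add(new)
    return Dendrogram(merges=merges, n_leaves=n)


def cluster_matrix(
    matrix: pd.DataFrame,
    cluster_rows: bool = True,
    cluster_columns: bool = True,
    center_arrays: bool = True,
) -> tuple[pd.DataFrame, Dendrogram | None, Dendrogram | None]:
    """Array-center then cluster rows and/or columns with 1 - r dissimilarity.

    Returns the (centered, reordered) matrix plus row and column dendrograms.
    Only array (column) centering is applied; gene-wise centering is not.
    """
    work = mean_center_arrays(matrix) if center_arrays else matrix.copy()
    row_tree = col_tree = None
    if cluster_rows and len(work) > 1:
        row_tree = average_linkage(pairwise_correlation_distance(work))
        work = work.iloc[row_tree.leaf_order]
    if cluster_columns and work.shape[1] > 1:
        col_tree = average_linkage(pairwise_correlation_distance(work.T))
        work = work.iloc[:, col_tree.leaf_order]
    return work, row_tree, col_tree


def _write_tree(path: Path, tree: Dendrogram, leaf_prefix: str) -> list[str]:
    """Write a .gtr/.atr file; heights are stored as similarities (1 - d)."""
    names = {}
    for i in range(tree.n_leaves):
        names[i] = f"{leaf_prefix}{i}X"
    lines = []
    for k, (a, b, h) in enumerate(tree.merges):
        node = f"NODE{k + 1}X"
        names[tree.n_leaves + k] = node
        lines.append(f"{node}\t{names[a]}\t{names[b]}\t{1.0 - h:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return lines


def write_treeview_files(
    matrix: pd.DataFrame,
    prefix: str | Path,
    row_tree: Dendrogram | None = None,
    col_tree: Dendrogram | None = None,
    gene_names: pd.Series | None = None,
) -> dict[str, Path]:
    """Write Cluster-3.0 .cdt (+ .gtr/.atr) files loadable in TreeView.

    ``matrix`` must already be in final (leaf) order, as returned by
    :func:`cluster_matrix`; row/column ids are taken from its index/columns.
    """
    prefix = Path(prefix)
    out: dict[str, Path] = {}
    n_rows = len(matrix)

    gene_ids = [f"GENE{i}X" for i in range(n_rows)]
    if row_tree is not None:
        order = row_tree.leaf_order
        gene_ids = [f"GENE{i}X" for i in order]
        out["gtr"] = prefix.with_suffix(".gtr")
        _write_tree(out["gtr"], row_tree, "GENE")
    arry_ids = [f"ARRY{j}X" for j in range(matrix.shape[1])]
    if col_tree is not None:
        arry_ids = [f"ARRY{j}X" for j in col_tree.leaf_order]
        out["atr"] = prefix.with_suffix(".atr")
        _write_tree(out["atr"], col_tree, "ARRY")

    lines = ["\t".join(["GID", "UNIQID", "NAME", "GWEIGHT", *matrix.columns])]
    if col_tree is not None:
        lines.append("\t".join(["AID", "", "", "", *arry_ids]))
    lines.append("\t".join(["EWEIGHT", "", "", "", *["1"] * matrix.shape[1]]))
    names = gene_names if gene_names is not None else pd.Series(matrix.index, index=matrix.index)
    for gid, (row_id, row) in zip(gene_ids, matrix.iterrows()):
        vals = "\t".join(f"{v:.6f}" for v in row)
        lines.append(f"{gid}\t{row_id}\t{names.loc[row_id]}\t1\t{vals}")
    out["cdt"] = prefix.with_suffix(".cdt")
    out["cdt"].write_text("\n".join(lines) + "\n")
    return out
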