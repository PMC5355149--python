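"""Normalization and complete-linkage hierarchical clustering of the
gene x phenotype co-occurrence matrix.

Rows (genes) are clustered; the fixed phenotype columns are not.  The
default preprocessing is per-row min-max scaling, which makes a gene's
profile across phenotypes comparable regardless of its overall literature
frequency; global min-max is available as an alternative.

The agglomeration uses complete ("maximum") linkage on Euclidean distance:
the distance between two clusters is the largest pairwise distance between
their members.  Complete linkage is monotone, so merge heights never
decrease.  Ties are broken deterministically by the smallest pair of lowest
original row indices, and within each merge the subtree containing the
lower original index is placed left — the dendrogram and heatmap row order
are therefore reproducible.

The merge list follows the scipy convention: leaves are clusters 0..n-1 and
the i-th merge creates cluster n+i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cooccurrence import CooccurrenceMatrix


@dataclass
class ClusterTree:
    """Agglomeration result: ordered merges (left_id, right_id, height)."""

    merges: list[tuple[int, int, float]]
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_linkage(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage matrix (for dendrogram interop)."""
        n = self.n_leaves
        sizes: dict[int, int] = {i: 1 for i in range(n)}
        rows = []
        for step, (left, right, height) in enumerate(self.merges):
            size = sizes[left] + sizes[right]
            sizes[n + step] = size
            rows.append([float(left), float(right), float(height), float(size)])
        return np.array(rows, dtype=float)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, CooccurrenceMatrix):
        return matrix.counts.astype(float)
    if isinstance(matrix, pd.DataFrame):
        return matrix.astype(float)
    arr = np.asarray(matrix, dtype=float)
    return pd.DataFrame(arr)


def linear_normalize(matrix, mode: str = "row") -> pd.DataFrame:
    """Min-max scale to [0, 1], per row (default) or over the whole matrix.

    Constant rows (or a constant matrix in global mode) map to all-zeros.
    """
    df = _as_frame(matrix)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValueError("matrix must have at least 1 row and 1 column")
    values = df.to_numpy(dtype=float)
    if mode == "row":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
    elif mode == "global":
        lo, hi = values.min(), values.max()
        out = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def hierarchical_cluster(
    matrix, linkage: str = "complete", metric: str = "euclidean"
) -> ClusterTree:
    """Agglomerative clustering of matrix rows.

    Only complete linkage is provided (the heatmap analysis uses nothing
    else); the metric is any :func:`scipy.spatial.distance.pdist` metric,
    Euclidean by default.  Requires at least 2 rows.
    """
    if linkage != "complete":
        raise ValueError("only complete (maximum) linkage is supported")
    df = _as_frame(matrix)
    n = df.shape[0]
    if n < 2:
        raise ValueError("clustering requires at least 2 rows")
    labels = tuple(str(i) for i in df.index)
    dist = squareform(pdist(df.to_numpy(dtype=float), metric=metric))

    # active cluster state: id -> (min original row index, member slot)
    # cluster-distance matrix updated by the Lance-Williams rule for
    # complete linkage: d(a+b, k) = max(d(a,k), d(b,k))
    cluster_dist = dist.copy()
    slot_id = list(range(n))  # slot -> current cluster id (-1 = dead)
    slot_min = list(range(n))  # slot -> min original row index of its cluster
    active = list(range(n))  # live slots
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best: tuple[float, tuple[int, int], int, int] | None = None
        for i_pos in range(len(active)):
            si = active[i_pos]
            for j_pos in range(i_pos + 1, len(active)):
                sj = active[j_pos]
                d = cluster_dist[si, sj]
                tie_key = tuple(sorted((slot_min[si], slot_min[sj])))
                cand = (d, tie_key, si, sj)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        d, _, si, sj = best
        # orient: subtree containing the lower original index goes left
        if slot_min[si] <= slot_min[sj]:
            left_slot, right_slot = si, sj
        else:
            left_slot, right_slot = sj, si
        merges.append((slot_id[left_slot], slot_id[right_slot], float(d)))
        # merge into left_slot
        new_row = np.maximum(cluster_dist[left_slot], cluster_dist[right_slot])
        cluster_dist[left_slot, :] = new_row
        cluster_dist[:, left_slot] = new_row
        cluster_dist[left_slot, left_slot] = 0.0
        slot_id[left_slot] = n + step
        slot_min[left_slot] = min(slot_min[left_slot], slot_min[right_slot])
        active.remove(right_slot)
    return ClusterTree(merges=merges, labels=labels)


def leaf_order(tree: ClusterTree) -> list[str]:
    """Left-to-right depth-first leaf labels of the dendrogram."""
    n = tree.n_leaves
    children = {n + i: (left, right) for i, (left, right, _) in enumerate(tree.merges)}
    if not tree.merges:
        return list(tree.labels)
    order: list[int] = []
    stack = [n + len(tree.merges) - 1]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
        else:
            left, right = children[node]
            stack.append(right)
            stack.append(left)
    return [tree.labels[i] for i in order]


def export_heatmap_data(matrix, tree: ClusterTree, path: str) -> None:
    """Write the matrix reordered by leaf order as TSV, plus the merge list
    as a sidecar JSON at ``<path>.tree.json``."""
    df = _as_frame(matrix)
    order = leaf_order(tree)
    df.loc[order].to_csv(path, sep="\t", index_label="symbol", float_format="%.17g")
    sidecar = {
        "labels": list(tree.labels),
        "merges": [[left, right, height] for left, right, height in tree.merges],
        "leaf_order": order,
    }
    with open(f"{path}.tree.json", "w") as handle:
        json.dump(sidecar, handle, indent=1)
        handle.write("\n")
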