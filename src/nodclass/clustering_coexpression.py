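"""Hierarchical clustering with Pearson distance and co-expression queries.

Profiles (gene rows or condition columns of the per-condition mean log2
matrix) are compared by Pearson correlation; the clustering distance is
``d = 1 - r`` (0 for identical shape, 2 for perfectly anti-correlated) and
trees are built by unweighted average linkage (UPGMA-style) with
deterministic smallest-index tie-breaking.  Trees serialise to Newick with
branch lengths equal to merge-height differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LinkageTree:
    """Merge list in scipy convention: leaves are 0..n-1, the k-th merge
    creates node n+k; each merge is (node_a, node_b, height, size)."""

    merges: list[tuple[int, int, float, int]]
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_linkage_matrix(self) -> np.ndarray:
        """scipy-compatible (n-1) x 4 linkage matrix."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)


def pearson_distance(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson distances (1 - r) between rows.

    Zero-variance rows cannot be correlated; they are excluded and returned
    in the second element (with a warning).
    """
    arr = matrix.to_numpy(dtype=float)
    variances = arr.var(axis=1)
    keep = variances > 0
    excluded = [str(i) for i in matrix.index[~keep]]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance rows from distance matrix",
            stacklevel=2,
        )
    sub = matrix.loc[keep]
    r = np.corrcoef(sub.to_numpy(dtype=float))
    r = np.atleast_2d(r)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    dist = pd.DataFrame(d, index=sub.index, columns=sub.index)
    return dist, excluded


def average_linkage(distances: pd.DataFrame | np.ndarray) -> LinkageTree:
    """Unweighted average (UPGMA-style) agglomeration of a distance matrix.

    At each step the pair of clusters with the smallest average distance is
    merged; exact ties are broken by the smallest pair of cluster indices
    (clusters numbered in creation order, so leaves first).  The input must
    be symmetric with a zero diagonal.
    """
    if isinstance(distances, pd.DataFrame):
        labels = [str(x) for x in distances.index]
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        labels = [str(i) for i in range(d.shape[0])]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")

    n = d.shape[0]
    # cluster id -> (size,); distances kept in a dict-of-dict keyed by id
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    active = list(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n

    for _ in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = dist[(i, j)]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        _, i, j = best
        height = dist[(i, j)]
        size = sizes[i] + sizes[j]
        merges.append((i, j, height, size))
        # unweighted average update: d(new, k) = (ni*d(i,k) + nj*d(j,k)) / (ni+nj)
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(k, next_id)] = (sizes[i] * dik + sizes[j] * djk) / size
        active = [k for k in active if k not in (i, j)] + [next_id]
        sizes[next_id] = size
        next_id += 1

    return LinkageTree(merges=merges, leaf_labels=labels)


def to_newick(tree: LinkageTree) -> str:
    """Serialise a linkage tree to Newick; branch length of a child is the
    parent merge height minus the child's own height (0 for leaves)."""
    n = tree.n_leaves
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, str] = {}
    for k, (a, b, h, _size) in enumerate(tree.merges):
        heights[n + k] = h
        parts = []
        for child in (a, b):
            label = (
                tree.leaf_labels[child] if child < n else nodes[child]
            )
            parts.append(f"{label}:{h - heights[child]:.6g}")
        nodes[n + k] = f"({parts[0]},{parts[1]})"
    return nodes[n + len(tree.merges) - 1] + ";"


def cluster_probes(mean_log2: pd.DataFrame) -> LinkageTree:
    """Cluster probe profiles (rows of the per-condition mean matrix)."""
    dist, _ = pearson_distance(mean_log2)
    return average_linkage(dist)


def cluster_conditions(mean_log2: pd.DataFrame) -> LinkageTree:
    """Cluster condition profiles (columns of the per-condition mean matrix)."""
    dist, _ = pearson_distance(mean_log2.T)
    return average_linkage(dist)


def coexpression_query(
    reference_profile: pd.Series,
    matrix: pd.DataFrame,
    threshold: float = 0.8,
    reference_id: str | None = None,
) -> list[tuple[str, float]]:
    """Probes whose profile correlates with the reference at r >= threshold.

    Profiles must share the same condition axis.  The reference row itself
    (matched by ``reference_id``, or by the series name) is excluded.
    Results are sorted by descending r, ties by probe id.
    """
    if list(reference_profile.index) != list(matrix.columns):
        raise ValueError("reference profile and dataset have different condition axes")
    ref_id = reference_id if reference_id is not None else reference_profile.name

    ref = reference_profile.to_numpy(dtype=float)
    arr = matrix.to_numpy(dtype=float)
    ref_c = ref - ref.mean()
    arr_c = arr - arr.mean(axis=1, keepdims=True)
    denom = np.sqrt((ref_c**2).sum()) * np.sqrt((arr_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (arr_c @ ref_c) / denom
    hits = [
        (str(p), float(rv))
        for p, rv in zip(matrix.index, r)
        if p != ref_id and np.isfinite(rv) and rv >= threshold
    ]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits
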