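"""Hierarchical clustering of diseases by their age pattern.

Diseases are compared by the Pearson correlation of their (normalized)
age-distribution rows; distance is 1 - r, so perfectly anti-correlated
patterns are maximally distant.  Agglomerative clustering (average linkage
by default) produces a dendrogram that can be cut into k groups or
exported as a Newick tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import AgeDiseaseMatrix

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray  # scipy linkage encoding of the merge tree
    labels: list[str]
    linkage_method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]


def correlation_distances(matrix: AgeDiseaseMatrix) -> tuple[np.ndarray, list[str]]:
    """Condensed 1 - Pearson distance over disease rows.

    Zero-variance rows (correlation undefined) are removed with a warning.
    """
    arr = matrix.data.to_numpy(dtype=float)
    labels = list(matrix.data.index)
    variances = arr.var(axis=1)
    if (variances == 0).any():
        dropped = [l for l, v in zip(labels, variances) if v == 0]
        logger.warning("dropping %d zero-variance disease rows: %s", len(dropped), dropped[:5])
        arr = arr[variances > 0]
        labels = [l for l, v in zip(labels, variances) if v > 0]
    if len(labels) < 2:
        raise ValueError("need at least 2 disease rows with variance to cluster")
    corr = np.corrcoef(arr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    return squareform(dist, checks=False), labels


def cluster_diseases(matrix: AgeDiseaseMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with 1 - r distances."""
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    condensed, labels = correlation_distances(matrix)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(linkage_matrix=Z, labels=labels, linkage_method=linkage)


def cut_tree(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut into exactly k clusters; returns disease -> cluster id (1-based)."""
    if not 1 <= k <= dendrogram.n_leaves:
        raise ValueError(f"k={k} out of range 1..{dendrogram.n_leaves}")
    assignment = hierarchy.fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    return {label: int(c) for label, c in zip(dendrogram.labels, assignment)}


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths = merge-height differences."""
    tree = hierarchy.to_tree(dendrogram.linkage_matrix)

    def quote(label: str) -> str:
        if any(c in label for c in ":;,()[]' \t"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{quote(dendrogram.labels[node.id])}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
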