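"""Compound similarity: distance matrices, UPGMA dendrograms, Newick export.

Similarity between compounds is measured either as Euclidean distance over
the standardized descriptor matrix (the default, matching descriptor-based
clustering practice) or as Tanimoto distance ``1 - |A&B| / |A|B|`` over
binary fingerprints.  Agglomerative average-linkage (UPGMA) clustering
produces an ultrametric merge tree whose heights are exported as Newick
branch lengths (each branch carries half the parent-child height gap, so
the leaf-to-leaf path length equals the cophenetic merge height).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .features import DescriptorMatrix

__all__ = [
    "DistanceMatrix",
    "DendrogramTree",
    "compound_distance_matrix",
    "hierarchical_cluster",
    "export_dendrogram",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    D: np.ndarray
    metric: str

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.D = D

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


@dataclass
class DendrogramTree:
    """Binary merge tree (scipy linkage encoding) with leaf ids."""

    linkage: np.ndarray
    leaf_ids: list[str]
    method: str = "average"

    def __post_init__(self):
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.linkage), checks=False)


def compound_distance_matrix(dm: DescriptorMatrix, metric: str = "euclidean_standardized"
                             ) -> DistanceMatrix:
    """Pairwise compound distances from descriptors or fingerprints."""
    X = dm.X
    if metric == "euclidean_standardized":
        cond = pdist(X, metric="euclidean")
    elif metric == "tanimoto":
        if not np.isin(X, (0, 1)).all():
            raise ValueError("tanimoto distance requires a binary fingerprint matrix")
        # Jaccard distance on boolean vectors == 1 - Tanimoto similarity
        cond = pdist(X.astype(bool), metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(dm.compound_ids), squareform(cond), metric)


def hierarchical_cluster(D: DistanceMatrix, linkage: str = "average") -> DendrogramTree:
    """Agglomerative clustering of a distance matrix (default UPGMA)."""
    if len(D.ids) < 2:
        raise ValueError("need at least 2 compounds to cluster")
    Z = hierarchy.linkage(D.condensed, method=linkage)
    return DendrogramTree(Z, list(D.ids), method=linkage)


def _newick(node, parent_height: float, leaf_ids: list[str]) -> str:
    length = (parent_height - (node.dist if not node.is_leaf() else 0.0)) / 2.0
    if node.is_leaf():
        return f"{leaf_ids[node.id]}:{length:.10g}"
    left = _newick(node.get_left(), node.dist, leaf_ids)
    right = _newick(node.get_right(), node.dist, leaf_ids)
    return f"({left},{right}):{length:.10g}"


def export_dendrogram(tree: DendrogramTree, path: str | Path) -> Path:
    """Write the merge tree as a Newick string with branch lengths."""
    path = Path(path)
    root = hierarchy.to_tree(tree.linkage)
    left = _newick(root.get_left(), root.dist, tree.leaf_ids)
    right = _newick(root.get_right(), root.dist, tree.leaf_ids)
    path.write_text(f"({left},{right});\n")
    return path
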