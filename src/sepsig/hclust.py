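"""Euclidean distances and complete-linkage agglomerative clustering.

Distances may be normalized by the square root of the feature count so
that merge heights are on a per-feature scale and remain comparable when
features are ablated (the leave-one-feature-out analysis relies on this).
The dendrogram keeps the full merge history; the vector of merge heights
is the observed statistic (``D_0``) that the permutation reference
distribution is compared against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .cohort import ClusterAssignment, CohortTable, canonicalize_labels

__all__ = ["DistanceMatrix", "Dendrogram", "pairwise_distance", "agglomerate_complete", "cut_at_height"]


class HClustError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Condensed pairwise Euclidean distances between patients."""

    condensed: np.ndarray
    n: int
    normalized: bool

    def full(self) -> np.ndarray:
        return squareform(self.condensed)


@dataclass
class Dendrogram:
    """Complete merge history, scipy linkage encoding.

    ``merges[k] = (left, right, height)`` where node ids < n are leaves and
    node n + k is the cluster created by merge k.  Complete linkage is
    monotone, so heights are nondecreasing in merge order; the height
    vector is the observed ``D_0``.
    """

    linkage_matrix: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage_matrix, dtype=float)
        if Z.shape != (self.n_leaves - 1, 4):
            raise HClustError("linkage matrix must have n-1 rows")
        if np.any(np.diff(Z[:, 2]) < -1e-12):
            raise HClustError("merge heights must be nondecreasing (monotone linkage)")
        self.linkage_matrix = Z

    @property
    def heights(self) -> np.ndarray:
        """Merge heights in merge order (the observed D_0 vector)."""
        return self.linkage_matrix[:, 2].copy()

    @property
    def root_height(self) -> float:
        return float(self.linkage_matrix[-1, 2])

    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix
        ]

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None):
        payload = {"n_leaves": self.n_leaves, "merges": self.merges()}
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    def to_newick(self, leaf_names=None) -> str:
        """Newick string with branch lengths derived from merge heights."""
        names = (
            [str(x) for x in leaf_names]
            if leaf_names is not None
            else [str(i) for i in range(self.n_leaves)]
        )
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            blen = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{blen:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{blen:.6g}"

        return walk(root, root.dist) + ";"


def pairwise_distance(table: CohortTable, normalize: bool = True) -> DistanceMatrix:
    """Euclidean distances between patient rows.

    With ``normalize`` the distance is divided by sqrt(p) (p = feature
    count), i.e. squared distance is averaged rather than summed over
    features, keeping heights comparable across feature subsets.
    """
    if table.has_missing:
        raise HClustError("distances require an imputed table (no missing cells)")
    d = pdist(table.values, metric="euclidean")
    if normalize:
        d = d / np.sqrt(table.n_features)
    return DistanceMatrix(d, table.n_patients, normalize)


def agglomerate_complete(dist: DistanceMatrix) -> Dendrogram:
    """Complete-linkage agglomeration over the full merge history.

    At every step the pair of clusters with the minimal maximum inter-point
    distance is merged; the merge height is that distance.
    """
    if dist.n < 2:
        raise HClustError("clustering requires at least 2 patients")
    Z = linkage(dist.condensed, method="complete")
    return Dendrogram(Z, dist.n)


def cut_at_height(dend: Dendrogram, h: float) -> ClusterAssignment:
    """Clusters = connected components after discarding merges above ``h``.

    Labels are canonical (size-descending, ties by smallest member index).
    """
    if h < 0:
        raise HClustError("cut height must be nonnegative")
    raw = fcluster(dend.linkage_matrix, t=h, criterion="distance")
    return ClusterAssignment(canonicalize_labels(raw), cut_height=float(h))
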