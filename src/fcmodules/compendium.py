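"""Representative-compendium construction.

A large array collection is reduced to a representative set by
average-linkage hierarchical clustering on correlation distance,
cutting the tree at a height read off a k-nearest-neighbor knee plot,
dropping small clusters, and keeping each surviving cluster's medoid
(the member with minimum summed distance to the rest of its cluster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import DistanceMatrix, ExpressionMatrix


@dataclass
class ClusterTree:
    """Agglomerative merge history in scipy linkage format plus leaf ids."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")


@dataclass
class CompendiumReport:
    cutoff: float
    assignments: dict[str, int]          # sample id -> cluster label
    retained_clusters: list[int]         # labels with size >= min_size
    medoids: dict[int, str]              # retained label -> medoid sample id

    @property
    def medoid_ids(self) -> list[str]:
        return [self.medoids[c] for c in self.retained_clusters]


def average_linkage_tree(d: DistanceMatrix) -> ClusterTree:
    """UPGMA-style agglomeration over the given distances (deterministic)."""
    if d.n < 2:
        raise ValueError("need at least 2 samples to build a tree")
    condensed = squareform(d.values, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return ClusterTree(Z, list(d.sample_ids))


def knn_knee_height(d: DistanceMatrix, k: int, tol: float = 1e-9) -> float:
    """Cut height from the knee of the sorted k-th-nearest-neighbor curve.

    Each sample's distance to its k-th nearest neighbor is computed, the
    values are sorted ascending, and the knee is the point of maximum
    perpendicular distance from the chord joining the curve's endpoints.
    A near-linear curve (no knee) raises; the caller may then supply a
    height manually.
    """
    if k >= d.n:
        raise ValueError("k must be smaller than the number of samples")
    D = d.values.copy()
    np.fill_diagonal(D, np.inf)
    kth = np.sort(D, axis=1)[:, k - 1]
    curve = np.sort(kth)
    m = curve.size
    x = np.arange(m, dtype=float)
    p0 = np.array([x[0], curve[0]])
    p1 = np.array([x[-1], curve[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        raise ValueError("no knee detected: degenerate curve")
    # perpendicular distance of every curve point from the chord
    dist = np.abs(chord[0] * (curve - p0[1]) - chord[1] * (x - p0[0])) / norm
    if dist.max() < tol:
        raise ValueError("no knee detected: curve is near-linear")
    return float(curve[int(np.argmax(dist))])


def cut_filter_medoids(tree: ClusterTree, d: DistanceMatrix, height: float,
                       min_size: int = 5) -> CompendiumReport:
    """Cut the tree at `height`, drop clusters below `min_size`, pick medoids.

    Cluster labels are renumbered in order of first-occurring sample
    index; medoid ties break to the smallest sample index.
    """
    if height < 0:
        raise ValueError("height must be nonnegative")
    raw = hierarchy.fcluster(tree.linkage, t=height, criterion="distance")
    # relabel by first occurrence
    label_map: dict[int, int] = {}
    for lab in raw:
        if lab not in label_map:
            label_map[lab] = len(label_map)
    labels = np.array([label_map[lab] for lab in raw])
    assignments = dict(zip(tree.leaf_ids, (int(v) for v in labels)))

    retained: list[int] = []
    medoids: dict[int, str] = {}
    for c in range(labels.max() + 1):
        members = np.flatnonzero(labels == c)
        if members.size < min_size:
            continue
        sub = d.values[np.ix_(members, members)]
        totals = sub.sum(axis=1)
        med = members[int(np.argmin(totals))]  # argmin takes the first minimum
        retained.append(c)
        medoids[c] = tree.leaf_ids[med]
    if not retained:
        warnings.warn("no cluster survived the size filter", stacklevel=2)
    return CompendiumReport(float(height), assignments, retained, medoids)


def representative_compendium(m: ExpressionMatrix, d: DistanceMatrix,
                              height: float | None = None, k: int = 4,
                              min_size: int = 5) -> tuple[ExpressionMatrix, CompendiumReport]:
    """End-to-end reduction: tree, cut height (knee unless given), medoids."""
    tree = average_linkage_tree(d)
    if height is None:
        height = knn_knee_height(d, k)
    report = cut_filter_medoids(tree, d, height, min_size)
    if not report.retained_clusters:
        return m.subset_samples([]), report
    return m.subset_samples(report.medoid_ids), report
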