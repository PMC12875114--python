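"""Density-based clustering of localization clouds and per-cluster geometry.

Condensed chromatin signals are identified with DBSCAN on the 3D Euclidean
coordinates: a point with at least ``min_pts`` neighbors within ``eps``
(counting itself) is a core point; core points connected through chains of
eps-neighborhoods form one cluster; non-core points within ``eps`` of a
core point are border points; everything else is noise (label -1).

The implementation is deterministic: border points take the label of the
lowest-uid core point that reaches them, so repeated runs on the same
table are bit-identical.  Cluster geometry (principal axes and the
long-axis length used as the fiber length measure) comes from the
eigendecomposition of the member covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


@dataclass
class ClusterLabeling:
    """DBSCAN output: one integer label per input point, -1 for noise."""

    labels: np.ndarray
    eps: float
    min_pts: int
    core_mask: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) and self.labels.max() >= 0 else 0


@dataclass
class Cluster:
    """Geometry of one cluster of localizations."""

    label: int
    member_indices: np.ndarray
    centroid: np.ndarray
    axes: np.ndarray  # (3, 3): rows are orthonormal axes, decreasing spread
    extents: np.ndarray  # projection range (max - min) along each axis, nm
    degenerate: bool = False

    @property
    def long_axis_length(self) -> float:
        return float(self.extents[0])


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> ClusterLabeling:
    """Cluster 3D points by density reachability.

    Labels are consecutive integers assigned in order of the smallest uid
    (row index) contained in each cluster; ties in border-point assignment
    are broken toward the lowest-uid core neighbor.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    if n == 0:
        return ClusterLabeling(np.empty(0, int), eps, min_pts, np.empty(0, bool))

    tree = cKDTree(points)
    neighbors = tree.query_ball_tree(tree, eps)  # closed balls, includes self
    counts = np.array([len(nb) for nb in neighbors])
    core = counts >= min_pts
    core_idx = np.flatnonzero(core)

    labels = np.full(n, -1, int)
    if len(core_idx):
        # connected components over the eps-graph restricted to core points
        pos = {int(i): k for k, i in enumerate(core_idx)}
        rows, cols = [], []
        for k, i in enumerate(core_idx):
            for j in neighbors[i]:
                if core[j]:
                    rows.append(k)
                    cols.append(pos[j])
        graph = csr_matrix(
            (np.ones(len(rows), bool), (rows, cols)), shape=(len(core_idx),) * 2
        )
        _, comp = connected_components(graph, directed=False)
        # relabel components by their smallest member uid for determinism
        order = {}
        for k in np.argsort(core_idx):
            order.setdefault(comp[k], len(order))
        for k, i in enumerate(core_idx):
            labels[i] = order[comp[k]]
        # border points: lowest-uid core neighbor wins
        for i in np.flatnonzero(~core):
            core_nb = [j for j in sorted(neighbors[i]) if core[j]]
            if core_nb:
                labels[i] = labels[core_nb[0]]
    return ClusterLabeling(labels, eps, min_pts, core)


def cluster_geometry(points: np.ndarray, labeling: ClusterLabeling) -> list[Cluster]:
    """Centroid, principal axes and extents for every cluster in a labeling.

    Clusters with fewer than 3 members in 3D have under-determined minor
    axes; they are flagged degenerate and returned with zero minor extents.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) != len(labeling.labels):
        raise ValueError("labeling does not match the point set")
    out: list[Cluster] = []
    for label in range(labeling.n_clusters):
        idx = np.flatnonzero(labeling.labels == label)
        members = points[idx]
        centroid = members.mean(axis=0)
        centered = members - centroid
        degenerate = len(members) < 3
        if degenerate and len(members) == 1:
            axes = np.eye(3)
        else:
            cov = centered.T @ centered / max(len(members) - 1, 1)
            evals, evecs = np.linalg.eigh(cov)
            axes = evecs[:, ::-1].T  # rows, decreasing eigenvalue
        proj = centered @ axes.T
        extents = proj.max(axis=0) - proj.min(axis=0) if len(members) else np.zeros(3)
        if degenerate:
            extents[1:] = 0.0
        out.append(Cluster(label, idx, centroid, axes, extents, degenerate))
    return out


def local_density(points: np.ndarray, radius: float) -> np.ndarray:
    """Neighbor count within a closed ball of ``radius`` nm, excluding self."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    points = np.atleast_2d(np.asarray(points, float))
    if len(points) == 0:
        return np.empty(0, int)
    tree = cKDTree(points)
    counts = np.array([len(nb) - 1 for nb in tree.query_ball_tree(tree, radius)])
    return counts
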