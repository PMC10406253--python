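"""Density-based voxel cluster detection within single axial slices.

Active voxels of a binarized slice are scanned with a density rule: a voxel
with strictly more than ``v_min`` other active voxels inside its ``eps``
neighborhood is a *core* voxel.  A non-core voxel lying within ``eps`` of a
core voxel is a *border* voxel and joins the cluster of its nearest core
voxel; every remaining active voxel is discarded.  Core voxels within
``eps`` of each other belong to the same cluster.  Clustering is strictly
2D, one slice at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = ["VoxelCluster", "binarize_slice", "detect_clusters", "largest_cluster"]


@dataclass(frozen=True)
class VoxelCluster:
    """A connected set of core and border voxels in one slice."""

    voxels: frozenset
    core: frozenset
    border: frozenset
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.core | self.border != self.voxels or (self.core & self.border):
            raise ValueError("core and border must partition the voxel set")
        if not self.voxels:
            raise ValueError("a cluster contains at least one voxel")

    @property
    def size(self) -> int:
        return len(self.voxels)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the cluster on a grid of the given shape."""
        m = np.zeros(shape, dtype=bool)
        idx = np.array(sorted(self.voxels))
        m[idx[:, 0], idx[:, 1]] = True
        return m

    def min_voxel(self) -> tuple[int, int]:
        return min(self.voxels)


def binarize_slice(slice_values: np.ndarray, z_threshold: float) -> np.ndarray:
    """Mask of voxels with ``|z| >= z_threshold`` (both signs retained)."""
    slice_values = np.asarray(slice_values)
    if not np.all(np.isfinite(slice_values)):
        raise ValueError("slice contains non-finite values")
    return np.abs(slice_values) >= z_threshold


def _metric_p(metric: str) -> float:
    if metric == "euclidean":
        return 2.0
    if metric == "chebyshev":
        return np.inf
    if metric == "manhattan":
        return 1.0
    raise ValueError(f"unsupported metric {metric!r}")


def detect_clusters(
    mask: np.ndarray,
    eps: float,
    v_min: int,
    metric: str = "euclidean",
    slice_index: int = 0,
) -> list[VoxelCluster]:
    """Partition the active voxels of ``mask`` into density clusters.

    Returns clusters ordered by their lexicographically smallest voxel, so
    the result is independent of voxel visitation order.  An empty mask
    yields an empty list.

    Border voxels equidistant from core voxels of different clusters are
    assigned to the cluster of the core voxel with the smallest ``(x, y)``
    coordinate, which keeps the partition deterministic.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if v_min < 1:
        raise ValueError("v_min must be >= 1")
    pts = np.argwhere(np.asarray(mask, dtype=bool))
    if pts.shape[0] == 0:
        return []
    p = _metric_p(metric)
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=eps, p=p)
    # query_ball_point includes the voxel itself; the density rule counts
    # strictly more than v_min *other* voxels.
    n_other = np.array([len(nb) - 1 for nb in neighbors])
    is_core = n_other > v_min

    n = pts.shape[0]
    core_idx = np.flatnonzero(is_core)
    if core_idx.size == 0:
        return []

    # Union core voxels that are mutual eps-neighbors.
    rows, cols = [], []
    core_set = set(core_idx.tolist())
    for i in core_idx:
        for j in neighbors[i]:
            if j in core_set:
                rows.append(i)
                cols.append(j)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, comp = connected_components(graph, directed=False)

    cluster_of = np.full(n, -1, dtype=int)
    cluster_of[core_idx] = comp[core_idx]

    # Border voxels: nearest core voxel within eps, ties broken by the core
    # voxel's (x, y) order.
    for i in np.flatnonzero(~is_core):
        best = None
        for j in neighbors[i]:
            if not is_core[j]:
                continue
            if p == np.inf:
                d = float(np.max(np.abs(pts[i] - pts[j])))
            else:
                d = float(np.linalg.norm(pts[i] - pts[j], ord=p))
            key = (d, int(pts[j][0]), int(pts[j][1]))
            if best is None or key < best[0]:
                best = (key, j)
        if best is not None:
            cluster_of[i] = cluster_of[best[1]]

    clusters = []
    for label in np.unique(cluster_of[cluster_of >= 0]):
        members = np.flatnonzero(cluster_of == label)
        vox = frozenset((int(pts[i][0]), int(pts[i][1])) for i in members)
        core = frozenset(
            (int(pts[i][0]), int(pts[i][1])) for i in members if is_core[i]
        )
        clusters.append(
            VoxelCluster(
                voxels=vox, core=core, border=vox - core, slice_index=slice_index
            )
        )
    clusters.sort(key=lambda c: c.min_voxel())
    return clusters


def largest_cluster(clusters) -> VoxelCluster | None:
    """The cluster with maximal size, or None for an empty collection.

    Size ties go to the cluster whose lexicographically smallest voxel
    coordinate is smallest.
    """
    clusters = list(clusters)
    if not clusters:
        return None
    return min(clusters, key=lambda c: (-c.size, c.min_voxel()))
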