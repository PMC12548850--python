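"""Point-cloud container, denoising, and PLY I/O.

Clouds arriving from the depth camera are accumulated over ~30 frames to
densify coverage, which also multiplies noise.  The cleaning recipe is:

1. voxel downsampling (keep the first point, in input order, per occupied
   voxel cell),
2. statistical local-outlier removal: per point, the mean Euclidean
   distance to its k nearest neighbors; points whose mean distance exceeds
   the population mean by ``sigma_mult`` standard deviations are dropped
   (a 2-sigma variant of the 3-sigma rule), and
3. a similarity transform to real-world scale.

kNN queries use a KD-tree and always exclude the query point itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "OutlierParams",
    "accumulate_frames",
    "voxel_downsample",
    "remove_outliers",
    "world_transform",
    "read_ply",
    "write_ply",
]


@dataclass
class PointCloud:
    """N points in meters with optional 8-bit per-point RGB colors."""

    points: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != len(self.points):
                raise ValueError("colors must match point count")

    def __len__(self) -> int:
        return len(self.points)

    def take(self, index: np.ndarray) -> "PointCloud":
        cols = self.colors[index] if self.colors is not None else None
        return PointCloud(self.points[index], cols)


@dataclass(frozen=True)
class OutlierParams:
    """k nearest neighbors (default 30) and sigma threshold (default 2)."""

    k: int = 30
    sigma_mult: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.sigma_mult <= 0:
            raise ValueError("sigma_mult must be positive")


def accumulate_frames(frames: list[PointCloud]) -> PointCloud:
    """Aggregate near-simultaneous frames into one cloud.

    Points that coincide exactly (bitwise-equal coordinates) across frames
    are retained as a single point; the first occurrence, in frame order,
    keeps its color.  Near-duplicates are left for voxel downsampling.
    """
    if not frames:
        raise ValueError("need at least one frame")
    pts = np.vstack([f.points for f in frames])
    have_colors = all(f.colors is not None for f in frames)
    cols = np.vstack([f.colors for f in frames]) if have_colors else None
    _, first = np.unique(pts, axis=0, return_index=True)
    first.sort()
    return PointCloud(pts[first], cols[first] if cols is not None else None)


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> PointCloud:
    """Keep the first input point landing in each voxel cell.

    Voxel index is ``floor(coordinate / voxel_size)`` per axis, anchored at
    the origin; boundary points fall in the lower-index cell.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if len(cloud) == 0:
        return cloud
    idx3 = np.floor(cloud.points / voxel_size).astype(np.int64)
    _, first = np.unique(idx3, axis=0, return_index=True)
    first.sort()
    return cloud.take(first)


def mean_knn_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Mean Euclidean distance from each point to its k nearest neighbors
    (query point excluded)."""
    tree = cKDTree(points)
    # k+1 because the closest hit is the query point itself (distance 0)
    dists, _ = tree.query(points, k=k + 1)
    return dists[:, 1:].mean(axis=1)


def remove_outliers(cloud: PointCloud, params: OutlierParams = OutlierParams()
                    ) -> tuple[PointCloud, np.ndarray]:
    """Drop points whose mean kNN distance exceeds mean + sigma_mult*std.

    The mean and standard deviation are taken globally over the per-point
    mean distances.  Returns the kept cloud and the removed indices (into
    the input).  Clouds with N <= k are returned unchanged with a warning:
    the neighborhood statistic is undefined there.
    """
    n = len(cloud)
    if n <= params.k:
        logger.warning("remove_outliers: N=%d <= k=%d, cloud unchanged",
                       n, params.k)
        return cloud, np.empty(0, dtype=int)
    d = mean_knn_distances(cloud.points, params.k)
    threshold = d.mean() + params.sigma_mult * d.std()
    removed = np.nonzero(d > threshold)[0]
    kept = np.nonzero(d <= threshold)[0]
    return cloud.take(kept), removed


def world_transform(cloud: PointCloud, T: np.ndarray, scale: float = 1.0
                    ) -> PointCloud:
    """Similarity transform to world scale: ``scale * (T @ [x y z 1])``."""
    T = np.asarray(T, dtype=float)
    if T.shape != (4, 4):
        raise ValueError("T must be 4x4")
    if scale <= 0:
        raise ValueError("scale must be positive")
    homo = np.hstack([cloud.points, np.ones((len(cloud), 1))])
    pts = scale * (homo @ T.T)[:, :3]
    return PointCloud(pts, cloud.colors)


def read_ply(path) -> PointCloud:
    """Load an XYZ(+RGB) point cloud from a binary or ASCII PLY file."""
    import trimesh

    mesh = trimesh.load(str(path), process=False)
    pts = np.asarray(mesh.vertices, dtype=float)
    colors = None
    try:
        c = np.asarray(mesh.colors)
        if c.size:
            colors = c[:, :3].astype(np.uint8)
    except (AttributeError, ValueError, IndexError):
        pass
    return PointCloud(pts, colors)


def write_ply(cloud: PointCloud, path) -> None:
    """Write a point cloud as PLY, preserving per-point colors if present."""
    import trimesh

    pc = trimesh.PointCloud(cloud.points, colors=cloud.colors)
    pc.export(str(path))
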