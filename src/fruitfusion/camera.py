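"""Pinhole camera model and 3D-to-2D alignment.

The depth camera delivers a point cloud in a camera-attached frame.  To
align cloud points with color-image pixels the pipeline applies, per point:

1. extrinsic transform into the camera frame (identity for a single rig),
2. pinhole projection ``u = x*fx/z + cx``, ``v = y*fy/z + cy``,
3. a horizontal mirror flip ``u' = mw - 1 - u`` (the projection of this
   sensor is a mirror mapping), and
4. additive per-dataset offset correction ``(uo, vo) = (u' + xoffset,
   v + yoffset)``.

All pixel coordinates are 0-based ``(u=column, v=row)``; in-image tests use
half-open bounds ``[0, mw) x [0, mh)``.  Rounding to integer pixels happens
only at rasterization, never inside the projection math.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CameraIntrinsics",
    "Extrinsics",
    "ProjectionOffsets",
    "to_camera",
    "project",
    "mirror_u",
    "offset_correct",
    "project_cloud",
    "back_project",
    "mark_points_in_boxes",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float
    mw: int  # image width, pixels
    mh: int  # image height, pixels

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.mw and 0 <= self.cy < self.mh):
            raise ValueError("principal point must lie inside the image")
        if self.mw < 1 or self.mh < 1:
            raise ValueError("image dimensions must be positive")

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix [[fx,0,cx],[0,fy,cy],[0,0,1]]."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


def _identity4() -> np.ndarray:
    return np.eye(4)


@dataclass(frozen=True)
class Extrinsics:
    """Rigid world-to-camera transform as a 4x4 homogeneous matrix.

    Defaults to the identity: for a single fixed rig the cloud is already
    expressed in the camera frame.
    """

    E: np.ndarray = field(default_factory=_identity4)

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        if E.shape != (4, 4):
            raise ValueError("extrinsics must be a 4x4 matrix")
        if not np.allclose(E[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("bottom row of extrinsics must be (0,0,0,1)")
        object.__setattr__(self, "E", E)


@dataclass(frozen=True)
class ProjectionOffsets:
    """Additive pixel corrections calibrated per dataset (default none)."""

    xoffset: float = 0.0
    yoffset: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.xoffset) and np.isfinite(self.yoffset)):
            raise ValueError("offsets must be finite")


def to_camera(points: np.ndarray, extrinsics: Extrinsics) -> np.ndarray:
    """Map (N,3) or (3,) world points into the camera frame.

    Returns the first three components of ``E @ [x y z 1]``.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    homo = np.hstack([p, np.ones((p.shape[0], 1))])
    cam = homo @ extrinsics.E.T
    out = cam[:, :3]
    return out[0] if np.asarray(points).ndim == 1 else out


def project(p_cam: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Project camera-frame points onto the image plane (no mirror/offset).

    ``u = x*fx/z + cx``, ``v = y*fy/z + cy``.  Raises for any point with
    ``z <= 0`` (behind the camera).
    """
    p = np.atleast_2d(np.asarray(p_cam, dtype=float))
    z = p[:, 2]
    if np.any(z <= 0):
        raise ValueError("cannot project points with z <= 0 (behind camera)")
    u = p[:, 0] * intr.fx / z + intr.cx
    v = p[:, 1] * intr.fy / z + intr.cy
    uv = np.column_stack([u, v])
    return uv[0] if np.asarray(p_cam).ndim == 1 else uv


def mirror_u(u, mw: int):
    """Horizontal mirror flip ``u' = mw - 1 - u`` (an involution)."""
    if mw < 1:
        raise ValueError("mw must be >= 1")
    return mw - 1 - np.asarray(u, dtype=float) if np.ndim(u) else mw - 1 - u


def offset_correct(u_prime, v, offsets: ProjectionOffsets):
    """Apply the calibration offsets: ``(uo, vo) = (u'+xoff, v+yoff)``."""
    return u_prime + offsets.xoffset, v + offsets.yoffset


def _full_chain(points: np.ndarray, intr: CameraIntrinsics,
                extrinsics: Extrinsics, offsets: ProjectionOffsets):
    """Project (N,3) points through the full chain.

    Returns (uo, vo, z_cam) arrays; points with z_cam <= 0 get NaN pixels.
    """
    cam = to_camera(np.atleast_2d(points), extrinsics)
    z = cam[:, 2]
    valid = z > 0
    u = np.full(len(cam), np.nan)
    v = np.full(len(cam), np.nan)
    u[valid] = cam[valid, 0] * intr.fx / z[valid] + intr.cx
    v[valid] = cam[valid, 1] * intr.fy / z[valid] + intr.cy
    u_prime = intr.mw - 1 - u
    uo, vo = offset_correct(u_prime, v, offsets)
    return uo, vo, z


def back_project(u, v, z, intr: CameraIntrinsics,
                 extrinsics: Extrinsics | None = None,
                 offsets: ProjectionOffsets | None = None,
                 mirrored: bool = True) -> np.ndarray:
    """Invert the full projection chain at known depth.

    Given corrected pixel coordinates ``(u, v)`` and camera-frame depth
    ``z``, recover the world point that the chain maps back onto them.
    With ``mirrored=False`` the mirror-flip step is skipped (plain pinhole
    inverse).
    """
    offsets = offsets or ProjectionOffsets()
    u = np.asarray(u, dtype=float) - offsets.xoffset
    v = np.asarray(v, dtype=float) - offsets.yoffset
    if mirrored:
        u = intr.mw - 1 - u
    z = np.asarray(z, dtype=float)
    x = z * (u - intr.cx) / intr.fx
    y = z * (v - intr.cy) / intr.fy
    cam = np.stack(np.broadcast_arrays(x, y, z), axis=-1)
    if extrinsics is not None and not np.allclose(extrinsics.E, np.eye(4)):
        inv = np.linalg.inv(extrinsics.E)
        flat = cam.reshape(-1, 3)
        homo = np.hstack([flat, np.ones((len(flat), 1))])
        cam = (homo @ inv.T)[:, :3].reshape(cam.shape)
    return cam


def project_cloud(cloud, intr: CameraIntrinsics,
                  extrinsics: Extrinsics | None = None,
                  offsets: ProjectionOffsets | None = None):
    """Project every cloud point through the full chain.

    Returns ``(indices, pixels, n_excluded)`` where ``indices`` selects the
    points whose corrected pixel lies inside ``[0,mw) x [0,mh)`` with
    positive camera depth, ``pixels`` is the matching (M,2) float array of
    (u, v), and ``n_excluded`` counts dropped points (behind camera or
    outside the raster).  Dropped points are never clamped.
    """
    extrinsics = extrinsics or Extrinsics()
    offsets = offsets or ProjectionOffsets()
    pts = np.asarray(cloud.points if hasattr(cloud, "points") else cloud,
                     dtype=float)
    if len(pts) == 0:
        logger.warning("project_cloud called with an empty cloud")
        return np.empty(0, dtype=int), np.empty((0, 2)), 0
    uo, vo, z = _full_chain(pts, intr, extrinsics, offsets)
    inside = (z > 0) & (uo >= 0) & (uo < intr.mw) & (vo >= 0) & (vo < intr.mh)
    idx = np.nonzero(inside)[0]
    return idx, np.column_stack([uo[idx], vo[idx]]), int(len(pts) - len(idx))


def rasterize_pixel(u, v):
    """Round continuous pixel coordinates half-away-from-zero to ints."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ru = np.sign(u) * np.floor(np.abs(u) + 0.5)
    rv = np.sign(v) * np.floor(np.abs(v) + 0.5)
    return ru.astype(int), rv.astype(int)


def mark_points_in_boxes(cloud, boxes, intr: CameraIntrinsics,
                         extrinsics: Extrinsics | None = None,
                         offsets: ProjectionOffsets | None = None):
    """Color black every point projecting into any pixel-space rectangle.

    ``boxes`` is a sequence of ``(u_min, v_min, u_max, v_max)`` rectangles
    (inclusive of min, exclusive of max).  Used for visual verification of
    the 2D-3D alignment: annotated fruit regions should come back as black
    blobs on the cloud.  Coordinates are never modified, only colors.
    """
    from .pointcloud import PointCloud  # local import avoids a cycle

    pts = np.asarray(cloud.points, dtype=float)
    colors = (np.array(cloud.colors, dtype=np.uint8, copy=True)
              if cloud.colors is not None
              else np.full((len(pts), 3), 255, dtype=np.uint8))
    if len(boxes) == 0:
        return PointCloud(pts.copy(), colors)
    idx, pix, _ = project_cloud(cloud, intr, extrinsics, offsets)
    if len(idx):
        u, v = pix[:, 0], pix[:, 1]
        hit = np.zeros(len(idx), dtype=bool)
        for (u0, v0, u1, v1) in boxes:
            hit |= (u >= u0) & (u < u1) & (v >= v0) & (v < v1)
        colors[idx[hit]] = 0
    return PointCloud(pts.copy(), colors)
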