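"""Depth decoding, XYZ rasterization, and 8-channel composition.

The detector consumes a stacked raster with fixed band order
``[R, G, B, F, D, X, Y, Z]``: appearance (RGB scaled to [0,1]), the fused
key-feature band F, metric depth D from the 16-bit depth raster, and the
per-pixel 3D coordinates of the aligned point cloud.  Pixels never hit by
a cloud point hold zeros in D/X/Y/Z — zero-filling keeps the raster dense
without inventing geometry.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import (CameraIntrinsics, Extrinsics, ProjectionOffsets,
                     project_cloud, rasterize_pixel)

logger = logging.getLogger(__name__)

BAND_NAMES = ("R", "G", "B", "F", "D", "X", "Y", "Z")

MAX_DEPTH_M = 4.0  # sensor's stated valid range

__all__ = [
    "BAND_NAMES",
    "MAX_DEPTH_M",
    "MultiChannelImage",
    "decode_depth",
    "xyz_raster",
    "compose",
    "write_container",
    "read_container",
]


@dataclass
class MultiChannelImage:
    """H x W x 8 raster with named bands and provenance metadata."""

    bands: np.ndarray
    band_names: tuple = BAND_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float32)
        if self.bands.ndim != 3 or self.bands.shape[2] != len(self.band_names):
            raise ValueError(
                f"expected HxWx{len(self.band_names)} bands, "
                f"got {self.bands.shape}")
        if not np.all(np.isfinite(self.bands)):
            raise ValueError("bands must be finite")

    def band(self, name: str) -> np.ndarray:
        return self.bands[..., self.band_names.index(name)]

    @property
    def shape(self):
        return self.bands.shape


def decode_depth(z16: np.ndarray) -> np.ndarray:
    """Convert a Z16 millimeter raster to meters, zeroing invalid samples.

    Raw value 0 is no-data; decoded depths beyond the sensor's 4 m valid
    range are also treated as no-data (set to 0).
    """
    z16 = np.asarray(z16)
    if z16.dtype != np.uint16:
        raise ValueError(f"depth raster must be uint16 (Z16), got {z16.dtype}")
    if z16.ndim != 2:
        raise ValueError("depth raster must be single-band")
    meters = z16.astype(np.float32) / 1000.0
    meters[(z16 == 0) | (meters > MAX_DEPTH_M)] = 0.0
    return meters


def xyz_raster(cloud, intr: CameraIntrinsics,
               extrinsics: Extrinsics | None = None,
               offsets: ProjectionOffsets | None = None,
               shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize a cloud into per-pixel (X, Y, Z) coordinate bands.

    Each point is pushed through the full projection chain and its world
    coordinates stored at the hit pixel.  When several points land on one
    pixel the nearest (smallest camera depth) wins — the occlusion-correct
    choice.  Unsampled pixels hold (0, 0, 0).
    """
    h, w = shape if shape is not None else (intr.mh, intr.mw)
    out = np.zeros((h, w, 3), dtype=np.float32)
    pts = np.asarray(cloud.points if hasattr(cloud, "points") else cloud,
                     dtype=float)
    if len(pts) == 0:
        logger.warning("xyz_raster: empty cloud, returning zero bands")
        return out
    idx, pix, _ = project_cloud(cloud, intr, extrinsics, offsets)
    if len(idx) == 0:
        return out
    u, v = rasterize_pixel(pix[:, 0], pix[:, 1])
    inside = (u >= 0) & (u < w) & (v >= 0) & (v < h)
    idx, u, v = idx[inside], u[inside], v[inside]
    z = pts[idx, 2]
    # nearest-depth-wins: process points far-to-near so near overwrites far
    order = np.argsort(-z, kind="stable")
    out[v[order], u[order]] = pts[idx[order]].astype(np.float32)
    return out


def compose(rgb: np.ndarray, F: np.ndarray, D: np.ndarray,
            XYZ: np.ndarray, meta: dict | None = None) -> MultiChannelImage:
    """Stack [R,G,B,F,D,X,Y,Z]; RGB is scaled from 8-bit to [0,1]."""
    parts = {"RGB": rgb, "F": F, "D": D, "XYZ": XYZ}
    for name, arr in parts.items():
        if arr is None:
            raise ValueError(f"missing band input: {name}")
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("RGB: expected an HxWx3 image")
    hw = rgb.shape[:2]
    for name, arr in (("F", F), ("D", D)):
        if np.asarray(arr).shape != hw:
            raise ValueError(f"{name}: shape {np.asarray(arr).shape} "
                             f"does not match RGB {hw}")
    XYZ = np.asarray(XYZ)
    if XYZ.shape != hw + (3,):
        raise ValueError(f"XYZ: shape {XYZ.shape} does not match RGB {hw}")
    bands = np.dstack([rgb.astype(np.float32) / 255.0,
                       np.asarray(F, dtype=np.float32),
                       np.asarray(D, dtype=np.float32),
                       XYZ.astype(np.float32)])
    return MultiChannelImage(bands, meta=dict(meta or {}))


def write_container(img: MultiChannelImage, path) -> None:
    """Write bands as a raw little-endian float32 blob + JSON sidecar.

    The sidecar (``<path>.json``) carries shape, dtype, band names, and the
    provenance metadata (calibration, preprocessing parameters) so a scene
    round-trips losslessly and stays readable from any language.
    """
    path = Path(path)
    data = np.ascontiguousarray(img.bands, dtype="<f4")
    path.write_bytes(data.tobytes())
    sidecar = {
        "shape": list(img.bands.shape),
        "dtype": "<f4",
        "band_names": list(img.band_names),
        "meta": img.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_container(path) -> MultiChannelImage:
    """Inverse of :func:`write_container` (bitwise round trip)."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing band-metadata sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("shape", "dtype", "band_names"):
        if key not in sidecar:
            raise ValueError(f"corrupt sidecar: missing '{key}'")
    shape = tuple(sidecar["shape"])
    data = np.frombuffer(path.read_bytes(), dtype=sidecar["dtype"])
    if data.size != int(np.prod(shape)):
        raise ValueError(
            f"container size {data.size} does not match sidecar shape {shape}")
    return MultiChannelImage(data.reshape(shape).copy(),
                             band_names=tuple(sidecar["band_names"]),
                             meta=sidecar.get("meta", {}))
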