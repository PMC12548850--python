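"""Key fruit-feature extraction from RGB imagery.

Red fruit on green foliage separates well in the R-G chroma difference;
object contours show up in the Laplacian of the grayscale image.  The two
maps, each min-max normalized to [0,1], are fused as a convex combination
(default weights 0.6 chroma / 0.4 edge) into a single key-feature band F
that rides alongside RGB in the multi-channel detector input.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "rg_chroma_map",
    "edge_map",
    "normalize_map",
    "key_feature",
    "key_feature_from_rgb",
    "LAPLACIAN_4",
    "LAPLACIAN_8",
    "BT601_WEIGHTS",
]

# 4-neighbor Laplacian; the 8-neighbor variant is available via `kernel=`.
LAPLACIAN_4 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
LAPLACIAN_8 = np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=float)

# ITU-R BT.601 luma weights for grayscale conversion.
BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])


def _check_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {rgb.shape}")
    return rgb


def rg_chroma_map(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel R - G difference, negatives clipped to zero.

    Computed in a widened integer range so 8-bit wraparound cannot occur.
    Green-dominant pixels (foliage, sky) carry no red-fruit signal and are
    zeroed rather than kept as negative responses.
    """
    rgb = _check_rgb(rgb)
    diff = rgb[..., 0].astype(np.int32) - rgb[..., 1].astype(np.int32)
    return np.clip(diff, 0, None).astype(float)


def grayscale(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma of an 8-bit RGB image (float, same range)."""
    return _check_rgb(rgb).astype(float) @ BT601_WEIGHTS


def edge_map(rgb: np.ndarray, kernel: np.ndarray = LAPLACIAN_4) -> np.ndarray:
    """Magnitude of the Laplacian of the grayscale image.

    The absolute value of the second-derivative response is returned, so
    both sides of an intensity step register as edges.  Borders use
    nearest-neighbor extension.
    """
    gray = grayscale(rgb)
    resp = ndimage.convolve(gray, kernel, mode="nearest")
    return np.abs(resp)


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Min-max scale to [0,1]; a constant map normalizes to all zeros."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("feature map must be finite")
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def key_feature(chroma: np.ndarray, edge: np.ndarray,
                w_chroma: float = 0.6, w_edge: float = 0.4) -> np.ndarray:
    """Weighted fusion F = w_chroma*chroma + w_edge*edge of normalized maps.

    The default 6:4 weighting favors the chroma cue, with the edge map
    recovering fruit contours washed out under difficult lighting.
    """
    chroma = np.asarray(chroma, dtype=float)
    edge = np.asarray(edge, dtype=float)
    if chroma.shape != edge.shape:
        raise ValueError(
            f"shape mismatch: chroma {chroma.shape} vs edge {edge.shape}")
    if abs(w_chroma + w_edge - 1.0) > 1e-9:
        raise ValueError("fusion weights must sum to 1")
    return w_chroma * chroma + w_edge * edge


def key_feature_from_rgb(rgb: np.ndarray, w_chroma: float = 0.6,
                         w_edge: float = 0.4,
                         kernel: np.ndarray = LAPLACIAN_4) -> np.ndarray:
    """Full chain: chroma and edge maps, each normalized, then fused."""
    chroma = normalize_map(rg_chroma_map(rgb))
    edges = normalize_map(edge_map(rgb, kernel))
    return key_feature(chroma, edges, w_chroma, w_edge)
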