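"""Synthetic orchard scenes with pinhole-consistent RGB, depth, and cloud.

Real orchard captures pair an 8-bit color frame with a Z16 depth raster
and an accumulated point cloud; no such dataset ships with this package,
so this module renders stand-in scenes: red quasi-spherical fruits over
green/brown clutter (leaves, branches) on a background plane, under a
per-scene global illumination gain.  Depth raster and point cloud are
derived from the same z-buffer through the inverse of the full projection
chain (including the mirror flip), so every stage of the pipeline — cloud
cleaning, alignment, rasterization — sees mutually consistent inputs.

Labeling follows orchard annotation practice: a fruit whose obscured area
exceeds 80% of its projected area is omitted from the labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import CameraIntrinsics, back_project
from .pointcloud import PointCloud

__all__ = [
    "SYNTH_INTRINSICS",
    "SceneParams",
    "SyntheticScene",
    "generate_scene",
    "inject_cloud_noise",
    "make_dataset",
]

# Synthetic rig: a quarter-resolution analogue of the 848x480 RGB-D camera
# (focal length scaled accordingly) so full scenes stay desk-sized.
SYNTH_INTRINSICS = CameraIntrinsics(fx=200.0, fy=200.0, cx=106.0, cy=60.0,
                                    mw=212, mh=120)


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic orchard scene.

    Fruits are apple-sized spheres (3-6 cm radius) hanging 0.6-2.0 m from
    the camera; the illumination gain spans roughly the brightness spread
    of dawn-to-noon captures; occlusion_prob controls how often a leaf
    partially covers a fruit.
    """

    n_fruits: int = 6
    fruit_radius: tuple = (0.03, 0.06)       # meters
    depth_range: tuple = (0.6, 2.0)          # meters
    illumination: tuple = (0.5, 1.3)         # per-scene RGB gain range
    occlusion_prob: float = 0.35
    clutter_density: int = 40                # background/foreground elements
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fruits < 0:
            raise ValueError("n_fruits must be nonnegative")
        for name in ("fruit_radius", "depth_range", "illumination"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if not (0 <= self.occlusion_prob <= 1):
            raise ValueError("occlusion_prob must be in [0, 1]")


@dataclass
class SyntheticScene:
    """One rendered scene plus its ground truth."""

    rgb: np.ndarray            # (H, W, 3) uint8
    depth_raw: np.ndarray      # (H, W) uint16, millimeters (Z16)
    cloud: PointCloud          # back-projected from the same z-buffer
    labels: np.ndarray         # (n, 4) normalized YOLO cx cy w h
    truth: dict = field(default_factory=dict)

    @property
    def labels_px(self) -> np.ndarray:
        """Labels as pixel-space (cx, cy, w, h)."""
        h, w = self.rgb.shape[:2]
        if len(self.labels) == 0:
            return np.empty((0, 4))
        return self.labels * np.array([w, h, w, h])


def _draw_ellipse(depth_buf, color_buf, id_buf, cx, cy, ax, ay, angle,
                  depth, color, elem_id):
    """Paint a rotated ellipse into the z-buffers where it is nearest."""
    h, w = depth_buf.shape
    r = int(np.ceil(max(ax, ay))) + 1
    u0, u1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    v0, v1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if u0 >= u1 or v0 >= v1:
        return
    uu, vv = np.meshgrid(np.arange(u0, u1), np.arange(v0, v1))
    du, dv = uu - cx, vv - cy
    ca, sa = np.cos(angle), np.sin(angle)
    e = ((du * ca + dv * sa) / ax) ** 2 + ((-du * sa + dv * ca) / ay) ** 2
    mask = (e <= 1.0) & (depth < depth_buf[v0:v1, u0:u1])
    depth_buf[v0:v1, u0:u1][mask] = depth
    color_buf[v0:v1, u0:u1][mask] = color
    id_buf[v0:v1, u0:u1][mask] = elem_id


def _draw_sphere(depth_buf, color_buf, id_buf, uc, vc, rp, zc, r_m,
                 base_color, elem_id):
    """Render the front hemisphere of a fruit; returns its full-extent
    pixel mask (clipped to the image) ignoring occlusion."""
    h, w = depth_buf.shape
    ri = int(np.ceil(rp)) + 1
    u0, u1 = max(0, int(uc) - ri), min(w, int(uc) + ri + 1)
    v0, v1 = max(0, int(vc) - ri), min(h, int(vc) + ri + 1)
    full = np.zeros((h, w), dtype=bool)
    if u0 >= u1 or v0 >= v1:
        return full
    uu, vv = np.meshgrid(np.arange(u0, u1), np.arange(v0, v1))
    d2 = ((uu - uc) ** 2 + (vv - vc) ** 2) / rp ** 2
    inside = d2 <= 1.0
    bulge = np.sqrt(np.clip(1.0 - d2, 0.0, 1.0))
    depth = zc - r_m * bulge  # front surface of the sphere
    shade = (0.55 + 0.45 * bulge)[..., None]
    color = np.clip(base_color * shade, 0, 255)
    nearer = inside & (depth < depth_buf[v0:v1, u0:u1])
    depth_buf[v0:v1, u0:u1][nearer] = depth[nearer]
    color_buf[v0:v1, u0:u1][nearer] = color[nearer]
    id_buf[v0:v1, u0:u1][nearer] = elem_id
    full[v0:v1, u0:u1] = inside
    return full


def generate_scene(params: SceneParams,
                   intr: CameraIntrinsics = SYNTH_INTRINSICS
                   ) -> SyntheticScene:
    """Render one scene; a pure function of (params, intrinsics).

    Returns RGB, Z16 depth raster, the cloud back-projected from the
    (millimeter-quantized) z-buffer, and YOLO labels for fruits with at
    least 20% of their projected area visible.
    """
    rng = np.random.default_rng(params.seed)
    h, w = intr.mh, intr.mw

    z_background = rng.uniform(2.4, 3.4)
    depth_buf = np.full((h, w), z_background)
    id_buf = np.full((h, w), -1, dtype=int)
    # mottled green background standing in for distant foliage
    base = np.array([46.0, 92.0, 34.0])
    color_buf = base + rng.normal(0, 10, (h, w, 3))

    clutter_palette = np.array([
        [35.0, 70.0, 25.0],    # dark leaf
        [60.0, 110.0, 40.0],   # lit leaf
        [95.0, 62.0, 30.0],    # branch brown
        [120.0, 85.0, 45.0],   # light bark
    ])
    # background clutter: ellipses on (or just before) the far plane
    for _ in range(params.clutter_density):
        col = clutter_palette[rng.integers(len(clutter_palette))]
        col = np.clip(col + rng.normal(0, 12, 3), 0, 255)
        _draw_ellipse(depth_buf, color_buf, id_buf,
                      cx=rng.uniform(0, w), cy=rng.uniform(0, h),
                      ax=rng.uniform(3, 18), ay=rng.uniform(2, 10),
                      angle=rng.uniform(0, np.pi),
                      depth=z_background - rng.uniform(0.0, 0.3),
                      color=col, elem_id=-1)

    # fruits
    fruit_info = []
    full_masks = []
    for i in range(params.n_fruits):
        z = rng.uniform(*params.depth_range)
        r = rng.uniform(*params.fruit_radius)
        rp = r * intr.fx / z
        uc = rng.uniform(rp, w - rp)
        vc = rng.uniform(rp, h - rp)
        red = np.clip(np.array([200.0, 40.0, 38.0]) +
                      rng.normal(0, 12, 3), 0, 255)
        full = _draw_sphere(depth_buf, color_buf, id_buf, uc, vc, rp, z, r,
                            red, elem_id=i)
        center_world = back_project(uc, vc, z, intr)
        fruit_info.append(dict(u=uc, v=vc, z=z, r=r, rp=rp,
                               center=np.asarray(center_world)))
        full_masks.append(full)

    # foreground occluders: leaves that may cover a fruit
    for i, info in enumerate(fruit_info):
        if rng.random() < params.occlusion_prob:
            col = np.clip(clutter_palette[rng.integers(2)] +
                          rng.normal(0, 10, 3), 0, 255)
            _draw_ellipse(
                depth_buf, color_buf, id_buf,
                cx=info["u"] + rng.uniform(-info["rp"], info["rp"]),
                cy=info["v"] + rng.uniform(-info["rp"], info["rp"]),
                ax=info["rp"] * rng.uniform(0.5, 1.6),
                ay=info["rp"] * rng.uniform(0.4, 1.2),
                angle=rng.uniform(0, np.pi),
                depth=max(info["z"] - info["r"] - rng.uniform(0.05, 0.3),
                          0.25),
                color=col, elem_id=-1)

    # labels: visible fraction from the id buffer vs the full extent mask
    labels = []
    visible_fractions = []
    for i, (info, full) in enumerate(zip(fruit_info, full_masks)):
        total = int(full.sum())
        visible = int((id_buf == i).sum())
        frac = visible / total if total else 0.0
        visible_fractions.append(frac)
        if frac >= 0.2:  # occluded more than 80% -> omitted
            rp, uc, vc = info["rp"], info["u"], info["v"]
            x0, x1 = max(0.0, uc - rp), min(float(w), uc + rp)
            y0, y1 = max(0.0, vc - rp), min(float(h), vc + rp)
            labels.append([(x0 + x1) / 2 / w, (y0 + y1) / 2 / h,
                           (x1 - x0) / w, (y1 - y0) / h])
    labels = (np.array(labels, dtype=float) if labels
              else np.empty((0, 4)))

    # illumination gain perturbs only the color image
    gain = rng.uniform(*params.illumination)
    rgb = np.clip(color_buf * gain, 0, 255).astype(np.uint8)

    # Z16 depth raster (millimeters); sensor range is 4 m
    depth_mm = np.round(depth_buf * 1000.0)
    depth_raw = np.where(depth_mm <= 4000, depth_mm, 0).astype(np.uint16)

    # cloud back-projected from the quantized depth so D and Z agree
    vv, uu = np.nonzero(depth_raw > 0)
    zz = depth_raw[vv, uu] / 1000.0
    pts = back_project(uu.astype(float), vv.astype(float), zz, intr)
    cloud = PointCloud(pts, rgb[vv, uu])

    return SyntheticScene(
        rgb=rgb, depth_raw=depth_raw, cloud=cloud, labels=labels,
        truth=dict(fruits=fruit_info, visible_fractions=visible_fractions,
                   gain=gain, z_background=z_background))


def inject_cloud_noise(cloud: PointCloud, n_outliers: int = 0,
                       displacement: float = 1.0,
                       jitter_sigma: float = 0.0, seed: int = 0
                       ) -> tuple[PointCloud, np.ndarray]:
    """Append far outlier points and jitter the originals.

    Outliers are placed ``displacement`` meters from randomly chosen cloud
    points along random directions.  Returns the noisy cloud and the
    indices (into it) of the injected outliers.
    """
    rng = np.random.default_rng(seed)
    pts = cloud.points.copy()
    if jitter_sigma > 0:
        pts = pts + rng.normal(0, jitter_sigma, pts.shape)
    if n_outliers > 0:
        base = pts[rng.integers(0, len(pts), n_outliers)]
        dirs = rng.normal(size=(n_outliers, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        far = base + displacement * dirs
        pts = np.vstack([pts, far])
    colors = None
    if cloud.colors is not None:
        extra = np.zeros((n_outliers, 3), dtype=np.uint8)
        colors = np.vstack([cloud.colors, extra])
    outlier_idx = np.arange(len(cloud), len(cloud) + n_outliers)
    return PointCloud(pts, colors), outlier_idx


def make_dataset(n_scenes: int, params: SceneParams = SceneParams(),
                 intr: CameraIntrinsics = SYNTH_INTRINSICS,
                 split: tuple = (0.7, 0.1, 0.2), seed: int = 0,
                 out_dir=None) -> dict:
    """Generate scenes and partition them 70/10/20 into train/val/test.

    Returns a manifest ``{"train": [...], "val": [...], "test": [...],
    "scenes": {...}}`` keyed by scene name.  In-memory scenes ride in the
    manifest; with ``out_dir`` set, each scene's 8-channel container,
    label file, and the manifest JSON are also written to disk.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split proportions must sum to 1")
    n_train = int(round(split[0] * n_scenes))
    n_val = int(round(split[1] * n_scenes))
    n_test = n_scenes - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"{n_scenes} scenes is too few for split {split}")

    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2 ** 31 - 1, size=n_scenes)
    scenes = {}
    for i, s in enumerate(scene_seeds):
        from dataclasses import replace
        scenes[f"scene_{i:04d}"] = generate_scene(
            replace(params, seed=int(s)), intr)

    names = list(scenes)
    order = rng.permutation(n_scenes)
    split_names = {
        "train": [names[i] for i in order[:n_train]],
        "val": [names[i] for i in order[n_train:n_train + n_val]],
        "test": [names[i] for i in order[n_train + n_val:]],
    }
    manifest = {**split_names, "scenes": scenes, "seed": seed}

    if out_dir is not None:
        from .pipeline import PipelineConfig, run_preprocess
        out_dir = Path(out_dir)
        (out_dir / "labels").mkdir(parents=True, exist_ok=True)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        cfg = PipelineConfig(intrinsics=intr)
        for name, scene in scenes.items():
            img = run_preprocess(scene, cfg)
            from .fusion import write_container
            write_container(img, out_dir / "images" / f"{name}.mcc")
            lines = ["0 " + " ".join(f"{x:.6f}" for x in row)
                     for row in scene.labels]
            (out_dir / "labels" / f"{name}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else ""))
        (out_dir / "manifest.json").write_text(json.dumps(
            {**split_names, "seed": seed, "n_scenes": n_scenes}, indent=1))
    return manifest
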