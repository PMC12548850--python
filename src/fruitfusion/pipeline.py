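"""End-to-end orchestration: preprocessing, channel selection, experiments.

A single configuration object carries the calibration block, the
preprocessing parameters (voxel size, outlier k and sigma), the feature
fusion weights, the channel selection, and the training schedule.  The
channel selection names any subset of the modality groups

    RGB (3 bands) | R-G | E | F | D | XYZ (3 bands)

which resolves to a 3- to 8-band detector input; ``RGB+XYZ+D+F`` is the
full 8-channel configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .anchors import AnchorSet, kmeans_anchors
from .camera import CameraIntrinsics, Extrinsics, ProjectionOffsets
from .detector import (Detection, EvalResult, InputLayerSpec, TrainConfig,
                       build_model, evaluate, train)
from .features import key_feature_from_rgb, normalize_map, rg_chroma_map, \
    edge_map
from .fusion import MAX_DEPTH_M, MultiChannelImage, compose, decode_depth, \
    xyz_raster
from .pointcloud import OutlierParams, remove_outliers, voxel_downsample
from .synth import SYNTH_INTRINSICS, SceneParams, make_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNEL_GROUPS",
    "PipelineConfig",
    "load_config",
    "run_preprocess",
    "select_channels",
    "build_detection_dataset",
    "load_dataset_dir",
    "OracleDetector",
    "run_experiment",
]

# modality groups and the band names each contributes
CHANNEL_GROUPS = {
    "RGB": ("R", "G", "B"),
    "R-G": ("R-G",),
    "E": ("E",),
    "F": ("F",),
    "D": ("D",),
    "XYZ": ("X", "Y", "Z"),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline in one place.

    The defaults pin the published recipe: 30-neighbor 2-sigma outlier
    removal, 0.6/0.4 chroma/edge fusion, 30 k-means iterations, and the
    SGD schedule of :class:`~fruitfusion.detector.TrainConfig`.
    """

    intrinsics: CameraIntrinsics = SYNTH_INTRINSICS
    extrinsics: Extrinsics = field(default_factory=Extrinsics)
    offsets: ProjectionOffsets = field(default_factory=ProjectionOffsets)
    voxel_size: float = 0.005           # meters
    outlier: OutlierParams = field(default_factory=OutlierParams)
    w_chroma: float = 0.6
    w_edge: float = 0.4
    channels: tuple = ("RGB", "XYZ", "D", "F")
    # training-time view normalization: D and Z divided by the sensor
    # range, X and Y by fixed scene half-extents
    x_half_extent: float = 1.0          # meters
    y_half_extent: float = 0.6          # meters
    kmeans_k: int = 3
    kmeans_iters: int = 30
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.w_chroma + self.w_edge - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")
        n_bands = sum(len(CHANNEL_GROUPS[c]) for c in self.channels)
        if not (3 <= n_bands <= 8):
            raise ValueError(
                f"channel selection {self.channels} resolves to {n_bands} "
                "bands; expected 3-8")

    @property
    def n_bands(self) -> int:
        return sum(len(CHANNEL_GROUPS[c]) for c in self.channels)


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Recognized blocks: ``calibration`` (fx, fy, cx, cy, width, height,
    xoffset, yoffset, extrinsics as 16 row-major numbers),
    ``preprocess`` (voxel_size, k, sigma_mult), ``features`` (w_chroma,
    w_edge), ``channels`` (list of group names), ``train`` (TrainConfig
    fields), and top-level ``seed``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    cal = raw.get("calibration", {})
    if cal:
        kwargs["intrinsics"] = CameraIntrinsics(
            fx=cal["fx"], fy=cal["fy"], cx=cal["cx"], cy=cal["cy"],
            mw=cal["width"], mh=cal["height"])
        kwargs["offsets"] = ProjectionOffsets(
            cal.get("xoffset", 0.0), cal.get("yoffset", 0.0))
        if "extrinsics" in cal:
            kwargs["extrinsics"] = Extrinsics(
                np.array(cal["extrinsics"], dtype=float).reshape(4, 4))
    pre = raw.get("preprocess", {})
    if "voxel_size" in pre:
        kwargs["voxel_size"] = float(pre["voxel_size"])
    if "k" in pre or "sigma_mult" in pre:
        kwargs["outlier"] = OutlierParams(
            k=int(pre.get("k", 30)), sigma_mult=float(pre.get("sigma_mult",
                                                              2.0)))
    feat = raw.get("features", {})
    if feat:
        kwargs["w_chroma"] = float(feat.get("w_chroma", 0.6))
        kwargs["w_edge"] = float(feat.get("w_edge", 0.4))
    if "channels" in raw:
        kwargs["channels"] = tuple(raw["channels"])
    if "train" in raw:
        kwargs["train"] = TrainConfig(**raw["train"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return PipelineConfig(**kwargs)


def run_preprocess(raw_scene, cfg: PipelineConfig) -> MultiChannelImage:
    """Clean the cloud, extract features, and compose the 8-band image.

    ``raw_scene`` provides ``rgb`` (HxWx3 uint8), ``depth_raw`` (HxW
    uint16 Z16), and ``cloud``.  Per-stage counts (points removed, pixels
    zero-filled) are logged and recorded in the container metadata.
    """
    rgb, depth_raw, cloud = raw_scene.rgb, raw_scene.depth_raw, \
        raw_scene.cloud
    n_in = len(cloud)
    cloud = voxel_downsample(cloud, cfg.voxel_size)
    n_voxel = len(cloud)
    cloud, removed = remove_outliers(cloud, cfg.outlier)
    logger.info("preprocess: %d points -> %d after voxel, %d removed as "
                "outliers", n_in, n_voxel, len(removed))

    F = key_feature_from_rgb(rgb, cfg.w_chroma, cfg.w_edge)
    D = decode_depth(depth_raw)
    XYZ = xyz_raster(cloud, cfg.intrinsics, cfg.extrinsics, cfg.offsets,
                     shape=rgb.shape[:2])
    n_zero = int((XYZ[..., 2] == 0).sum())
    logger.info("preprocess: %d/%d XYZ pixels zero-filled", n_zero,
                XYZ.shape[0] * XYZ.shape[1])
    meta = dict(
        fx=cfg.intrinsics.fx, fy=cfg.intrinsics.fy,
        cx=cfg.intrinsics.cx, cy=cfg.intrinsics.cy,
        xoffset=cfg.offsets.xoffset, yoffset=cfg.offsets.yoffset,
        voxel_size=cfg.voxel_size, outlier_k=cfg.outlier.k,
        outlier_sigma=cfg.outlier.sigma_mult,
        points_in=n_in, points_after_voxel=n_voxel,
        points_removed=len(removed), xyz_pixels_zero=n_zero)
    return compose(rgb, F, D, XYZ, meta=meta)


def select_channels(img: MultiChannelImage, channels,
                    cfg: PipelineConfig, rgb_uint8: np.ndarray | None = None
                    ) -> np.ndarray:
    """Assemble the normalized (C, H, W) training tensor for a selection.

    Bands appear in selection order.  Normalization is a training-time
    view only — the container keeps raw meters: R, G, B, F already sit in
    [0,1]; D and Z are divided by the 4 m sensor range; X and Y by the
    configured scene half-extents.  The intermediate R-G and E maps are
    recomputed from RGB on demand (they are inputs to F, not stored
    bands).
    """
    h, w = img.bands.shape[:2]
    if rgb_uint8 is None:
        rgb_uint8 = np.clip(img.bands[..., :3] * 255.0, 0,
                            255).astype(np.uint8)
    out = []
    for group in channels:
        if group not in CHANNEL_GROUPS:
            raise ValueError(f"unknown channel group '{group}'")
        if group == "RGB":
            out.extend(img.bands[..., i] for i in range(3))
        elif group == "R-G":
            out.append(normalize_map(rg_chroma_map(rgb_uint8)
                                     ).astype(np.float32))
        elif group == "E":
            out.append(normalize_map(edge_map(rgb_uint8)
                                     ).astype(np.float32))
        elif group == "F":
            out.append(img.band("F"))
        elif group == "D":
            out.append(img.band("D") / MAX_DEPTH_M)
        elif group == "XYZ":
            out.append(img.band("X") / cfg.x_half_extent)
            out.append(img.band("Y") / cfg.y_half_extent)
            out.append(img.band("Z") / MAX_DEPTH_M)
    return np.stack(out).astype(np.float32)


def build_detection_dataset(manifest: dict, split: str,
                            cfg: PipelineConfig,
                            cache: dict | None = None) -> list[dict]:
    """Preprocess every scene of a split into detector-ready samples.

    The composed 8-band image is channel-independent, so an optional
    ``cache`` dict lets several channel configurations share one
    preprocessing pass per scene.
    """
    samples = []
    for name in manifest[split]:
        scene = manifest["scenes"][name]
        if cache is not None and name in cache:
            img = cache[name]
        else:
            img = run_preprocess(scene, cfg)
            if cache is not None:
                cache[name] = img
        tensor = select_channels(img, cfg.channels, cfg, rgb_uint8=scene.rgb)
        samples.append(dict(name=name, image=tensor,
                            boxes=scene.labels_px.astype(np.float32)))
    return samples


def load_dataset_dir(data_dir, split: str, cfg: PipelineConfig
                     ) -> list[dict]:
    """Load detector-ready samples from a dataset directory on disk.

    Expects the layout written by :func:`fruitfusion.synth.make_dataset`
    with ``out_dir``: ``manifest.json``, ``images/<name>.mcc`` containers,
    and ``labels/<name>.txt`` YOLO label files.
    """
    import json

    from .fusion import read_container

    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    samples = []
    for name in manifest[split]:
        img = read_container(data_dir / "images" / f"{name}.mcc")
        h, w = img.bands.shape[:2]
        boxes = []
        label_path = data_dir / "labels" / f"{name}.txt"
        if label_path.exists():
            for line in label_path.read_text().splitlines():
                parts = line.split()
                if len(parts) >= 5:
                    cx, cy, bw, bh = (float(x) for x in parts[1:5])
                    boxes.append([cx * w, cy * h, bw * w, bh * h])
        boxes = (np.array(boxes, dtype=np.float32) if boxes
                 else np.empty((0, 4), dtype=np.float32))
        tensor = select_channels(img, cfg.channels, cfg)
        samples.append(dict(name=name, image=tensor, boxes=boxes))
    return samples


class OracleDetector:
    """Plug-in stand-in that emits the ground-truth boxes with confidence 1.

    Useful for exercising the evaluation plumbing end to end: a perfect
    detector must score P = R = F1 = 100.
    """

    def __init__(self, dataset):
        self._truth = {id(s["image"]): s["boxes"] for s in dataset}

    def predict(self, image, conf_thr=0.25, nms_iou=0.45):
        boxes = self._truth[id(image)]
        return [Detection(np.asarray(b, dtype=float), 1.0) for b in boxes]


def run_experiment(channel_configs, n_scenes: int = 200,
                   params: SceneParams = SceneParams(),
                   base_cfg: PipelineConfig | None = None,
                   epochs: int = 15, seed: int = 0,
                   iou_thr: float = 0.5, oracle: bool = False
                   ) -> list[dict]:
    """Train and evaluate one detector per channel configuration.

    All configurations share the same scenes, split, anchor set recipe,
    seed, and training budget, so rows differ only in the input-layer
    channel stack.  Returns one row per configuration with the channel
    names, band count, and P/R/F1 on the test split.
    """
    base_cfg = base_cfg or PipelineConfig()
    manifest = make_dataset(n_scenes, params=params,
                            intr=base_cfg.intrinsics, seed=seed)
    cache: dict = {}
    rows = []
    for channels in channel_configs:
        cfg = replace(base_cfg, channels=tuple(channels),
                      train=replace(base_cfg.train, epochs=epochs,
                                    seed=seed),
                      seed=seed)
        train_set = build_detection_dataset(manifest, "train", cfg, cache)
        test_set = build_detection_dataset(manifest, "test", cfg, cache)
        label_wh = np.vstack([s["boxes"][:, 2:4] for s in train_set
                              if len(s["boxes"])])
        anchor_set = kmeans_anchors(label_wh, k=cfg.kmeans_k,
                                    iters=cfg.kmeans_iters, seed=seed)
        if oracle:
            model = OracleDetector(test_set)
        else:
            spec = InputLayerSpec(m=cfg.n_bands)
            model = build_model(spec, anchor_set, seed=seed)
            model, history = train(model, train_set, cfg.train)
        result: EvalResult = evaluate(model, test_set, iou_thr=iou_thr)
        rows.append(dict(channels="+".join(channels), nc=cfg.n_bands,
                         P=result.P, R=result.R, F1=result.F1))
        logger.info("config %s (nc=%d): P=%.1f R=%.1f F1=%.2f",
                    rows[-1]["channels"], cfg.n_bands, result.P, result.R,
                    result.F1)
    return rows
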