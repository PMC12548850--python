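"""Compact anchor-based single-stage detector and evaluation metrics.

The contribution under test in this package is the *input-layer channel
configuration*, not a detector architecture, so the network is a small
fixed convolutional trunk behind a configurable input layer: a 6x6,
stride-2 convolution with m input channels (m between 3 and 8, matching
the dataset's band count) and 32 filters, three further conv blocks, and a
single-scale anchor head predicting objectness and box offsets.  Changing
m changes only the first layer; everything downstream is untouched.

Evaluation uses the standard counting metrics: a prediction is a true
positive when it is the highest-confidence match (IoU >= threshold,
one-to-one) of a ground-truth box; precision, recall, and F1 are reported
as percentages with F1 = 2PR/(P+R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .anchors import AnchorSet, _ratio_matrix
from .nn import SGD, Conv2d, LeakyReLU, Sequential, sigmoid

logger = logging.getLogger(__name__)

__all__ = [
    "InputLayerSpec",
    "TrainConfig",
    "Detection",
    "EvalResult",
    "DetectorModel",
    "build_model",
    "save_model",
    "load_model",
    "train",
    "momentum_at_epoch",
    "lr_at_epoch",
    "box_iou",
    "nms",
    "match_detections",
    "precision",
    "recall",
    "f1",
    "evaluate",
]


@dataclass(frozen=True)
class InputLayerSpec:
    """First-layer kernel geometry: W x H x m x n (6 x 6 x m x 32)."""

    m: int = 8  # input channels; 3 = RGB only, 8 = full multimodal stack
    W: int = 6
    H: int = 6
    n: int = 32

    def __post_init__(self) -> None:
        if not (3 <= self.m <= 8):
            raise ValueError("m (input channels) must be in [3, 8]")
        if min(self.W, self.H, self.n) <= 0:
            raise ValueError("kernel dimensions must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """SGD training schedule.

    Defaults mirror common single-stage detector practice: batch size 4,
    initial learning rate 0.01 decayed linearly by a factor of 0.01 over
    training, momentum 0.937 with 0.8 during a 3-epoch warm-up in which
    the bias learning rate is held at 0.1, and L2 regularization 0.0005.
    """

    batch: int = 4
    lr0: float = 0.01
    lr_decay: float = 0.01  # final lr = lr0 * lr_decay
    momentum: float = 0.937
    warmup_momentum: float = 0.8
    weight_decay: float = 0.0005
    warmup_epochs: int = 3
    warmup_bias_lr: float = 0.1
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= self.warmup_epochs:
            raise ValueError("epochs must exceed warmup_epochs")
        if min(self.batch, self.lr0, self.momentum, self.epochs) <= 0:
            raise ValueError("training parameters must be positive")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Linear decay from lr0 to lr0*lr_decay across the training run."""
    frac = epoch / cfg.epochs
    return cfg.lr0 * ((1.0 - frac) + frac * cfg.lr_decay)


def momentum_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    return cfg.warmup_momentum if epoch < cfg.warmup_epochs else cfg.momentum


@dataclass
class Detection:
    """One predicted box: (cx, cy, w, h) pixels + confidence."""

    box: np.ndarray
    confidence: float
    class_id: int = 0


@dataclass
class EvalResult:
    """Aggregate detection metrics over a split, in percent."""

    P: float
    R: float
    F1: float
    per_image: list = field(default_factory=list)  # (TP, FP, FN) triples

    @property
    def totals(self):
        arr = np.array(self.per_image, dtype=int).reshape(-1, 3)
        return tuple(arr.sum(axis=0))


class DetectorModel:
    """Input layer + fixed trunk + single-scale anchor head."""

    def __init__(self, spec: InputLayerSpec, anchors: AnchorSet,
                 seed: int = 0):
        self.spec = spec
        self.anchors_px = np.asarray(anchors.anchors, dtype=np.float32)
        self.na = len(self.anchors_px)
        rng = np.random.default_rng(seed)
        trunk_channels = (32, 48, 64)
        self.input_layer = Conv2d(spec.m, spec.n, kernel=spec.W, stride=2,
                                  pad=2, rng=rng)
        self.net = Sequential(
            self.input_layer, LeakyReLU(),
            Conv2d(trunk_channels[0], trunk_channels[1], 3, stride=2, pad=1,
                   rng=rng), LeakyReLU(),
            Conv2d(trunk_channels[1], trunk_channels[2], 3, stride=2, pad=1,
                   rng=rng), LeakyReLU(),
            Conv2d(trunk_channels[2], trunk_channels[2], 3, stride=1, pad=1,
                   rng=rng), LeakyReLU(),
            Conv2d(trunk_channels[2], self.na * 5, 1, rng=rng),
        )
        self.stride = 8  # product of the three stride-2 convolutions

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, m, H, W) -> (N, na, 5, Hg, Wg) raw head output."""
        if x.shape[1] != self.spec.m:
            raise ValueError(
                f"model expects {self.spec.m}-channel input, "
                f"got {x.shape[1]} channels")
        out = self.net.forward(x.astype(np.float32), train=train)
        n, _, hg, wg = out.shape
        return out.reshape(n, self.na, 5, hg, wg)

    def predict(self, image: np.ndarray, conf_thr: float = 0.25,
                nms_iou: float = 0.45) -> list[Detection]:
        """Decode detections for one (C, H, W) image."""
        raw = self.forward(image[None], train=False)[0]
        na, _, hg, wg = raw.shape
        obj = sigmoid(raw[:, 0])
        keep = obj >= conf_thr
        if not keep.any():
            return []
        a_idx, gy, gx = np.nonzero(keep)
        tx = sigmoid(raw[a_idx, 1, gy, gx])
        ty = sigmoid(raw[a_idx, 2, gy, gx])
        tw = sigmoid(raw[a_idx, 3, gy, gx])
        th = sigmoid(raw[a_idx, 4, gy, gx])
        # bounded decode: center offset in [-0.5, 1.5) cells, size in
        # (0, 4) anchor units
        cx = (gx + 2.0 * tx - 0.5) * self.stride
        cy = (gy + 2.0 * ty - 0.5) * self.stride
        w = self.anchors_px[a_idx, 0] * (2.0 * tw) ** 2
        h = self.anchors_px[a_idx, 1] * (2.0 * th) ** 2
        img_h, img_w = image.shape[1], image.shape[2]
        boxes = np.column_stack([cx, cy, w, h])
        boxes = _clip_boxes(boxes, img_w, img_h)
        confs = obj[a_idx, gy, gx]
        keep_idx = nms(boxes, confs, nms_iou)
        return [Detection(boxes[i], float(confs[i])) for i in keep_idx]


def build_model(spec: InputLayerSpec, anchors: AnchorSet,
                seed: int = 0) -> DetectorModel:
    """Construct the detector; first-layer parameter count is W*H*m*n + n."""
    return DetectorModel(spec, anchors, seed=seed)


def save_model(model: DetectorModel, path) -> None:
    """Serialize weights, input-layer spec, and anchors to an .npz file."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, m=model.spec.m, anchors=model.anchors_px, **arrays)


def load_model(path) -> DetectorModel:
    """Rebuild a detector saved with :func:`save_model`."""
    data = np.load(path)
    model = DetectorModel(InputLayerSpec(m=int(data["m"])),
                          AnchorSet(data["anchors"]))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"param_{i}"]
    return model


def _clip_boxes(boxes_cxcywh: np.ndarray, img_w: int, img_h: int
                ) -> np.ndarray:
    x0 = np.clip(boxes_cxcywh[:, 0] - boxes_cxcywh[:, 2] / 2, 0, img_w)
    y0 = np.clip(boxes_cxcywh[:, 1] - boxes_cxcywh[:, 3] / 2, 0, img_h)
    x1 = np.clip(boxes_cxcywh[:, 0] + boxes_cxcywh[:, 2] / 2, 0, img_w)
    y1 = np.clip(boxes_cxcywh[:, 1] + boxes_cxcywh[:, 3] / 2, 0, img_h)
    return np.column_stack([(x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0])


# ---------------------------------------------------------------------------
# Loss


class DetectionLoss:
    """Objectness BCE + box regression MSE against anchor-relative targets.

    Each ground-truth box is assigned to the grid cell holding its
    center, plus the nearest horizontal and vertical neighbor cells, and
    within each cell to every anchor within the width/height ratio
    threshold of its size (falling back to the best anchor when none
    matches).  Box offsets are regressed in sigmoid space against the
    bounded decode (center offset ``2s-0.5`` cells, size ``(2s)^2``
    anchor units, ``s`` the sigmoid of the raw output).  The
    objectness term is a focal BCE (alpha 0.25, gamma 2) normalized by the
    positive count, so sparse positives are not drowned out while hard
    negative cells around each object still feel suppression pressure.
    """

    def __init__(self, model: DetectorModel, ratio_threshold: float = 4.0,
                 focal_alpha: float = 0.25, focal_gamma: float = 2.0,
                 box_gain: float = 5.0):
        self.model = model
        self.ratio_threshold = ratio_threshold
        self.focal_alpha = focal_alpha
        self.focal_gamma = focal_gamma
        self.box_gain = box_gain

    def _targets(self, raw_shape, batch_boxes):
        n, na, _, hg, wg = raw_shape
        obj_t = np.zeros((n, na, hg, wg), dtype=np.float32)
        box_t = np.zeros((n, na, 4, hg, wg), dtype=np.float32)
        pos = np.zeros((n, na, hg, wg), dtype=bool)
        stride = self.model.stride
        for i, boxes in enumerate(batch_boxes):
            for (cx, cy, w, h) in np.atleast_2d(boxes) if len(boxes) else []:
                gx = min(int(cx / stride), wg - 1)
                gy = min(int(cy / stride), hg - 1)
                fx, fy = cx / stride - gx, cy / stride - gy
                cells = [(gx, gy)]
                nx = gx - 1 if fx < 0.5 else gx + 1
                ny = gy - 1 if fy < 0.5 else gy + 1
                if 0 <= nx < wg:
                    cells.append((nx, gy))
                if 0 <= ny < hg:
                    cells.append((gx, ny))
                r = _ratio_matrix(np.array([[w, h]]),
                                  self.model.anchors_px)[0]
                matched = np.nonzero(r < self.ratio_threshold)[0]
                if len(matched) == 0:
                    matched = [int(r.argmin())]
                wh_t = np.clip(np.sqrt(
                    [w, h] / self.model.anchors_px[matched]) / 2.0,
                    1e-3, 1.0 - 1e-3)
                for ai, a in enumerate(matched):
                    for (cgx, cgy) in cells:
                        # sigmoid-space targets for the bounded decode
                        sx = (cx / stride - cgx + 0.5) / 2.0
                        sy = (cy / stride - cgy + 0.5) / 2.0
                        if not (0.0 <= sx <= 1.0 and 0.0 <= sy <= 1.0):
                            continue
                        obj_t[i, a, cgy, cgx] = 1.0
                        pos[i, a, cgy, cgx] = True
                        box_t[i, a, :, cgy, cgx] = (sx, sy, wh_t[ai, 0],
                                                    wh_t[ai, 1])
        return obj_t, box_t, pos

    def __call__(self, raw: np.ndarray, batch_boxes
                 ) -> tuple[float, np.ndarray]:
        """Return (scalar loss, gradient wrt raw head output)."""
        n, na, _, hg, wg = raw.shape
        obj_t, box_t, pos = self._targets(raw.shape, batch_boxes)
        grad = np.zeros_like(raw)

        # objectness: focal BCE with logits, normalized by positive count
        p = sigmoid(raw[:, :, 0])
        eps = 1e-7
        p_t = np.where(pos, p, 1.0 - p)
        alpha_t = np.where(pos, self.focal_alpha, 1.0 - self.focal_alpha)
        g = self.focal_gamma
        one_m = 1.0 - p_t
        log_pt = np.log(p_t + eps)
        n_pos_obj = max(int(pos.sum()), 1)
        obj_loss = float((-alpha_t * one_m ** g * log_pt).sum() / n_pos_obj)
        # d/dlogit of the focal term; dp_t/dlogit = +-p(1-p)
        dfocal_dpt = alpha_t * one_m ** (g - 1) * (g * log_pt
                                                   - one_m / (p_t + eps))
        dpt_dlogit = np.where(pos, 1.0, -1.0) * p * (1.0 - p)
        grad[:, :, 0] = dfocal_dpt * dpt_dlogit / n_pos_obj

        # box regression on responsible cells only
        n_pos = int(pos.sum())
        box_loss = 0.0
        if n_pos:
            t = sigmoid(raw[:, :, 1:5])
            d = t - box_t
            mask = pos[:, :, None]
            box_loss = float((d ** 2 * mask).sum() / n_pos)
            scale = self.box_gain * 2.0 / n_pos
            grad[:, :, 1:5] = scale * d * t * (1 - t) * mask
        return obj_loss + self.box_gain * box_loss, grad


def train(model: DetectorModel, dataset, cfg: TrainConfig
          ) -> tuple[DetectorModel, list[float]]:
    """SGD training loop; returns the model and per-epoch mean loss.

    ``dataset`` is a sequence of samples with ``image`` (C, H, W, already
    normalized) and ``boxes`` ((n, 4) pixel cx cy w h).  Runs are
    reproducible for a fixed seed on one device.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    ch = dataset[0]["image"].shape[0]
    if ch != model.spec.m:
        raise ValueError(f"dataset has {ch} channels, model expects "
                         f"{model.spec.m}")
    loss_fn = DetectionLoss(model)
    opt = SGD(model.params(), weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = []
    batches_per_epoch = int(np.ceil(len(dataset) / cfg.batch))
    warmup_iters = max(1, cfg.warmup_epochs * batches_per_epoch)
    it = 0
    for epoch in range(cfg.epochs):
        lr_sched = lr_at_epoch(cfg, epoch)
        order = rng.permutation(len(dataset))
        losses = []
        for start in range(0, len(order), cfg.batch):
            # warm-up: weight lr ramps 0 -> schedule, bias lr ramps from
            # its fixed 0.1, momentum from the warm-up value
            # (momentum itself stays at the warm-up value for whole
            # warm-up epochs, per the published schedule)
            if it < warmup_iters:
                frac = it / warmup_iters
                lr = frac * lr_sched
                bias_lr = cfg.warmup_bias_lr + frac * (lr_sched -
                                                       cfg.warmup_bias_lr)
            else:
                lr = bias_lr = lr_sched
            momentum = momentum_at_epoch(cfg, epoch)
            idx = order[start:start + cfg.batch]
            x = np.stack([dataset[i]["image"] for i in idx])
            boxes = [dataset[i]["boxes"] for i in idx]
            model.net.zero_grad()
            raw = model.forward(x, train=True)
            loss, grad = loss_fn(raw, boxes)
            model.net.backward(grad.reshape(len(idx), -1, *raw.shape[3:]))
            _clip_grad_norm(model.params(), max_norm=10.0)
            opt.step(lr=lr, momentum=momentum, bias_lr=bias_lr)
            losses.append(loss)
            it += 1
        history.append(float(np.mean(losses)))
    return model, history


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale


# ---------------------------------------------------------------------------
# Metrics


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU matrix between (N,4) and (M,4) cx cy w h boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ax0, ay0 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax1, ay1 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx0, by0 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx1, by1 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    iw = np.clip(np.minimum(ax1[:, None], bx1) -
                 np.maximum(ax0[:, None], bx0), 0, None)
    ih = np.clip(np.minimum(ay1[:, None], by1) -
                 np.maximum(ay0[:, None], by0), 0, None)
    inter = iw * ih
    union = (a[:, 2] * a[:, 3])[:, None] + b[:, 2] * b[:, 3] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(boxes: np.ndarray, confs: np.ndarray, iou_thr: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices."""
    order = list(np.argsort(-confs, kind="stable"))
    keep = []
    while order:
        i = order.pop(0)
        keep.append(i)
        if not order:
            break
        ious = box_iou(boxes[i], boxes[order])[0]
        order = [j for j, iou in zip(order, ious) if iou < iou_thr]
    return keep


def match_detections(preds: list[Detection], truths, iou_thr: float = 0.5
                     ) -> tuple[int, int, int]:
    """Greedy one-to-one matching in descending confidence.

    Each prediction claims the unmatched ground-truth box of highest IoU
    at or above the threshold.  Counts conserve: TP+FP = #preds and
    TP+FN = #truths.
    """
    if not (0 < iou_thr < 1):
        raise ValueError("iou_thr must be in (0, 1)")
    truths = np.atleast_2d(np.asarray(truths, dtype=float)) if len(truths) \
        else np.empty((0, 4))
    tp = 0
    matched = np.zeros(len(truths), dtype=bool)
    for det in sorted(preds, key=lambda d: -d.confidence):
        if len(truths) == 0:
            break
        ious = box_iou(det.box, truths)[0]
        ious[matched] = -1.0
        j = int(ious.argmax())
        if ious[j] >= iou_thr:
            matched[j] = True
            tp += 1
    fp = len(preds) - tp
    fn = len(truths) - tp
    return tp, fp, fn


def _safe_pct(num: float, den: float, name: str) -> float:
    if den <= 0:
        logger.warning("%s denominator is zero; reporting 0", name)
        return 0.0
    return 100.0 * num / den


def precision(tp: int, fp: int) -> float:
    """P = TP / (TP + FP), in percent."""
    return _safe_pct(tp, tp + fp, "precision")


def recall(tp: int, fn: int) -> float:
    """R = TP / (TP + FN), in percent."""
    return _safe_pct(tp, tp + fn, "recall")


def f1(p: float, r: float) -> float:
    """F1 = 2PR / (P + R), the harmonic mean, in percent."""
    if p + r <= 0:
        logger.warning("F1 denominator is zero; reporting 0")
        return 0.0
    return 2.0 * p * r / (p + r)


def evaluate(model, dataset, iou_thr: float = 0.5, conf_thr: float = 0.25,
             nms_iou: float = 0.45) -> EvalResult:
    """Aggregate TP/FP/FN over a split and report P, R, F1 (percent).

    ``model`` needs only a ``predict(image)`` method, so an oracle stub
    can stand in for a trained network when exercising the metrics.
    """
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty split")
    per_image = []
    for sample in dataset:
        preds = model.predict(sample["image"], conf_thr=conf_thr,
                              nms_iou=nms_iou)
        per_image.append(match_detections(preds, sample["boxes"], iou_thr))
    totals = np.array(per_image, dtype=int).sum(axis=0)
    p = precision(int(totals[0]), int(totals[1]))
    r = recall(int(totals[0]), int(totals[2]))
    return EvalResult(P=p, R=r, F1=f1(p, r), per_image=per_image)
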