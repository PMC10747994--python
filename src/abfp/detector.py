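"""A deliberately tiny anchor-based single-stage detector.

Purpose: prove the attention-balanced neck end-to-end — images in, boxes
out, metrics computed — at desk scale on CPU.  The architecture follows the
RetinaNet recipe (anchors, focal loss, smooth-L1 box regression) but with a
four-stage micro convolutional backbone (strides 4/8/16/32, widths
16/32/64/128) in place of a deep residual network; all of the
neck mathematics is backbone-agnostic, so nothing about the balanced
pyramid or the attention gates changes with backbone depth.

Training uses SGD with momentum, weight decay, linear warmup and stepped
learning-rate drops, and random horizontal flips.  The loop is a pure
function of the seed, so loss curves reproduce bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, conv2d, where
from .pyramid import FeaturePyramid
from .neck import NeckConfig, FPNParams, ABFPParams, fpn_forward, abfp_forward
from .attention import ChannelAttentionParams, SpatialAttentionParams, _kaiming_uniform
from .evaluation import BoxSet, EvalResult, evaluate, iou_matrix

__all__ = [
    "AnchorSpec",
    "TrainConfig",
    "MicroDetector",
    "build_detector",
    "train",
    "predict",
    "predict_and_evaluate",
    "nms",
]

_BACKBONE_WIDTHS = [8, 16, 32, 64, 128]  # stem + four pyramid stages
_PYRAMID_WIDTHS = [16, 32, 64, 128]
_STRIDES = [4, 8, 16, 32]


@dataclass
class AnchorSpec:
    """Per-level anchors and the IoU assignment rule.

    One size per level (``4 * stride`` by default, matching the RetinaNet
    octave-0 convention) crossed with the aspect ratios.  Anchors with IoU
    >= ``pos_iou`` to some ground truth are positive, < ``neg_iou`` are
    negative, the band in between is ignored; the best anchor of every
    ground truth is always positive.
    """

    sizes: list[float] = field(default_factory=lambda: [4.0 * s for s in _STRIDES])
    aspect_ratios: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0])
    pos_iou: float = 0.5
    neg_iou: float = 0.4

    def __post_init__(self):
        if not self.aspect_ratios:
            raise ValueError("at least one anchor per level is required")

    @property
    def per_cell(self) -> int:
        return len(self.aspect_ratios)


@dataclass
class TrainConfig:
    """SGD training schedule.

    The learning-rate recipe (0.01, momentum 0.9, weight decay 1e-4, linear
    warmup, stepped drops, batch 4, 50% horizontal flips) follows the
    reference detector; epochs and drop epochs default to the desk-scale
    schedule (12 epochs, drops at 8 and 11; the full-scale schedule is 24
    with drops at 16 and 22).
    """

    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    epochs: int = 12
    lr_drops: list[int] = field(default_factory=lambda: [8, 11])
    lr_drop_factor: float = 0.1
    batch_size: int = 4
    hflip_prob: float = 0.5
    warmup_iters: int = 50
    warmup_factor: float = 1.0 / 3.0
    clip_grad_norm: float | None = 10.0
    seed: int = 0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if any(d > self.epochs for d in self.lr_drops):
            raise ValueError("lr_drops must lie within the epoch range")


def micro_neck_config(attention: bool = True, out_channels: int = 32,
                      reduction_ratio: int = 16) -> NeckConfig:
    return NeckConfig(
        in_channels=list(_PYRAMID_WIDTHS),
        out_channels=out_channels,
        attention=attention,
        reduction_ratio=reduction_ratio,
    )


class MicroDetector:
    """Micro backbone -> FPN -> (optional) ABFP -> shared detection head."""

    def __init__(self, neck_cfg: NeckConfig, anchors: AnchorSpec | None = None,
                 use_abfp: bool = True, seed: int = 0, prior_prob: float = 0.01):
        if list(neck_cfg.in_channels) != _PYRAMID_WIDTHS:
            raise ValueError(f"micro backbone produces channels {_PYRAMID_WIDTHS}")
        self.neck_cfg = neck_cfg
        self.anchors = anchors or AnchorSpec()
        self.use_abfp = use_abfp
        self.prior_prob = prior_prob
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(seed))

    # -- parameters -----------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> None:
        p = self.params
        widths = _BACKBONE_WIDTHS
        c_prev = 1
        for i, c in enumerate(widths):
            p[f"backbone.conv{i}.w"] = _kaiming_uniform(rng, (c, c_prev, 3, 3), c_prev * 9)
            p[f"backbone.conv{i}.b"] = np.zeros(c, dtype=np.float32)
            c_prev = c
        fpn = FPNParams.init(self.neck_cfg, rng)
        for i in range(self.neck_cfg.num_levels):
            p[f"fpn.lateral{i}.w"] = fpn.lateral_w[i]
            p[f"fpn.lateral{i}.b"] = fpn.lateral_b[i]
            p[f"fpn.output{i}.w"] = fpn.output_w[i]
            p[f"fpn.output{i}.b"] = fpn.output_b[i]
        if self.use_abfp:
            abfp = ABFPParams.init(self.neck_cfg, rng)
            if self.neck_cfg.attention:
                p["abfp.channel.w0"] = abfp.channel.w0
                p["abfp.channel.b0"] = abfp.channel.b0
                p["abfp.channel.w1"] = abfp.channel.w1
                p["abfp.channel.b1"] = abfp.channel.b1
                p["abfp.spatial.kernel"] = abfp.spatial.kernel
                p["abfp.spatial.bias"] = abfp.spatial.bias
                self._reduction_ratio = abfp.channel.reduction_ratio
            else:
                p["abfp.refine.w"] = abfp.refine_w
                p["abfp.refine.b"] = abfp.refine_b
        co = self.neck_cfg.out_channels
        a = self.anchors.per_cell
        p["head.shared.w"] = _kaiming_uniform(rng, (co, co, 3, 3), co * 9)
        p["head.shared.b"] = np.zeros(co, dtype=np.float32)
        p["head.cls.w"] = _kaiming_uniform(rng, (a, co, 3, 3), co * 9)
        # bias so the initial foreground probability is prior_prob (focal-loss init)
        p["head.cls.b"] = np.full(
            a, -np.log((1.0 - self.prior_prob) / self.prior_prob), dtype=np.float32
        )
        p["head.reg.w"] = _kaiming_uniform(rng, (4 * a, co, 3, 3), co * 9)
        p["head.reg.b"] = np.zeros(4 * a, dtype=np.float32)

    def num_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def save(self, path) -> None:
        meta = {
            "neck_cfg": asdict(self.neck_cfg),
            "anchors": asdict(self.anchors),
            "use_abfp": self.use_abfp,
            "prior_prob": self.prior_prob,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "MicroDetector":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
        det = cls(NeckConfig(**meta["neck_cfg"]), AnchorSpec(**meta["anchors"]),
                  use_abfp=meta["use_abfp"], prior_prob=meta["prior_prob"])
        for k in det.params:
            det.params[k] = arrays[k].astype(np.float32)
        return det

    # -- forward --------------------------------------------------------------
    def _wrap(self, requires_grad: bool) -> dict[str, Tensor]:
        return {k: Tensor(v, requires_grad=requires_grad) for k, v in self.params.items()}

    def _containers(self, t: dict[str, Tensor]):
        n = self.neck_cfg.num_levels
        fpn = FPNParams(
            lateral_w=[t[f"fpn.lateral{i}.w"] for i in range(n)],
            lateral_b=[t[f"fpn.lateral{i}.b"] for i in range(n)],
            output_w=[t[f"fpn.output{i}.w"] for i in range(n)],
            output_b=[t[f"fpn.output{i}.b"] for i in range(n)],
        )
        abfp = None
        if self.use_abfp:
            if self.neck_cfg.attention:
                abfp = ABFPParams(
                    channel=ChannelAttentionParams(
                        w0=t["abfp.channel.w0"], b0=t["abfp.channel.b0"],
                        w1=t["abfp.channel.w1"], b1=t["abfp.channel.b1"],
                        reduction_ratio=self._reduction_ratio,
                    ),
                    spatial=SpatialAttentionParams(
                        kernel=t["abfp.spatial.kernel"], bias=t["abfp.spatial.bias"]
                    ),
                )
            else:
                abfp = ABFPParams(channel=None, spatial=None,
                                  refine_w=t["abfp.refine.w"], refine_b=t["abfp.refine.b"])
        return fpn, abfp

    def forward(self, images: np.ndarray, requires_grad: bool = False):
        """Batch of (B, 1, H, W) images -> per-level class logits and box deltas.

        Returns ``(cls_levels, reg_levels, tensors)`` where level ``l`` has
        class logits of shape (B, A, H_l, W_l) and deltas (B, 4A, H_l, W_l).
        """
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[:, None]
        h, w = images.shape[-2:]
        if h % _STRIDES[-1] or w % _STRIDES[-1]:
            raise ValueError(f"image size {h}x{w} must be divisible by {_STRIDES[-1]}")
        t = self._wrap(requires_grad)
        x = Tensor(images)
        feats = []
        for i in range(len(_BACKBONE_WIDTHS)):
            x = conv2d(x, t[f"backbone.conv{i}.w"], t[f"backbone.conv{i}.b"],
                       stride=2, pad=1).relu()
            if i >= 1:  # taps at strides 4, 8, 16, 32
                feats.append(x)
        pyramid = FeaturePyramid(levels=feats)
        fpn_params, abfp_params = self._containers(t)
        pyramid = fpn_forward(pyramid, self.neck_cfg, fpn_params)
        if self.use_abfp:
            pyramid = abfp_forward(pyramid, self.neck_cfg, abfp_params)
        cls_levels, reg_levels = [], []
        for lvl in pyramid.levels:
            shared = conv2d(lvl, t["head.shared.w"], t["head.shared.b"], pad=1).relu()
            cls_levels.append(conv2d(shared, t["head.cls.w"], t["head.cls.b"], pad=1))
            reg_levels.append(conv2d(shared, t["head.reg.w"], t["head.reg.b"], pad=1))
        return cls_levels, reg_levels, t

    # -- anchors --------------------------------------------------------------
    def anchor_boxes(self, image_hw: tuple[int, int]) -> np.ndarray:
        """All anchors for an image, (total, 4) corner coordinates.

        Enumeration order matches the flattened head outputs: level-major,
        then rows, columns, and aspect ratio.
        """
        h, w = image_hw
        boxes = []
        for stride, size in zip(_STRIDES, self.anchors.sizes):
            hl, wl = h // stride, w // stride
            cy = (np.arange(hl) + 0.5) * stride
            cx = (np.arange(wl) + 0.5) * stride
            for yy in cy:
                for xx in cx:
                    for ratio in self.anchors.aspect_ratios:
                        ah = size * np.sqrt(ratio)
                        aw = size / np.sqrt(ratio)
                        boxes.append([xx - aw / 2, yy - ah / 2, xx + aw / 2, yy + ah / 2])
        return np.asarray(boxes, dtype=np.float64)


def build_detector(attention: bool = True, use_abfp: bool = True, out_channels: int = 32,
                   reduction_ratio: int = 16, seed: int = 0,
                   anchors: AnchorSpec | None = None) -> MicroDetector:
    """Convenience constructor: micro backbone + FPN (+ ABFP) + head.

    ``attention=False`` keeps the balanced-pyramid path but replaces the
    attention refinement with a 3x3 convolution (the ablation arm);
    ``use_abfp=False`` drops the balanced pyramid entirely (plain FPN).
    """
    cfg = micro_neck_config(attention=attention, out_channels=out_channels,
                            reduction_ratio=reduction_ratio)
    return MicroDetector(cfg, anchors=anchors, use_abfp=use_abfp, seed=seed)


# -- target assignment --------------------------------------------------------

def _encode_boxes(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gcx = gt[:, 0] + gw / 2
    gcy = gt[:, 1] + gh / 2
    return np.stack([(gcx - acx) / aw, (gcy - acy) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def _decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    acx = anchors[:, 0] + aw / 2
    acy = anchors[:, 1] + ah / 2
    cx = acx + deltas[:, 0] * aw
    cy = acy + deltas[:, 1] * ah
    w = aw * np.exp(np.clip(deltas[:, 2], -8, 8))
    h = ah * np.exp(np.clip(deltas[:, 3], -8, 8))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def assign_targets(anchors: np.ndarray, gt_boxes: np.ndarray, spec: AnchorSpec):
    """Label anchors 1/0/-1 (pos/neg/ignore) and encode regression targets."""
    n = len(anchors)
    labels = np.zeros(n, dtype=np.int8)
    reg_targets = np.zeros((n, 4), dtype=np.float32)
    if len(gt_boxes) == 0:
        return labels, reg_targets
    ious = iou_matrix(anchors, gt_boxes)
    best_gt = ious.argmax(axis=1)
    best_iou = ious[np.arange(n), best_gt]
    labels[best_iou >= spec.pos_iou] = 1
    labels[(best_iou >= spec.neg_iou) & (best_iou < spec.pos_iou)] = -1
    # every ground truth claims its best-overlapping anchor
    best_anchor = ious.argmax(axis=0)
    labels[best_anchor] = 1
    best_gt[best_anchor] = np.arange(len(gt_boxes))
    pos = labels == 1
    reg_targets[pos] = _encode_boxes(anchors[pos], gt_boxes[best_gt[pos]]).astype(np.float32)
    return labels, reg_targets


def _flatten_head(cls_levels, reg_levels, per_cell: int):
    """(B, A, H, W) / (B, 4A, H, W) levels -> (B, T) logits and (B, T, 4) deltas."""
    cls_flat, reg_flat = [], []
    for cl, rl in zip(cls_levels, reg_levels):
        b, a, hl, wl = cl.shape
        cls_flat.append(cl.transpose((0, 2, 3, 1)).reshape(b, hl * wl * a))
        r = rl.reshape(b, per_cell, 4, hl, wl).transpose((0, 3, 4, 1, 2))
        reg_flat.append(r.reshape(b, hl * wl * per_cell, 4))
    from .autodiff import concat

    return concat(cls_flat, axis=1), concat(reg_flat, axis=1)


def detection_loss(detector: MicroDetector, images: np.ndarray,
                   gt_boxes_per_image: list[np.ndarray], cfg: TrainConfig,
                   requires_grad: bool = True):
    """Focal classification loss + smooth-L1 box loss, normalised by #positives."""
    cls_levels, reg_levels, tensors = detector.forward(images, requires_grad=requires_grad)
    logits, deltas = _flatten_head(cls_levels, reg_levels, detector.anchors.per_cell)
    anchors = detector.anchor_boxes(np.asarray(images).shape[-2:])
    assigned = [assign_targets(anchors, gb, detector.anchors) for gb in gt_boxes_per_image]
    labels = np.stack([a[0] for a in assigned])
    reg_targets = np.stack([a[1] for a in assigned])
    valid = (labels >= 0).astype(np.float32)
    y = (labels == 1).astype(np.float32)
    n_pos = max(1.0, float(y.sum()))
    p = logits.sigmoid()
    alpha, gamma = cfg.focal_alpha, cfg.focal_gamma
    # stable focal loss: -log(sigmoid(x)) == softplus(-x)
    pos_term = (alpha * y) * (1.0 - p) ** gamma * (-logits).softplus()
    neg_term = ((1.0 - alpha) * (1.0 - y)) * p**gamma * logits.softplus()
    cls_loss = (Tensor(valid) * (pos_term + neg_term)).sum() * (1.0 / n_pos)
    pos_mask = y[..., None]
    diff = (deltas - Tensor(reg_targets)).abs()
    huber = where(diff.data < 1.0, diff * diff * 0.5, diff - 0.5)
    reg_loss = (Tensor(pos_mask) * huber).sum() * (1.0 / n_pos)
    return cls_loss + reg_loss, tensors


# -- training -----------------------------------------------------------------

def _lr_at(cfg: TrainConfig, epoch: int, it: int) -> float:
    lr = cfg.lr
    for drop in cfg.lr_drops:
        if epoch >= drop:
            lr *= cfg.lr_drop_factor
    if it < cfg.warmup_iters and cfg.warmup_iters > 0:
        frac = it / cfg.warmup_iters
        lr *= cfg.warmup_factor + (1.0 - cfg.warmup_factor) * frac
    return lr


def _gt_corner_boxes(coco: dict) -> dict[int, np.ndarray]:
    out: dict[int, list] = {rec["id"]: [] for rec in coco["images"]}
    for ann in coco["annotations"]:
        x, y, w, h = ann["bbox"]
        out[ann["image_id"]].append([x, y, x + w, y + h])
    return {k: np.asarray(v, dtype=np.float64).reshape(-1, 4) for k, v in out.items()}


def train(detector: MicroDetector, images: list[np.ndarray], coco: dict,
          cfg: TrainConfig, image_ids: list[int] | None = None,
          log=None) -> dict:
    """SGD training; returns per-epoch mean losses and the per-step loss trace."""
    gt = _gt_corner_boxes(coco)
    ids = list(image_ids) if image_ids is not None else [r["id"] for r in coco["images"]]
    if not ids:
        raise ValueError("training requires a nonempty dataset")
    id_to_index = {r["id"]: i for i, r in enumerate(coco["images"])}
    rng = np.random.default_rng(cfg.seed)
    velocity = {k: np.zeros_like(v) for k, v in detector.params.items()}
    epoch_losses: list[float] = []
    step_losses: list[float] = []
    it = 0
    img_w = images[0].shape[-1]
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(ids))
        batch_losses = []
        for start in range(0, len(ids), cfg.batch_size):
            batch_ids = [ids[i] for i in order[start : start + cfg.batch_size]]
            batch_imgs, batch_boxes = [], []
            for iid in batch_ids:
                img = images[id_to_index[iid]]
                boxes = gt[iid].copy()
                if rng.random() < cfg.hflip_prob:
                    img = img[..., ::-1].copy()
                    if len(boxes):
                        x1 = img_w - boxes[:, 2]
                        x2 = img_w - boxes[:, 0]
                        boxes[:, 0], boxes[:, 2] = x1, x2
                batch_imgs.append(img)
                batch_boxes.append(boxes)
            batch = np.stack(batch_imgs)[:, None]
            loss, tensors = detection_loss(detector, batch, batch_boxes, cfg)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss {loss_val} at epoch {epoch}, iteration {it}"
                )
            loss.backward()
            lr = _lr_at(cfg, epoch, it)
            grads = {}
            for name, param in detector.params.items():
                g = tensors[name].grad
                grads[name] = np.zeros_like(param) if g is None else g
            if cfg.clip_grad_norm is not None:
                total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
                if total > cfg.clip_grad_norm:
                    scale = np.float32(cfg.clip_grad_norm / total)
                    grads = {k: g * scale for k, g in grads.items()}
            for name, param in detector.params.items():
                g = grads[name] + cfg.weight_decay * param
                velocity[name] = cfg.momentum * velocity[name] + g
                param -= (lr * velocity[name]).astype(np.float32)
            batch_losses.append(loss_val)
            step_losses.append(loss_val)
            it += 1
        epoch_losses.append(float(np.mean(batch_losses)))
        if log is not None:
            log(f"epoch {epoch + 1}/{cfg.epochs}  loss {epoch_losses[-1]:.4f}  lr {lr:.5f}")
    return {"epoch_losses": epoch_losses, "step_losses": step_losses}


# -- inference ----------------------------------------------------------------

def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float = 0.5) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices in score order."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        if len(boxes) > 1:
            overlaps = iou_matrix(boxes[i : i + 1], boxes)[0]
            suppressed |= overlaps > iou_thresh
            suppressed[i] = True
    return np.asarray(keep, dtype=np.intp)


def predict(detector: MicroDetector, images: list[np.ndarray],
            image_ids: list[int], score_thresh: float = 0.05,
            nms_iou: float = 0.5, max_detections: int = 100,
            batch_size: int = 8) -> list[BoxSet]:
    """Decode, threshold and NMS-filter detections for a list of images."""
    out: list[BoxSet] = []
    for start in range(0, len(images), batch_size):
        chunk = images[start : start + batch_size]
        batch = np.stack(chunk)[:, None].astype(np.float32)
        cls_levels, reg_levels, _ = detector.forward(batch, requires_grad=False)
        logits, deltas = _flatten_head(cls_levels, reg_levels, detector.anchors.per_cell)
        anchors = detector.anchor_boxes(batch.shape[-2:])
        scores_all = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
        h, w = batch.shape[-2:]
        for bi in range(len(chunk)):
            scores = scores_all[bi]
            keep = scores >= score_thresh
            if not keep.any():
                out.append(BoxSet(boxes=np.zeros((0, 4)), scores=np.zeros(0),
                                  image_id=image_ids[start + bi]))
                continue
            boxes = _decode_boxes(anchors[keep], deltas.data[bi][keep].astype(np.float64))
            boxes[:, [0, 2]] = np.clip(boxes[:, [0, 2]], 0, w)
            boxes[:, [1, 3]] = np.clip(boxes[:, [1, 3]], 0, h)
            ok = (boxes[:, 2] - boxes[:, 0] > 1e-3) & (boxes[:, 3] - boxes[:, 1] > 1e-3)
            boxes, sc = boxes[ok], scores[keep][ok]
            kept = nms(boxes, sc, nms_iou)[:max_detections]
            out.append(BoxSet(boxes=boxes[kept], scores=sc[kept],
                              image_id=image_ids[start + bi]))
    return out


def predict_and_evaluate(detector: MicroDetector, images: list[np.ndarray],
                         coco: dict, image_ids: list[int] | None = None,
                         score_thresh: float = 0.05, nms_iou: float = 0.5) -> EvalResult:
    """Run inference on the given split and score it with the COCO-style metrics."""
    ids = list(image_ids) if image_ids is not None else [r["id"] for r in coco["images"]]
    id_to_index = {r["id"]: i for i, r in enumerate(coco["images"])}
    imgs = [images[id_to_index[i]] for i in ids]
    dets = predict(detector, imgs, ids, score_thresh=score_thresh, nms_iou=nms_iou)
    gt = _gt_corner_boxes(coco)
    gts = [BoxSet(boxes=gt[i], image_id=i) for i in ids]
    return evaluate(dets, gts)
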