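"""Single-class detection metrics: IoU, greedy matching, AP/AP50/AP75/AR.

The protocol follows the COCO convention for a single foreground class:
detections are pooled over images, sorted by descending confidence (ties
broken by input order), greedily matched to at most one unmatched ground
truth per image at a given IoU threshold, and the resulting
precision-recall curve is summarised by 101-point interpolated average
precision.  Headline numbers average over the ten IoU thresholds
0.50:0.05:0.95; AP50 and AP75 fix the threshold at 0.50 and 0.75.  Average
recall is the mean, over the same thresholds, of the recall achieved with
at most ``max_detections`` highest-scoring detections per image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "BoxSet",
    "EvalResult",
    "IOU_THRESHOLDS",
    "iou",
    "iou_matrix",
    "match_and_pr",
    "average_precision",
    "evaluate",
    "load_coco_ground_truth",
    "load_coco_detections",
    "boxsets_to_coco",
]

IOU_THRESHOLDS: np.ndarray = np.round(np.arange(0.50, 0.951, 0.05), 2)
RECALL_GRID: np.ndarray = np.linspace(0.0, 1.0, 101)


@dataclass
class BoxSet:
    """Axis-aligned boxes for one image, corner coordinates (x1, y1, x2, y2)."""

    boxes: np.ndarray  # (n, 4) float
    scores: np.ndarray | None = None  # (n,) confidences for detections
    image_id: int = 0

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(-1, 4)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
            if len(self.scores) != len(self.boxes):
                raise ValueError("scores and boxes length mismatch")
        if not np.isfinite(self.boxes).all():
            raise ValueError("box coordinates must be finite")
        if len(self.boxes) and (
            (self.boxes[:, 2] <= self.boxes[:, 0]).any()
            or (self.boxes[:, 3] <= self.boxes[:, 1]).any()
        ):
            raise ValueError("boxes must satisfy x2 > x1 and y2 > y1")

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class EvalResult:
    """AP/AR summary over IoU thresholds 0.50:0.05:0.95."""

    AP: float
    AP50: float
    AP75: float
    AR: float
    per_threshold_AP: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def iou(a, b) -> float:
    """Intersection over union of two (x1, y1, x2, y2) boxes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    if area_a <= 0 or area_b <= 0:
        raise ValueError("degenerate (zero-area) box")
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n, 4) and (m, 4) corner-coordinate boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    iw = np.clip(
        np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]),
        0.0, None,
    )
    ih = np.clip(
        np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]),
        0.0, None,
    )
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def _match_dataset(dets: list[BoxSet], gts: list[BoxSet], iou_thresh: float,
                   max_detections: int | None = None):
    """Greedy matching pooled over images.

    Returns (scores, is_tp, n_gt): pooled detection scores sorted descending
    with stable tie-break by input order, the TP flag per detection, and the
    total ground-truth count.
    """
    gt_by_image = {g.image_id: g for g in gts}
    n_gt = sum(len(g) for g in gts)
    all_scores: list[float] = []
    all_tp: list[bool] = []
    order_key: list[int] = []
    counter = 0
    for d in dets:
        if d.scores is None:
            raise ValueError("detections must carry confidence scores")
        order = np.argsort(-d.scores, kind="stable")
        if max_detections is not None:
            order = order[:max_detections]
        g = gt_by_image.get(d.image_id)
        gt_boxes = g.boxes if g is not None else np.zeros((0, 4))
        used = np.zeros(len(gt_boxes), dtype=bool)
        ious = iou_matrix(d.boxes, gt_boxes) if len(gt_boxes) and len(d) else None
        for di in order:
            matched = False
            if ious is not None:
                cand = np.where(~used & (ious[di] >= iou_thresh))[0]
                if len(cand):
                    best = cand[np.argmax(ious[di][cand])]
                    used[best] = True
                    matched = True
            all_scores.append(float(d.scores[di]))
            all_tp.append(matched)
            order_key.append(counter)
            counter += 1
    if not all_scores:
        return np.zeros(0), np.zeros(0, dtype=bool), n_gt
    scores = np.asarray(all_scores)
    tp = np.asarray(all_tp)
    pooled_order = np.lexsort((np.asarray(order_key), -scores))
    return scores[pooled_order], tp[pooled_order], n_gt


def match_and_pr(dets: list[BoxSet], gts: list[BoxSet], iou_thresh: float):
    """Precision-recall points from greedy matching at one IoU threshold.

    Returns an (n_det, 2) array of (recall, precision) after each pooled
    detection, in descending-score order.  With zero ground truths the
    recall is undefined and an empty array is returned (AP is then 0).
    """
    _, tp, n_gt = _match_dataset(dets, gts, iou_thresh)
    if n_gt == 0 or len(tp) == 0:
        return np.zeros((0, 2))
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    return np.stack([recall, precision], axis=1)


def average_precision(pr_points: np.ndarray) -> float:
    """101-point interpolated AP from (recall, precision) points.

    The precision envelope (running max from the right) is sampled on the
    recall grid 0:0.01:1; unreachable recalls contribute zero.
    """
    pr_points = np.asarray(pr_points, dtype=np.float64).reshape(-1, 2)
    if len(pr_points) == 0:
        return 0.0
    recall = pr_points[:, 0]
    precision = pr_points[:, 1]
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    # for each grid recall, precision of the first PR point with recall >= r
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    sampled = np.where(idx < len(recall), envelope[np.minimum(idx, len(recall) - 1)], 0.0)
    return float(sampled.mean())


def evaluate(dets: list[BoxSet], gts: list[BoxSet],
             max_detections: int = 100) -> EvalResult:
    """AP, AP50, AP75 and AR over IoU thresholds 0.50:0.05:0.95."""
    if not gts:
        raise ValueError("evaluation requires at least one ground-truth image")
    per_threshold = []
    recalls = []
    for t in IOU_THRESHOLDS:
        pr = match_and_pr(dets, gts, float(t))
        per_threshold.append(average_precision(pr))
        _, tp, n_gt = _match_dataset(dets, gts, float(t), max_detections=max_detections)
        recalls.append(float(tp.sum()) / n_gt if n_gt else 0.0)
    per_threshold = [float(a) for a in per_threshold]
    idx50 = int(np.argmin(np.abs(IOU_THRESHOLDS - 0.50)))
    idx75 = int(np.argmin(np.abs(IOU_THRESHOLDS - 0.75)))
    return EvalResult(
        AP=float(np.mean(per_threshold)),
        AP50=per_threshold[idx50],
        AP75=per_threshold[idx75],
        AR=float(np.mean(recalls)),
        per_threshold_AP=per_threshold,
    )


# -- COCO-dialect JSON --------------------------------------------------------

def load_coco_ground_truth(path) -> list[BoxSet]:
    """Read a COCO-style annotation file into per-image corner-coordinate boxes."""
    with open(path) as fh:
        coco = json.load(fh)
    by_image: dict[int, list] = {img["id"]: [] for img in coco.get("images", [])}
    for ann in coco.get("annotations", []):
        x, y, w, h = ann["bbox"]
        by_image.setdefault(ann["image_id"], []).append([x, y, x + w, y + h])
    return [
        BoxSet(boxes=np.asarray(b, dtype=np.float64).reshape(-1, 4), image_id=i)
        for i, b in sorted(by_image.items())
    ]


def load_coco_detections(path) -> list[BoxSet]:
    """Read a COCO-style results list [{image_id, bbox, score}, ...]."""
    with open(path) as fh:
        results = json.load(fh)
    by_image: dict[int, list] = {}
    for r in results:
        x, y, w, h = r["bbox"]
        by_image.setdefault(r["image_id"], []).append([x, y, x + w, y + h, r["score"]])
    out = []
    for i, rows in sorted(by_image.items()):
        arr = np.asarray(rows, dtype=np.float64)
        out.append(BoxSet(boxes=arr[:, :4], scores=arr[:, 4], image_id=i))
    return out


def boxsets_to_coco(dets: list[BoxSet]) -> list[dict]:
    """Corner-coordinate detections -> COCO results list with [x, y, w, h] boxes."""
    rows = []
    for d in dets:
        for b, s in zip(d.boxes, d.scores if d.scores is not None else np.ones(len(d))):
            rows.append({
                "image_id": int(d.image_id),
                "category_id": 1,
                "bbox": [float(b[0]), float(b[1]), float(b[2] - b[0]), float(b[3] - b[1])],
                "score": float(s),
            })
    return rows
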