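"""Detection evaluation: IoU, average precision, and mAP over an
IoU-threshold sweep (0.50:0.05:0.95).

The matcher is the standard greedy score-descending one: detections are
visited in decreasing score (ties broken by insertion order), each is
matched to the unmatched ground-truth box of the same class with the
highest IoU, provided that IoU reaches the threshold. AP is the
COCO-style 101-point interpolated area under the precision-recall
curve; mAP averages AP over thresholds and over the classes present in
the ground truth with equal weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import Annotation

__all__ = [
    "Detection",
    "iou",
    "average_precision",
    "map_over_thresholds",
    "evaluate_coco_files",
    "jitter_oracle_detections",
    "COCO_THRESHOLDS",
]

COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class Detection:
    """One detector output box."""

    frame_id: int
    class_name: str
    bbox: tuple[float, float, float, float]
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be in [0, 1]")
        if self.bbox[2] <= 0 or self.bbox[3] <= 0:
            raise ValueError("bbox width/height must be positive")


def iou(a, b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive width and height")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def _match_tp_fp(
    dets: list[Detection],
    gts: list[Annotation],
    iou_thr: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy matching within one class; returns (tp, fp, n_gt) with
    detections ordered by decreasing score (stable)."""
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    gt_by_frame: dict = {}
    for j, g in enumerate(gts):
        gt_by_frame.setdefault(g.frame_id, []).append(j)
    matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(order))
    fp = np.zeros(len(order))
    for rank, i in enumerate(order):
        d = dets[i]
        best_j, best_iou = -1, 0.0
        for j in gt_by_frame.get(d.frame_id, []):
            if matched[j]:
                continue
            v = iou(d.bbox, gts[j].bbox)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_thr:
            matched[best_j] = True
            tp[rank] = 1
        else:
            fp[rank] = 1
    return tp, fp, len(gts)


def average_precision(
    dets: list[Detection],
    gts: list[Annotation],
    iou_thr: float = 0.5,
) -> float:
    """COCO-style 101-point interpolated AP for a single class.

    Edge cases: empty ground truth with no detections is defined as 1.0;
    empty ground truth with detections is 0.0; no detections against a
    nonempty ground truth is 0.0.
    """
    if not gts:
        return 1.0 if not dets else 0.0
    if not dets:
        return 0.0
    tp, fp, n_gt = _match_tp_fp(dets, gts, iou_thr)
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # precision envelope: best precision at any recall >= r
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    recall_points = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, recall_points, side="left")
    interp = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return float(interp.mean())


def map_over_thresholds(
    dets: list[Detection],
    gts: list[Annotation],
    thresholds: tuple[float, ...] = COCO_THRESHOLDS,
) -> float:
    """Mean AP over IoU thresholds and over the classes present in GT."""
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    classes = sorted({g.class_name for g in gts})
    if not classes:
        return 1.0 if not dets else 0.0
    aps = []
    for cls in classes:
        cls_dets = [d for d in dets if d.class_name == cls]
        cls_gts = [g for g in gts if g.class_name == cls]
        for thr in thresholds:
            aps.append(average_precision(cls_dets, cls_gts, thr))
    return float(np.mean(aps))


def evaluate_coco_files(gt_path: str | Path, det_path: str | Path) -> float:
    """mAP from a COCO ground-truth JSON and a detections JSON.

    The detections file is a list of ``{image_id, category_id, bbox,
    score}`` records (the standard COCO results format).
    """
    gt = json.loads(Path(gt_path).read_text())
    id_to_name = {c["id"]: c["name"] for c in gt["categories"]}
    gts = [
        Annotation(
            id_to_name[a["category_id"]], tuple(a["bbox"]), a["image_id"]
        )
        for a in gt["annotations"]
    ]
    dets_raw = json.loads(Path(det_path).read_text())
    dets = [
        Detection(
            d["image_id"], id_to_name[d["category_id"]], tuple(d["bbox"]), d["score"]
        )
        for d in dets_raw
    ]
    return map_over_thresholds(dets, gts)


def jitter_oracle_detections(
    gts: list[Annotation],
    jitter_px: float,
    seed: int | np.random.SeedSequence | None = None,
) -> list[Detection]:
    """Synthetic "oracle detector": ground-truth boxes with positional
    jitter. Useful for tracing the expected mAP-vs-jitter curve of the
    evaluator without any trained model."""
    rng = np.random.default_rng(seed)
    out = []
    for g in gts:
        dx, dy = rng.normal(0.0, jitter_px, size=2)
        x, y, w, h = g.bbox
        out.append(
            Detection(
                g.frame_id,
                g.class_name,
                (x + dx, y + dy, w, h),
                float(rng.uniform(0.5, 1.0)),
            )
        )
    return out
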