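"""Independent brute-force detection evaluator used as a test oracle.

Deliberately written with naive loops and an explicit recall scan so it
shares no code with the package's evaluator: detections are matched
greedily in score order against per-frame ground truth, the PR curve is
built point by point, and the 101-point interpolated AP is computed by
scanning all precisions at each recall level.
"""

from __future__ import annotations


def _iou(a, b) -> float:
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ax1, ay1 = ax0 + aw, ay0 + ah
    bx1, by1 = bx0 + bw, by0 + bh
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (aw * ah + bw * bh - inter)


def reference_ap(dets, gts, thr) -> float:
    """dets: list of (frame_id, bbox, score); gts: list of (frame_id, bbox)."""
    if len(gts) == 0:
        return 1.0 if len(dets) == 0 else 0.0
    if len(dets) == 0:
        return 0.0
    ranked = sorted(enumerate(dets), key=lambda t: (-t[1][2], t[0]))
    used = [False] * len(gts)
    flags = []
    for _, (frame, bbox, _) in ranked:
        best, best_iou = None, 0.0
        for j, (g_frame, g_bbox) in enumerate(gts):
            if used[j] or g_frame != frame:
                continue
            v = _iou(bbox, g_bbox)
            if v > best_iou:
                best, best_iou = j, v
        if best is not None and best_iou >= thr:
            used[best] = True
            flags.append(True)
        else:
            flags.append(False)
    precisions, recalls = [], []
    tp = 0
    for k, is_tp in enumerate(flags, start=1):
        if is_tp:
            tp += 1
        precisions.append(tp / k)
        recalls.append(tp / len(gts))
    total = 0.0
    for i in range(101):
        r = i / 100.0
        best_p = 0.0
        for p, rec in zip(precisions, recalls):
            if rec >= r and p > best_p:
                best_p = p
        total += best_p
    return total / 101.0


def reference_map(dets_by_class, gts_by_class, thresholds) -> float:
    """Mean over thresholds and over the classes present in ground truth."""
    values = []
    for cls, gts in gts_by_class.items():
        if not gts:
            continue
        dets = dets_by_class.get(cls, [])
        for thr in thresholds:
            values.append(reference_ap(dets, gts, thr))
    return sum(values) / len(values)
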