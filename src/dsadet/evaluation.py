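"""Detection metrics: precision, recall, F1, AP, mAP50 and mAP50:95.

Matching is greedy in descending score order with same-class constraint;
each ground-truth box matches at most one detection.  AP is the area
under the precision–recall curve with 101-point interpolation (the COCO
convention); an all-point variant is available for cross-checks.
mAP50:95 averages IoU thresholds 0.50:0.05:0.95.  Dataset-level P/R/F1
are reported at the score threshold that maximizes F1 at IoU 0.5.

Inputs are flat records — ground truth ``(image_id, class_id, box)`` and
detections ``(image_id, class_id, score, box)`` with xyxy pixel boxes —
or COCO-dialect JSON files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvalResult",
    "box_iou",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "evaluate_detections",
    "load_coco_ground_truth",
    "load_coco_results",
]

IOU_THRESHOLDS_5095 = np.arange(0.50, 0.96, 0.05)


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    ap_per_class: dict[int, float]
    map50: float
    map5095: float
    counts: tuple[int, int, int]  # (TP, FP, FN) at the operating point

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "map50": self.map50,
            "map5095": self.map5095,
            "ap_per_class": {int(k): v for k, v in self.ap_per_class.items()},
            "counts": {"tp": self.counts[0], "fp": self.counts[1], "fn": self.counts[2]},
        }


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of xyxy boxes; a: (N,4), b: (M,4) -> (N,M)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    x1 = np.maximum(a[:, None, 0], b[None, :, 0])
    y1 = np.maximum(a[:, None, 1], b[None, :, 1])
    x2 = np.minimum(a[:, None, 2], b[None, :, 2])
    y2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def _greedy_match(dets, gts, iou_thresh):
    """Greedy matcher within one image+class pool.

    ``dets``: list of (score, box, det_index); ``gts``: list of boxes.
    Returns a boolean TP flag per detection (in the given order) plus the
    matched-gt count.  Detections are processed in descending score,
    ties broken by detection index.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][0], dets[i][2]))
    matched = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    if len(gts):
        gt_arr = np.asarray([g for g in gts], dtype=np.float64)
    for i in order:
        if not len(gts):
            break
        ious = box_iou(np.asarray(dets[i][1])[None], gt_arr)[0]
        ious[matched] = -1.0
        j = int(np.argmax(ious))
        if ious[j] >= iou_thresh:
            matched[j] = True
            tp[i] = True
    return tp, int(matched.sum())


def match_detections(dets, gts, iou_thresh: float = 0.5):
    """Count (TP, FP, FN) for one image.

    ``dets``: list of (class_id, score, xyxy box); ``gts``: list of
    (class_id, xyxy box).  Same-class greedy matching in descending
    score order; every ground truth matches at most once.
    """
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError("iou_thresh must be in (0, 1)")
    classes = {c for c, *_ in dets} | {c for c, _ in gts}
    tp = fp = fn = 0
    for c in classes:
        dc = [(s, b, i) for i, (cc, s, b) in enumerate(dets) if cc == c]
        gc = [b for cc, b in gts if cc == c]
        flags, n_matched = _greedy_match(dc, gc, iou_thresh)
        tp += n_matched
        fp += len(dc) - n_matched
        fn += len(gc) - n_matched
    return tp, fp, fn


def precision_recall_f1(tp: int, fp: int, fn: int):
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 defined as 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _class_pr_points(dets, gts, class_id, iou_thresh):
    """Scored TP flags and gt count for one class over all images."""
    n_gt = sum(1 for _, c, _ in gts if c == class_id)
    by_img_gt: dict = {}
    for img_id, c, box in gts:
        if c == class_id:
            by_img_gt.setdefault(img_id, []).append(box)
    recs = [
        (i, img_id, s, box)
        for i, (img_id, c, s, box) in enumerate(dets)
        if c == class_id
    ]
    flags = []
    for img_id in {r[1] for r in recs}:
        dc = [(s, box, i) for i, ii, s, box in recs if ii == img_id]
        tp, _ = _greedy_match(dc, by_img_gt.get(img_id, []), iou_thresh)
        flags.extend(
            (s, idx, bool(t)) for (s, _, idx), t in zip(dc, tp)
        )
    flags.sort(key=lambda r: (-r[0], r[1]))
    tps = np.array([f[2] for f in flags], dtype=np.float64)
    return tps, n_gt


def average_precision(
    dets,
    gts,
    class_id: int,
    iou_thresh: float = 0.5,
    interpolation: str = "101point",
) -> float:
    """AP for one class at one IoU threshold.

    ``dets``: (image_id, class_id, score, box); ``gts``: (image_id,
    class_id, box).  ``interpolation``: '101point' (default) or
    'all_point' (exact area under the stepwise PR curve).
    """
    tps, n_gt = _class_pr_points(dets, gts, class_id, iou_thresh)
    if n_gt == 0:
        return float("nan")
    if len(tps) == 0:
        return 0.0
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1.0 - tps)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    if interpolation == "101point":
        ap = 0.0
        for r in np.linspace(0, 1, 101):
            mask = recall >= r - 1e-12
            ap += precision[mask].max() if mask.any() else 0.0
        return ap / 101.0
    if interpolation == "all_point":
        # envelope + exact area of the stepwise curve
        mrec = np.concatenate([[0.0], recall, [1.0]])
        mpre = np.concatenate([[1.0], precision, [0.0]])
        for i in range(len(mpre) - 2, -1, -1):
            mpre[i] = max(mpre[i], mpre[i + 1])
        idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
        return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    raise ValueError("interpolation must be '101point' or 'all_point'")


def evaluate_detections(
    dets,
    gts,
    num_classes: int = 5,
    interpolation: str = "101point",
) -> EvalResult:
    """Full metric suite over flat detection/ground-truth records."""
    classes = [c for c in range(num_classes) if any(g[1] == c for g in gts)]
    ap50 = {
        c: average_precision(dets, gts, c, 0.5, interpolation) for c in classes
    }
    map50 = float(np.mean([ap50[c] for c in classes])) if classes else 0.0
    aps_all = []
    for thr in IOU_THRESHOLDS_5095:
        vals = [average_precision(dets, gts, c, float(thr), interpolation) for c in classes]
        aps_all.append(np.mean(vals) if vals else 0.0)
    map5095 = float(np.mean(aps_all)) if aps_all else 0.0

    # operating point: score threshold maximizing F1 at IoU 0.5
    best = (0.0, 0.0, 0.0, (0, 0, sum(1 for _ in gts)))
    scores = sorted({d[2] for d in dets})
    gt_by_img: dict = {}
    for img_id, c, box in gts:
        gt_by_img.setdefault(img_id, []).append((c, box))
    for thr in scores:
        tp = fp = fn = 0
        det_by_img: dict = {}
        for img_id, c, s, box in dets:
            if s >= thr:
                det_by_img.setdefault(img_id, []).append((c, s, box))
        for img_id in set(gt_by_img) | set(det_by_img):
            t, f, n = match_detections(
                det_by_img.get(img_id, []), gt_by_img.get(img_id, []), 0.5
            )
            tp += t
            fp += f
            fn += n
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        if f1 > best[2]:
            best = (p, r, f1, (tp, fp, fn))
    p, r, f1, counts = best
    return EvalResult(p, r, f1, ap50, map50, map5095, counts)


def load_coco_ground_truth(path: str):
    """COCO JSON -> flat (image_id, class_id, xyxy box) records."""
    with open(path) as fh:
        coco = json.load(fh)
    out = []
    for ann in coco["annotations"]:
        x, y, w, h = ann["bbox"]
        out.append((ann["image_id"], ann["category_id"] - 1, (x, y, x + w, y + h)))
    return out


def load_coco_results(path: str):
    """COCO results JSON -> flat (image_id, class_id, score, xyxy box)."""
    with open(path) as fh:
        res = json.load(fh)
    out = []
    for r in res:
        x, y, w, h = r["bbox"]
        out.append(
            (r["image_id"], r["category_id"] - 1, r["score"], (x, y, x + w, y + h))
        )
    return out
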