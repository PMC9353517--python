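"""COCO-style detection/segmentation metrics: AP, AP50, AP75, AR@{1,10,100}.

Faithful to the COCO evaluation protocol the field standardizes on: greedy
score-ordered one-to-one matching per IoU threshold, 101-point interpolated
precision, primary AP averaged over the 10 thresholds 0.50:0.05:0.95, recall
capped at 1/10/100 detections per image.  A prediction counts as a true
positive at IoU >= threshold (the reference convention); a ground truth can
be claimed by at most one prediction.  With a single category the category
average is a no-op.  When a quantity is undefined (no ground truth at all)
the sentinel -1.0 is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import load_coco, rasterize_instance

__all__ = [
    "IOU_THRESHOLDS",
    "MatchCounts",
    "MetricsReport",
    "pairwise_iou",
    "box_iou_matrix",
    "mask_iou_matrix",
    "match_predictions",
    "average_precision",
    "average_recall",
    "evaluate",
]

IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)   # 0.50 ... 0.95, 10 values
_REC_THRESHOLDS = np.linspace(0.0, 1.0, 101)


@dataclass
class MatchCounts:
    tp: int
    fp: int
    fn: int
    iou_threshold: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0


@dataclass
class MetricsReport:
    """The six COCO metrics for one task, as fractions in [0, 1] (or -1)."""

    task: str            # "box" | "segm"
    ap: float
    ap50: float
    ap75: float
    ar1: float
    ar10: float
    ar100: float

    def as_dict(self) -> dict:
        return asdict(self)

    def as_percent(self) -> dict:
        return {k: (round(v * 100.0, 2) if isinstance(v, float) and v >= 0 else v)
                for k, v in asdict(self).items() if k != "task"} | {"task": self.task}

    def table(self) -> str:
        rows = [("AP", self.ap), ("AP@IoU=0.5", self.ap50), ("AP@IoU=0.75", self.ap75),
                ("AR@max=1", self.ar1), ("AR@max=10", self.ar10), ("AR@max=100", self.ar100)]
        lines = [f"{'Metric':<14}{self.task:>10}"]
        for name, v in rows:
            pct = f"{v * 100:.2f}" if v >= 0 else "n/a"
            lines.append(f"{name:<14}{pct:>10}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# IoU


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU of (N, 4) vs (M, 4) boxes in (x, y, w, h) form."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ax1, ay1 = a[:, 0], a[:, 1]
    ax2, ay2 = a[:, 0] + a[:, 2], a[:, 1] + a[:, 3]
    bx1, by1 = b[:, 0], b[:, 1]
    bx2, by2 = b[:, 0] + b[:, 2], b[:, 1] + b[:, 3]
    ix = np.maximum(0.0, np.minimum(ax2[:, None], bx2[None, :])
                    - np.maximum(ax1[:, None], bx1[None, :]))
    iy = np.maximum(0.0, np.minimum(ay2[:, None], by2[None, :])
                    - np.maximum(ay1[:, None], by1[None, :]))
    inter = ix * iy
    union = (a[:, 2] * a[:, 3])[:, None] + (b[:, 2] * b[:, 3])[None, :] - inter
    out = np.zeros_like(inter)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def mask_iou_matrix(a: Sequence[np.ndarray], b: Sequence[np.ndarray]) -> np.ndarray:
    """IoU of two lists of boolean masks (empty union → 0 by convention)."""
    out = np.zeros((len(a), len(b)))
    flat_b = [m.reshape(-1) for m in b]
    areas_b = np.array([m.sum() for m in flat_b], dtype=float)
    for i, ma in enumerate(a):
        fa = ma.reshape(-1)
        area_a = float(fa.sum())
        for j, fb in enumerate(flat_b):
            inter = float(np.count_nonzero(fa & fb))
            union = area_a + areas_b[j] - inter
            out[i, j] = inter / union if union > 0 else 0.0
    return out


def pairwise_iou(a, b) -> float:
    """IoU of two boxes (len-4 sequences, xywh) or two boolean masks."""
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    a_is_mask = a_arr.dtype == bool or a_arr.ndim == 2
    b_is_mask = b_arr.dtype == bool or b_arr.ndim == 2
    if a_is_mask != b_is_mask:
        raise TypeError("cannot mix a box with a mask")
    if a_is_mask:
        return float(mask_iou_matrix([a_arr.astype(bool)], [b_arr.astype(bool)])[0, 0])
    return float(box_iou_matrix(a_arr[None], b_arr[None])[0, 0])


# ---------------------------------------------------------------------------
# matching


def match_predictions(iou: np.ndarray, iou_threshold: float):
    """Greedy one-to-one matching of score-sorted predictions to ground truth.

    `iou` is (n_pred, n_gt) with predictions already sorted by descending
    score.  Each prediction claims the still-unmatched ground truth with the
    highest IoU >= threshold; the rest are false positives.  Returns
    (MatchCounts, matched_gt_index_per_pred) with -1 marking false positives.
    """
    n_pred, n_gt = iou.shape
    gt_taken = np.zeros(n_gt, dtype=bool)
    match = np.full(n_pred, -1, dtype=int)
    for d in range(n_pred):
        best, best_iou = -1, iou_threshold
        for g in range(n_gt):
            if gt_taken[g]:
                continue
            if iou[d, g] >= best_iou:
                best, best_iou = g, iou[d, g]
        if best >= 0:
            match[d] = best
            gt_taken[best] = True
    tp = int((match >= 0).sum())
    return MatchCounts(tp=tp, fp=n_pred - tp, fn=n_gt - tp,
                       iou_threshold=float(iou_threshold)), match


def _accumulate(per_image, iou_thresholds, max_det: int):
    """Shared AP/AR accumulation over images.

    per_image: list of (iou_matrix (n_pred, n_gt) sorted by score, scores).
    Returns (ap_per_threshold, recall_per_threshold); entries are -1 when
    there is no ground truth anywhere.
    """
    n_gt_total = sum(m.shape[1] for m, _ in per_image)
    T = len(iou_thresholds)
    if n_gt_total == 0:
        return np.full(T, -1.0), np.full(T, -1.0)
    all_scores, all_matched = [], []
    for m, scores in per_image:
        m = m[:max_det]
        scores = np.asarray(scores)[:max_det]
        matched = np.zeros((T, len(scores)), dtype=bool)
        for ti, t in enumerate(iou_thresholds):
            _, match = match_predictions(m, t)
            matched[ti] = match >= 0
        all_scores.append(scores)
        all_matched.append(matched)
    if all_scores and sum(len(s) for s in all_scores):
        scores = np.concatenate(all_scores)
        matched = np.concatenate(all_matched, axis=1)
    else:
        scores = np.zeros(0)
        matched = np.zeros((T, 0), dtype=bool)
    order = np.argsort(-scores, kind="mergesort")
    matched = matched[:, order]
    ap = np.zeros(T)
    rec_out = np.zeros(T)
    for ti in range(T):
        tp = np.cumsum(matched[ti]).astype(float)
        fp = np.cumsum(~matched[ti]).astype(float)
        rc = tp / n_gt_total
        pr = np.zeros_like(tp)
        np.divide(tp, tp + fp, out=pr, where=(tp + fp) > 0)
        rec_out[ti] = rc[-1] if len(rc) else 0.0
        # right-to-left precision envelope, then 101-point interpolation
        for i in range(len(pr) - 1, 0, -1):
            pr[i - 1] = max(pr[i - 1], pr[i])
        inds = np.searchsorted(rc, _REC_THRESHOLDS, side="left")
        q = np.zeros(len(_REC_THRESHOLDS))
        valid = inds < len(pr)
        q[valid] = pr[inds[valid]]
        ap[ti] = q.mean()
    return ap, rec_out


def average_precision(per_image, iou_thresholds=IOU_THRESHOLDS, max_det: int = 100):
    """Interpolated AP averaged over the IoU thresholds (primary COCO AP).

    per_image: list of (iou_matrix score-sorted, scores).  Returns (primary
    AP, AP per threshold).
    """
    iou_thresholds = np.atleast_1d(iou_thresholds)
    if len(iou_thresholds) == 0:
        raise ValueError("need at least one IoU threshold")
    ap, _ = _accumulate(per_image, iou_thresholds, max_det)
    return float(ap.mean()), ap


def average_recall(per_image, max_detections: int, iou_thresholds=IOU_THRESHOLDS):
    """Recall with at most `max_detections` per image, averaged over thresholds."""
    _, rec = _accumulate(per_image, np.atleast_1d(iou_thresholds), max_detections)
    return float(rec.mean())


# ---------------------------------------------------------------------------
# COCO-format entry point


def _decode_segmentation(seg, h: int, w: int) -> np.ndarray:
    if isinstance(seg, dict):
        raise ValueError("RLE segmentations are not supported; use polygon lists")
    parts = [np.asarray(p, dtype=float).reshape(-1, 2) for p in seg]
    return rasterize_instance(parts, h, w)


def evaluate(coco_gt, coco_results, task: str = "box",
             iou_thresholds=IOU_THRESHOLDS) -> MetricsReport:
    """Score COCO-format results against COCO-format ground truth.

    coco_results: list of {image_id, category_id, bbox, score[, segmentation]}
    (or a path to such a JSON).  ``task`` selects box or mask IoU.  Masks may
    be given as polygon segmentation lists or as dense boolean arrays under a
    ``mask`` key.
    """
    if task not in ("box", "segm"):
        raise ValueError("task must be 'box' or 'segm'")
    gt = load_coco(coco_gt)
    if isinstance(coco_results, (str, Path)):
        with open(coco_results) as fh:
            coco_results = json.load(fh)
    img_ids = [im["id"] for im in gt["images"]]
    img_dims = {im["id"]: (im["height"], im["width"]) for im in gt["images"]}
    orphan = sorted({r["image_id"] for r in coco_results} - set(img_ids))
    if orphan:
        raise ValueError(f"results reference unknown image ids: {orphan[:5]}")
    gt_by_img = {i: [] for i in img_ids}
    for a in gt["annotations"]:
        gt_by_img[a["image_id"]].append(a)
    dt_by_img = {i: [] for i in img_ids}
    for r in coco_results:
        dt_by_img[r["image_id"]].append(r)

    per_image = []
    for i in img_ids:
        h, w = img_dims[i]
        gts, dts = gt_by_img[i], dt_by_img[i]
        dts = sorted(dts, key=lambda r: -r["score"])
        scores = [r["score"] for r in dts]
        if task == "box":
            if gts and dts:
                iou = box_iou_matrix([r["bbox"] for r in dts], [a["bbox"] for a in gts])
            else:
                iou = np.zeros((len(dts), len(gts)))
        else:
            gm = [_decode_segmentation(a["segmentation"], h, w) for a in gts]
            dm = [r["mask"] if "mask" in r else
                  _decode_segmentation(r["segmentation"], h, w) for r in dts]
            iou = mask_iou_matrix(dm, gm) if (gm and dm) else np.zeros((len(dm), len(gm)))
        per_image.append((iou, scores))

    ap_mean, ap_per_t = average_precision(per_image, iou_thresholds, max_det=100)
    t_arr = np.asarray(iou_thresholds)

    def at(t):
        idx = np.where(np.isclose(t_arr, t))[0]
        return float(ap_per_t[idx[0]]) if len(idx) else float("nan")

    return MetricsReport(
        task=task,
        ap=ap_mean,
        ap50=at(0.5),
        ap75=at(0.75),
        ar1=average_recall(per_image, 1, iou_thresholds),
        ar10=average_recall(per_image, 10, iou_thresholds),
        ar100=average_recall(per_image, 100, iou_thresholds),
    )
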