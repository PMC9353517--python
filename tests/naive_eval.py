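"""Independent brute-force COCO-metric oracle used only by tests.

Deliberately naive: Python loops, explicit greedy matching, explicit
precision envelope and 101-point interpolation — a second, independent route
to the same protocol the package implements with vectorized code.
"""

import numpy as np


def naive_box_iou(a, b):
    ax1, ay1, aw, ah = a
    bx1, by1, bw, bh = b
    ax2, ay2 = ax1 + aw, ay1 + ah
    bx2, by2 = bx1 + bw, by1 + bh
    ix = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    iy = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def naive_mask_iou(a, b):
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    return inter / union if union > 0 else 0.0


def naive_match(gt_objs, dt_objs, iou_fn, thr):
    """Greedy: detections in score order claim the best unmatched gt."""
    taken = [False] * len(gt_objs)
    flags = []
    for obj, _score in dt_objs:
        best, best_iou = -1, thr
        for g, gobj in enumerate(gt_objs):
            if taken[g]:
                continue
            v = iou_fn(obj, gobj)
            if v >= best_iou:
                best, best_iou = g, v
        if best >= 0:
            taken[best] = True
        flags.append(best >= 0)
    return flags


def naive_metrics(gt_per_image, dt_per_image, iou_fn):
    """Full six-metric report.  dt entries are (object, score) lists."""
    thresholds = [round(0.5 + 0.05 * i, 2) for i in range(10)]
    n_gt = sum(len(g) for g in gt_per_image)
    if n_gt == 0:
        return {k: -1.0 for k in ("ap", "ap50", "ap75", "ar1", "ar10", "ar100")}

    def sorted_dets(k):
        per_img = []
        for dts in dt_per_image:
            dts = sorted(dts, key=lambda t: -t[1])[:k]
            per_img.append(dts)
        return per_img

    def ap_at(thr, k=100):
        scored = []
        for gts, dts in zip(gt_per_image, sorted_dets(k)):
            flags = naive_match(gts, dts, iou_fn, thr)
            for (obj, s), f in zip(dts, flags):
                scored.append((s, f))
        scored.sort(key=lambda t: -t[0])
        tp = fp = 0
        pr, rc = [], []
        for _s, f in scored:
            if f:
                tp += 1
            else:
                fp += 1
            pr.append(tp / (tp + fp))
            rc.append(tp / n_gt)
        for i in range(len(pr) - 1, 0, -1):
            pr[i - 1] = max(pr[i - 1], pr[i])
        total = 0.0
        for r in np.linspace(0, 1, 101):
            p_here = 0.0
            for i in range(len(rc)):
                if rc[i] >= r:
                    p_here = pr[i]
                    break
            total += p_here
        return total / 101.0

    def ar_at(k):
        vals = []
        for thr in thresholds:
            tp = 0
            for gts, dts in zip(gt_per_image, sorted_dets(k)):
                tp += sum(naive_match(gts, dts, iou_fn, thr))
            vals.append(tp / n_gt)
        return float(np.mean(vals))

    ap_all = [ap_at(t) for t in thresholds]
    return {"ap": float(np.mean(ap_all)), "ap50": ap_at(0.5), "ap75": ap_at(0.75),
            "ar1": ar_at(1), "ar10": ar_at(10), "ar100": ar_at(100)}
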