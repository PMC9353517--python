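"""Region proposals, RoI heads and the three-term loss.

Anchor design follows the grape detector's recipe: five scales
{8, 16, 32, 64, 128} assigned one per pyramid level P2..P6 (smallest scale
on the highest-resolution level), three aspect ratios {0.5, 1, 2}, fifteen
templates in total.  RoIAlign pools quantization-free 7x7 features for the
classification/box branch and 14x14 for the mask branch; the mask branch
predicts an m x m (default 28) per-class logit grid supervised with mean
per-pixel sigmoid binary cross-entropy.  The training objective is the plain
unweighted sum L = L_cls + L_box + L_mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .backbone import FeaturePyramid

__all__ = ["AnchorTemplate", "Detection", "LossBreakdown", "TrainingDivergence",
           "build_anchor_templates", "generate_level_anchors", "nms",
           "encode_boxes", "decode_boxes", "RPN", "BoxHead", "MaskHead",
           "RoIHeads", "mask_loss", "total_loss"]

DEFAULT_SCALES = (8, 16, 32, 64, 128)
DEFAULT_RATIOS = (0.5, 1.0, 2.0)
LEVEL_NAMES = ("P2", "P3", "P4", "P5", "P6")


# ---------------------------------------------------------------------------
# anchors


@dataclass(frozen=True)
class AnchorTemplate:
    """One benchmark window: base scale, aspect ratio (width/height), the
    pyramid level it lives on, and its pixel extent."""

    scale: float
    aspect_ratio: float
    level: str
    width: int
    height: int


def build_anchor_templates(scales: Sequence[float] = DEFAULT_SCALES,
                           ratios: Sequence[float] = DEFAULT_RATIOS,
                           levels: Sequence[str] = LEVEL_NAMES) -> list:
    """Cartesian product of scales x ratios, scale-major then ratio order.

    Each scale is an anchor side length in input pixels; at fixed scale the
    area is preserved across ratios (w = s*sqrt(a), h = s/sqrt(a), rounded).
    Scales are assigned to levels in increasing order, one per level.
    """
    if not scales or not ratios:
        raise ValueError("need nonempty scale and ratio sets")
    if any(s <= 0 for s in scales) or any(r <= 0 for r in ratios):
        raise ValueError("scales and ratios must be positive")
    if len(scales) != len(levels):
        raise ValueError(f"{len(scales)} scales for {len(levels)} levels")
    out = []
    for s, lv in zip(sorted(scales), levels):
        for r in ratios:
            w = int(round(s * np.sqrt(r)))
            h = int(round(s / np.sqrt(r)))
            out.append(AnchorTemplate(scale=float(s), aspect_ratio=float(r),
                                      level=lv, width=w, height=h))
    return out


def generate_level_anchors(templates: list, level: str, height: int, width: int,
                           stride: int) -> np.ndarray:
    """(H*W*A, 4) xyxy anchors for one level, centers at (j+0.5)*stride.

    Ordering is row-major over the grid, template-minor — matching the
    (A*4)-channel layout of the RPN delta map.
    """
    tpl = [t for t in templates if t.level == level]
    cx = (np.arange(width) + 0.5) * stride
    cy = (np.arange(height) + 0.5) * stride
    cxg, cyg = np.meshgrid(cx, cy)
    centers = np.stack([cxg.ravel(), cyg.ravel()], axis=1)   # (H*W, 2)
    wh = np.array([[t.width, t.height] for t in tpl], dtype=float)  # (A, 2)
    half = wh / 2.0
    mins = centers[:, None, :] - half[None, :, :]
    maxs = centers[:, None, :] + half[None, :, :]
    return np.concatenate([mins, maxs], axis=2).reshape(-1, 4)


# ---------------------------------------------------------------------------
# box coding / NMS


def encode_boxes(ref: np.ndarray, gt: np.ndarray, weights=(1., 1., 1., 1.)) -> np.ndarray:
    """(dx, dy, dw, dh) regression targets of gt boxes against reference boxes
    (both xyxy)."""
    rw = ref[:, 2] - ref[:, 0]
    rh = ref[:, 3] - ref[:, 1]
    rx = ref[:, 0] + 0.5 * rw
    ry = ref[:, 1] + 0.5 * rh
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gx = gt[:, 0] + 0.5 * gw
    gy = gt[:, 1] + 0.5 * gh
    wx, wy, ww, wh = weights
    return np.stack([wx * (gx - rx) / rw, wy * (gy - ry) / rh,
                     ww * np.log(gw / rw), wh * np.log(gh / rh)], axis=1)


def decode_boxes(ref: np.ndarray, deltas: np.ndarray,
                 weights=(1., 1., 1., 1.)) -> np.ndarray:
    """Inverse of :func:`encode_boxes`; dw/dh clamped for stability."""
    rw = ref[:, 2] - ref[:, 0]
    rh = ref[:, 3] - ref[:, 1]
    rx = ref[:, 0] + 0.5 * rw
    ry = ref[:, 1] + 0.5 * rh
    wx, wy, ww, wh = weights
    dx, dy, dw, dh = deltas[:, 0] / wx, deltas[:, 1] / wy, \
        deltas[:, 2] / ww, deltas[:, 3] / wh
    clamp = np.log(1000.0 / 16)
    dw = np.clip(dw, -clamp, clamp)
    dh = np.clip(dh, -clamp, clamp)
    cx = rx + dx * rw
    cy = ry + dy * rh
    w = rw * np.exp(dw)
    h = rh * np.exp(dh)
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def nms(boxes: np.ndarray, scores: np.ndarray, threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression on xyxy boxes; returns kept indices."""
    order = np.argsort(-scores, kind="mergesort")
    x1, y1, x2, y2 = boxes[:, 0], boxes[:, 1], boxes[:, 2], boxes[:, 3]
    areas = np.maximum(x2 - x1, 0) * np.maximum(y2 - y1, 0)
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ix = np.maximum(0, np.minimum(x2[i], x2[rest]) - np.maximum(x1[i], x1[rest]))
        iy = np.maximum(0, np.minimum(y2[i], y2[rest]) - np.maximum(y1[i], y1[rest]))
        inter = ix * iy
        union = areas[i] + areas[rest] - inter
        iou = np.where(union > 0, inter / union, 0.0)
        order = rest[iou <= threshold]
    return np.array(keep, dtype=int)


def _clip_xyxy(boxes: np.ndarray, height: int, width: int) -> np.ndarray:
    out = boxes.copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0, width)
    out[:, 1::2] = np.clip(out[:, 1::2], 0, height)
    return out


def _box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ix = np.maximum(0.0, np.minimum(a[:, None, 2], b[None, :, 2])
                    - np.maximum(a[:, None, 0], b[None, :, 0]))
    iy = np.maximum(0.0, np.minimum(a[:, None, 3], b[None, :, 3])
                    - np.maximum(a[:, None, 1], b[None, :, 1]))
    inter = ix * iy
    aa = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    ab = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = aa[:, None] + ab[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


# ---------------------------------------------------------------------------
# losses


class TrainingDivergence(RuntimeError):
    """A loss term went non-finite."""


@dataclass
class LossBreakdown:
    """The three training loss terms and their exact sum."""

    l_cls: float
    l_box: float
    l_mask: float

    @property
    def l_total(self) -> float:
        return self.l_cls + self.l_box + self.l_mask

    def as_dict(self) -> dict:
        return {"l_cls": self.l_cls, "l_box": self.l_box,
                "l_mask": self.l_mask, "l_total": self.l_total}


def total_loss(l_cls, l_box, l_mask) -> LossBreakdown:
    """Combine the three terms; raises :class:`TrainingDivergence` naming the
    first non-finite term."""
    vals = {}
    for name, term in (("l_cls", l_cls), ("l_box", l_box), ("l_mask", l_mask)):
        v = term.item() if isinstance(term, Tensor) else float(term)
        if not np.isfinite(v):
            raise TrainingDivergence(f"loss term {name} is non-finite ({v})")
        vals[name] = v
    return LossBreakdown(**vals)


def mask_loss(logits: Tensor, target: np.ndarray, class_index: int) -> Tensor:
    """Mean per-pixel sigmoid binary cross-entropy on one RoI.

    `logits` is (n_classes, m, m); only the target class's slice is
    supervised.  All-zero logits give exactly ln 2 for any target.
    """
    m = logits.shape[-1]
    if target.shape != (m, m):
        raise ValueError(f"target shape {target.shape} != ({m}, {m})")
    sel = logits[class_index]
    return nn.bce_with_logits(sel, target.astype(float), reduction="mean")


# ---------------------------------------------------------------------------
# network heads


class RPN(nn.Module):
    """Shared 3x3 conv + objectness / delta 1x1 heads over every level."""

    def __init__(self, in_channels: int, num_anchors: int = 3, rng=None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv = nn.Conv2d(in_channels, in_channels, 3, padding=1, rng=rng, dtype=dtype)
        self.obj = nn.Conv2d(in_channels, num_anchors, 1, rng=rng, dtype=dtype)
        self.delta = nn.Conv2d(in_channels, num_anchors * 4, 1, rng=rng, dtype=dtype)
        self.num_anchors = num_anchors

    def forward(self, pyramid: FeaturePyramid):
        """Per-level (objectness (N, A, H, W), deltas (N, 4A, H, W))."""
        out = {}
        for name, feat in pyramid.levels.items():
            h = self.conv(feat).relu()
            out[name] = (self.obj(h), self.delta(h))
        return out

    @staticmethod
    def flatten_level(obj: Tensor, delta: Tensor):
        """Reorder maps to (N, H*W*A) scores and (N, H*W*A, 4) deltas matching
        anchor ordering (row-major grid, template-minor)."""
        n, a, h, w = obj.shape
        scores = obj.transpose((0, 2, 3, 1)).reshape(n, h * w * a)
        deltas = delta.reshape(n, a, 4, h, w).transpose((0, 3, 4, 1, 2)) \
            .reshape(n, h * w * a, 4)
        return scores, deltas

    def propose(self, level_outputs, anchors_per_level: dict, image_size,
                pre_nms: int = 1000, post_nms: int = 300,
                nms_thresh: float = 0.7, min_size: float = 1.0):
        """Decode, clip, filter and NMS the per-level predictions.

        Returns per image (boxes xyxy, objectness scores), score-sorted.
        """
        hgt, wdt = image_size
        n = next(iter(level_outputs.values()))[0].shape[0]
        results = []
        for i in range(n):
            boxes_all, scores_all = [], []
            for name, (obj, delta) in level_outputs.items():
                scores_t, deltas_t = self.flatten_level(obj, delta)
                scores = scores_t.data[i]
                deltas = deltas_t.data[i]
                anchors = anchors_per_level[name]
                k = min(pre_nms, scores.shape[0])
                top = np.argpartition(-scores, k - 1)[:k] if k < scores.shape[0] \
                    else np.arange(scores.shape[0])
                boxes = decode_boxes(anchors[top], deltas[top])
                boxes = _clip_xyxy(boxes, hgt, wdt)
                ok = ((boxes[:, 2] - boxes[:, 0]) >= min_size) & \
                     ((boxes[:, 3] - boxes[:, 1]) >= min_size)
                boxes_all.append(boxes[ok])
                scores_all.append(scores[top][ok])
            boxes = np.concatenate(boxes_all, axis=0)
            scores = np.concatenate(scores_all, axis=0)
            order = np.argsort(-scores, kind="mergesort")[:pre_nms]
            boxes, scores = boxes[order], scores[order]
            keep = nms(boxes, scores, nms_thresh)[:post_nms]
            results.append((boxes[keep], scores[keep]))
        return results

    def loss(self, level_outputs, anchors_per_level: dict, gt_boxes_per_image,
             rng: np.random.Generator, batch_per_image: int = 256,
             pos_fraction: float = 0.5, pos_iou: float = 0.7,
             neg_iou: float = 0.3):
        """Sampled objectness BCE + smooth-L1 on positive anchor deltas."""
        level_names = list(level_outputs)
        anchors = np.concatenate([anchors_per_level[nm] for nm in level_names])
        n_img = next(iter(level_outputs.values()))[0].shape[0]
        scores_cat, deltas_cat = [], []
        for nm in level_names:
            s, d = self.flatten_level(*level_outputs[nm])
            scores_cat.append(s)
            deltas_cat.append(d)
        scores = nn.concatenate(scores_cat, axis=1)      # (N, total_A)
        deltas = nn.concatenate(deltas_cat, axis=1)      # (N, total_A, 4)
        obj_terms, box_terms = [], []
        for i in range(n_img):
            gt = np.asarray(gt_boxes_per_image[i], dtype=float).reshape(-1, 4)
            if gt.shape[0] == 0:
                labels = np.zeros(anchors.shape[0])
                neg_idx = rng.choice(anchors.shape[0],
                                     min(batch_per_image, anchors.shape[0]),
                                     replace=False)
                obj_terms.append(nn.bce_with_logits(scores[i][neg_idx],
                                                    labels[neg_idx]))
                continue
            iou = _box_iou_xyxy(anchors, gt)
            best_gt = iou.argmax(axis=1)
            best_iou = iou[np.arange(iou.shape[0]), best_gt]
            labels = np.full(anchors.shape[0], -1.0)     # -1 = ignored
            labels[best_iou < neg_iou] = 0.0
            labels[best_iou >= pos_iou] = 1.0
            # low-quality matches: every gt claims its best anchor(s)
            gt_best = iou.max(axis=0)
            for g in range(gt.shape[0]):
                labels[np.isclose(iou[:, g], gt_best[g]) & (iou[:, g] > 0)] = 1.0
                best_gt[np.isclose(iou[:, g], gt_best[g])] = g
            pos = np.nonzero(labels == 1.0)[0]
            neg = np.nonzero(labels == 0.0)[0]
            n_pos = min(len(pos), int(batch_per_image * pos_fraction))
            n_neg = min(len(neg), batch_per_image - n_pos)
            pos = rng.permutation(pos)[:n_pos]
            neg = rng.permutation(neg)[:n_neg]
            sel = np.concatenate([pos, neg])
            obj_terms.append(nn.bce_with_logits(scores[i][sel], labels[sel]))
            if len(pos):
                tgt = encode_boxes(anchors[pos], gt[best_gt[pos]])
                box_terms.append(nn.smooth_l1(deltas[i][pos], tgt,
                                              beta=1.0 / 9, reduction="sum")
                                 * (1.0 / max(len(sel), 1)))
        l_obj = obj_terms[0]
        for t in obj_terms[1:]:
            l_obj = l_obj + t
        l_obj = l_obj * (1.0 / n_img)
        if box_terms:
            l_box = box_terms[0]
            for t in box_terms[1:]:
                l_box = l_box + t
            l_box = l_box * (1.0 / n_img)
        else:
            l_box = Tensor(np.asarray(0.0))
        return l_obj, l_box


class BoxHead(nn.Module):
    """7x7 pooled features -> 2 FC -> class logits + per-class box deltas."""

    def __init__(self, in_channels: int, pool: int = 7, hidden: int = 1024,
                 num_classes: int = 2, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(in_channels * pool * pool, hidden, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(hidden, hidden, rng=rng, dtype=dtype)
        self.cls = nn.Linear(hidden, num_classes, rng=rng, dtype=dtype)
        self.reg = nn.Linear(hidden, num_classes * 4, rng=rng, dtype=dtype)
        # small init for the output layers stabilizes early training
        self.cls.weight.data *= 0.1
        self.reg.weight.data *= 0.1
        self.num_classes = num_classes
        self.pool = pool

    def forward(self, pooled: Tensor):
        n = pooled.shape[0]
        x = pooled.reshape(n, -1)
        x = self.fc1(x).relu()
        x = self.fc2(x).relu()
        return self.cls(x), self.reg(x)


class MaskHead(nn.Module):
    """14x14 pooled features -> convs -> 2x2 stride-2 deconv -> per-class
    m x m mask logits (m = 2 * pool size = 28 by default)."""

    def __init__(self, in_channels: int, conv_dim: int = 256, n_convs: int = 4,
                 num_classes: int = 2, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        convs = []
        ch = in_channels
        for _ in range(n_convs):
            convs.append(nn.Conv2d(ch, conv_dim, 3, padding=1, rng=rng, dtype=dtype))
            ch = conv_dim
        self.convs = convs
        self.deconv = nn.ConvTranspose2x2(ch, conv_dim, rng=rng, dtype=dtype)
        self.logit = nn.Conv2d(conv_dim, num_classes, 1, rng=rng, dtype=dtype)
        self.num_classes = num_classes

    def forward(self, pooled: Tensor) -> Tensor:
        x = pooled
        for c in self.convs:
            x = c(x).relu()
        x = self.deconv(x).relu()
        return self.logit(x)       # (R, n_classes, m, m)


# ---------------------------------------------------------------------------
# RoI orchestration


@dataclass
class Detection:
    """One final prediction: box, score, class and pasted binary mask."""

    bbox: tuple          # (x, y, w, h) in input pixels
    score: float
    class_index: int
    category: str
    mask: Optional[np.ndarray] = None     # full-image bool array


def _assign_levels(boxes: np.ndarray, available: list) -> list:
    """FPN heuristic: level k = floor(4 + log2(sqrt(area)/224)), clamped."""
    area = np.maximum((boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1]), 1e-6)
    k = np.floor(4 + np.log2(np.sqrt(area) / 224.0)).astype(int)
    lo = min(int(nm[1]) for nm in available)
    hi = max(int(nm[1]) for nm in available)
    k = np.clip(k, lo, hi)
    return [f"P{v}" for v in k]


class RoIHeads(nn.Module):
    """RoIAlign + box/mask branches with their sampling and losses."""

    BOX_WEIGHTS = (10.0, 10.0, 5.0, 5.0)

    def __init__(self, in_channels: int, num_classes: int = 2,
                 box_pool: int = 7, mask_pool: int = 14, hidden: int = 1024,
                 mask_conv_dim: int = 256, mask_n_convs: int = 4,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.box_head = BoxHead(in_channels, box_pool, hidden, num_classes, rng, dtype)
        self.mask_head = MaskHead(in_channels, mask_conv_dim, mask_n_convs,
                                  num_classes, rng, dtype)
        self.box_pool = box_pool
        self.mask_pool = mask_pool
        self.num_classes = num_classes

    # ---- pooling helpers
    def _pool(self, pyramid: FeaturePyramid, boxes: np.ndarray,
              batch_idx: np.ndarray, out_size: int) -> Tensor:
        """Multi-level RoIAlign gathering each box from its assigned level."""
        if boxes.shape[0] == 0:
            c = pyramid.channels
            dt = next(iter(pyramid.levels.values())).dtype
            return Tensor(np.zeros((0, c, out_size, out_size), dtype=dt))
        levels = _assign_levels(boxes, [nm for nm in pyramid.names if nm != "P6"])
        pieces, order = [], []
        for nm in pyramid.names:
            idx = [i for i, lv in enumerate(levels) if lv == nm]
            if not idx:
                continue
            idx_arr = np.asarray(idx)
            pooled = nn.roi_align(pyramid[nm], boxes[idx_arr], batch_idx[idx_arr],
                                  out_size, 1.0 / pyramid.strides[nm])
            pieces.append(pooled)
            order.extend(idx)
        cat = nn.concatenate(pieces, axis=0)
        inv = np.argsort(np.asarray(order))
        return cat[inv]

    # ---- training
    def sample_and_loss(self, pyramid: FeaturePyramid, proposals,
                        gt_boxes_per_image, gt_masks_per_image,
                        rng: np.random.Generator, batch_per_image: int = 64,
                        pos_fraction: float = 0.25, fg_iou: float = 0.5,
                        mask_size: int = 28):
        """Sample proposals, run both branches, return (l_cls, l_box, l_mask)."""
        all_boxes, all_bidx, all_labels, all_tgt = [], [], [], []
        fg_rows, fg_gt, fg_img = [], [], []
        row = 0
        for i, (prop, _) in enumerate(proposals):
            gt = np.asarray(gt_boxes_per_image[i], dtype=float).reshape(-1, 4)
            boxes = np.concatenate([prop, gt], axis=0) if gt.size else prop
            if boxes.shape[0] == 0:
                continue
            if gt.shape[0]:
                iou = _box_iou_xyxy(boxes, gt)
                best_gt = iou.argmax(axis=1)
                best_iou = iou[np.arange(len(boxes)), best_gt]
            else:
                best_gt = np.zeros(len(boxes), dtype=int)
                best_iou = np.zeros(len(boxes))
            fg = np.nonzero(best_iou >= fg_iou)[0]
            bg = np.nonzero(best_iou < fg_iou)[0]
            n_fg = min(len(fg), int(batch_per_image * pos_fraction))
            n_bg = min(len(bg), batch_per_image - n_fg)
            fg = rng.permutation(fg)[:n_fg]
            bg = rng.permutation(bg)[:n_bg]
            sel = np.concatenate([fg, bg]).astype(int)
            labels = np.zeros(len(sel), dtype=int)
            labels[:len(fg)] = 1
            tgt = np.zeros((len(sel), 4))
            if len(fg):
                tgt[:len(fg)] = encode_boxes(boxes[fg], gt[best_gt[fg]],
                                             self.BOX_WEIGHTS)
            all_boxes.append(boxes[sel])
            all_bidx.append(np.full(len(sel), i))
            all_labels.append(labels)
            all_tgt.append(tgt)
            for j, fidx in enumerate(fg):
                fg_rows.append(row + j)
                fg_gt.append(best_gt[fidx])
                fg_img.append(i)
            row += len(sel)
        if row == 0:
            zero = Tensor(np.asarray(0.0))
            return zero, zero, zero
        boxes = np.concatenate(all_boxes)
        bidx = np.concatenate(all_bidx)
        labels = np.concatenate(all_labels)
        tgt = np.concatenate(all_tgt)

        pooled = self._pool(pyramid, boxes, bidx, self.box_pool)
        cls_logits, reg = self.box_head(pooled)
        l_cls = nn.softmax_cross_entropy(cls_logits, labels)
        fg_all = np.nonzero(labels == 1)[0]
        if len(fg_all):
            r = reg.reshape(reg.shape[0], self.num_classes, 4)
            r_fg = r[fg_all, labels[fg_all]]
            l_box = nn.smooth_l1(r_fg, tgt[fg_all], beta=1.0,
                                 reduction="sum") * (1.0 / max(len(labels), 1))
        else:
            l_box = Tensor(np.asarray(0.0))

        # mask branch on foreground RoIs
        if fg_rows:
            fg_rows_arr = np.asarray(fg_rows)
            fg_boxes = boxes[fg_rows_arr]
            fg_bidx = bidx[fg_rows_arr]
            mpooled = self._pool(pyramid, fg_boxes, fg_bidx, self.mask_pool)
            mlogits = self.mask_head(mpooled)      # (F, n_cls, m, m)
            m = mlogits.shape[-1]
            targets = np.zeros((len(fg_rows), m, m))
            for j, (gi, ii) in enumerate(zip(fg_gt, fg_img)):
                gm = gt_masks_per_image[ii][gi].astype(np.float32)
                crop = nn.roi_align(Tensor(gm[None, None]), fg_boxes[j:j + 1],
                                    np.array([0]), m, 1.0, 2)
                targets[j] = crop.data[0, 0] >= 0.5
            sel_logits = mlogits[np.arange(len(fg_rows)), np.ones(len(fg_rows), dtype=int)]
            l_mask = nn.bce_with_logits(sel_logits, targets)
        else:
            l_mask = Tensor(np.asarray(0.0))
        return l_cls, l_box, l_mask

    # ---- inference
    def predict(self, pyramid: FeaturePyramid, proposals, image_size,
                score_thresh: float = 0.05, nms_thresh: float = 0.5,
                max_detections: int = 100, category: str = "grape",
                mask_threshold: float = 0.5):
        """Final per-image detections with pasted binary masks, score-sorted."""
        from skimage.transform import resize as sk_resize
        hgt, wdt = image_size
        out = []
        for i, (prop, _) in enumerate(proposals):
            if prop.shape[0] == 0:
                out.append([])
                continue
            bidx = np.full(len(prop), i)
            pooled = self._pool(pyramid, prop, bidx, self.box_pool)
            cls_logits, reg = self.box_head(pooled)
            z = cls_logits.data
            ez = np.exp(z - z.max(axis=1, keepdims=True))
            probs = ez / ez.sum(axis=1, keepdims=True)
            scores = probs[:, 1]                       # grape class
            deltas = reg.data.reshape(len(prop), self.num_classes, 4)[:, 1]
            boxes = decode_boxes(prop, deltas, self.BOX_WEIGHTS)
            boxes = _clip_xyxy(boxes, hgt, wdt)
            ok = (scores >= score_thresh) & \
                 ((boxes[:, 2] - boxes[:, 0]) > 1) & ((boxes[:, 3] - boxes[:, 1]) > 1)
            boxes, scores = boxes[ok], scores[ok]
            if boxes.shape[0] == 0:
                out.append([])
                continue
            keep = nms(boxes, scores, nms_thresh)[:max_detections]
            boxes, scores = boxes[keep], scores[keep]
            order = np.argsort(-scores, kind="mergesort")
            boxes, scores = boxes[order], scores[order]

            mpooled = self._pool(pyramid, boxes, np.full(len(boxes), i),
                                 self.mask_pool)
            mlogits = self.mask_head(mpooled).data
            dets = []
            for j in range(len(boxes)):
                x1, y1, x2, y2 = boxes[j]
                xi1, yi1 = int(np.floor(x1)), int(np.floor(y1))
                xi2, yi2 = min(int(np.ceil(x2)), wdt), min(int(np.ceil(y2)), hgt)
                full = np.zeros((hgt, wdt), dtype=bool)
                if xi2 > xi1 and yi2 > yi1:
                    prob = 1.0 / (1.0 + np.exp(-mlogits[j, 1]))
                    patch = sk_resize(prob, (yi2 - yi1, xi2 - xi1), order=1,
                                      anti_aliasing=False, preserve_range=True)
                    full[yi1:yi2, xi1:xi2] = patch >= mask_threshold
                dets.append(Detection(
                    bbox=(float(x1), float(y1), float(x2 - x1), float(y2 - y1)),
                    score=float(scores[j]), class_index=1, category=category,
                    mask=full))
            out.append(dets)
        return out
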