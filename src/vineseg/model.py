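"""The improved Mask R-CNN: ResNet50-FPN-ED backbone + RPN + RoI heads.

Two presets are provided.  ``full_scale`` is the full architecture
(ResNet50 stages, 256-channel pyramid, 1024-wide box head, four 256-channel
mask convolutions).  ``test_scale`` keeps the identical topology — ECA gates,
DUC fusion, five pyramid levels, both branches — at reduced width/depth so
the whole train/predict path runs in seconds per iteration on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor
from .backbone import BackboneED
from .heads import (RPN, RoIHeads, build_anchor_templates, generate_level_anchors,
                    total_loss, LossBreakdown, Detection)

__all__ = ["ModelConfig", "MaskRCNN"]

_IMAGE_MEAN = np.array([123.675, 116.28, 103.53], dtype=np.float32)
_IMAGE_STD = np.array([58.395, 57.12, 57.375], dtype=np.float32)


@dataclass
class ModelConfig:
    """Architecture + inference hyperparameters (defaults = full scale)."""

    preset: str = "full"
    anchor_scales: tuple = (8, 16, 32, 64, 128)
    anchor_ratios: tuple = (0.5, 1.0, 2.0)
    fpn_channels: int = 256
    use_eca: bool = True
    use_duc: bool = True
    eca_gamma: float = 2.0
    eca_b: float = 1.0
    frozen_bn: bool = False
    stem_width: int = 64
    widths: tuple = (64, 128, 256, 512)
    blocks: tuple = (3, 4, 6, 3)
    box_head_hidden: int = 1024
    mask_conv_dim: int = 256
    mask_n_convs: int = 4
    box_pool: int = 7
    mask_pool: int = 14
    mask_size: int = 28
    num_classes: int = 2            # background + grape
    rpn_pre_nms: int = 1000
    rpn_post_nms_train: int = 300
    rpn_post_nms_test: int = 300
    rpn_nms_thresh: float = 0.7
    score_thresh: float = 0.05
    detection_nms_thresh: float = 0.5
    max_detections: int = 100
    roi_batch_per_image: int = 64
    rpn_batch_per_image: int = 256
    seed: int = 0

    @classmethod
    def test_scale(cls, **kw) -> "ModelConfig":
        kw.setdefault("preset", "test")
        kw.setdefault("stem_width", 16)
        kw.setdefault("widths", (16, 32, 64, 128))
        kw.setdefault("blocks", (1, 1, 1, 1))
        kw.setdefault("fpn_channels", 64)
        kw.setdefault("box_head_hidden", 128)
        kw.setdefault("mask_conv_dim", 64)
        kw.setdefault("mask_n_convs", 2)
        kw.setdefault("frozen_bn", True)
        return cls(**kw)


class MaskRCNN(nn.Module):
    def __init__(self, config: Optional[ModelConfig] = None, dtype=np.float32):
        super().__init__()
        self.config = config or ModelConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        self.backbone = BackboneED(c.stem_width, c.widths, c.blocks,
                                   c.fpn_channels, c.use_eca, c.use_duc,
                                   c.eca_gamma, c.eca_b, c.frozen_bn, rng, dtype)
        self.rpn = RPN(c.fpn_channels, len(c.anchor_ratios), rng, dtype)
        self.roi_heads = RoIHeads(c.fpn_channels, c.num_classes, c.box_pool,
                                  c.mask_pool, c.box_head_hidden,
                                  c.mask_conv_dim, c.mask_n_convs, rng, dtype)
        self.templates = build_anchor_templates(c.anchor_scales, c.anchor_ratios)
        self._dtype = dtype

    # ---- preprocessing
    def preprocess(self, images) -> tuple:
        """Stack uint8 HxWx3 images into a normalized, padded (N,3,H,W) batch.

        Sides are zero-padded (right/bottom) to the next multiple of 64 so
        every pyramid level has exact integer geometry; the original sizes
        are returned for coordinate un-mapping.
        """
        if isinstance(images, np.ndarray) and images.ndim == 3:
            images = [images]
        sizes = [(im.shape[0], im.shape[1]) for im in images]
        H = max(h for h, _ in sizes)
        W = max(w for _, w in sizes)
        H = int(np.ceil(H / 64.0)) * 64
        W = int(np.ceil(W / 64.0)) * 64
        batch = np.zeros((len(images), 3, H, W), dtype=self._dtype)
        for i, im in enumerate(images):
            if im.ndim != 3 or im.shape[2] != 3:
                raise ValueError("expected HxWx3 RGB images")
            x = (im.astype(np.float32) - _IMAGE_MEAN) / _IMAGE_STD
            batch[i, :, :im.shape[0], :im.shape[1]] = x.transpose(2, 0, 1)
        return Tensor(batch), sizes

    def _anchors_for(self, pyramid) -> dict:
        out = {}
        for name, feat in pyramid.levels.items():
            _, _, h, w = feat.shape
            out[name] = generate_level_anchors(self.templates, name, h, w,
                                               pyramid.strides[name])
        return out

    # ---- training
    def training_losses(self, images, gt_boxes, gt_masks,
                        rng: np.random.Generator):
        """One forward pass returning (total loss Tensor, LossBreakdown).

        gt_boxes: per image (K, 4) xyxy arrays; gt_masks: per image list of
        full-image boolean masks aligned with the boxes.
        """
        c = self.config
        x, sizes = self.preprocess(images)
        pyramid = self.backbone(x)
        anchors = self._anchors_for(pyramid)
        level_out = self.rpn(pyramid)
        l_obj, l_rpn_box = self.rpn.loss(level_out, anchors, gt_boxes, rng,
                                         batch_per_image=c.rpn_batch_per_image)
        proposals = self.rpn.propose(level_out, anchors, x.shape[2:],
                                     pre_nms=c.rpn_pre_nms,
                                     post_nms=c.rpn_post_nms_train,
                                     nms_thresh=c.rpn_nms_thresh)
        l_cls, l_box, l_mask = self.roi_heads.sample_and_loss(
            pyramid, proposals, gt_boxes, gt_masks, rng,
            batch_per_image=c.roi_batch_per_image, mask_size=c.mask_size)
        # Eq-style decomposition: classification (RPN objectness + RoI class),
        # box regression (both stages), mask — summed without coefficients.
        t_cls = l_obj + l_cls
        t_box = l_rpn_box + l_box
        t_mask = l_mask
        breakdown = total_loss(t_cls, t_box, t_mask)
        return t_cls + t_box + t_mask, breakdown

    # ---- inference
    def predict(self, images) -> list:
        """Score-sorted detections with pasted binary masks, per image."""
        c = self.config
        was_training = self.training
        self.eval()
        x, sizes = self.preprocess(images)
        pyramid = self.backbone(x)
        anchors = self._anchors_for(pyramid)
        level_out = self.rpn(pyramid)
        proposals = self.rpn.propose(level_out, anchors, x.shape[2:],
                                     pre_nms=c.rpn_pre_nms,
                                     post_nms=c.rpn_post_nms_test,
                                     nms_thresh=c.rpn_nms_thresh)
        dets = self.roi_heads.predict(pyramid, proposals, x.shape[2:],
                                      score_thresh=c.score_thresh,
                                      nms_thresh=c.detection_nms_thresh,
                                      max_detections=c.max_detections)
        # crop masks/boxes back to each true (unpadded) image size
        clipped = []
        for (h, w), image_dets in zip(sizes, dets):
            kept = []
            for d in image_dets:
                mask = d.mask[:h, :w] if d.mask is not None else None
                x0, y0, bw, bh = d.bbox
                x0c, y0c = min(x0, w), min(y0, h)
                bwc = max(min(x0 + bw, w) - x0c, 0.0)
                bhc = max(min(y0 + bh, h) - y0c, 0.0)
                if bwc <= 0 or bhc <= 0:
                    continue
                kept.append(Detection(bbox=(x0c, y0c, bwc, bhc), score=d.score,
                                      class_index=d.class_index,
                                      category=d.category, mask=mask))
            clipped.append(kept)
        if was_training:
            self.train()
        return clipped

    def predict_coco(self, images, image_ids) -> list:
        """COCO-results-style records (with dense masks attached)."""
        out = []
        for img_id, dets in zip(image_ids, self.predict(images)):
            for d in dets:
                out.append({"image_id": int(img_id), "category_id": 1,
                            "bbox": [round(float(v), 2) for v in d.bbox],
                            "score": float(d.score), "mask": d.mask})
        return out

    # ---- checkpointing
    def save_checkpoint(self, path, rng_state: Optional[dict] = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = self.state_dict()
        meta = {"config": asdict(self.config),
                "rng_state": rng_state or {},
                "keys": sorted(state)}
        np.savez(path, __meta__=json.dumps(meta), **state)

    @classmethod
    def load_checkpoint(cls, path, dtype=np.float32) -> "MaskRCNN":
        with np.load(Path(path), allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in meta["config"].items()})
            model = cls(cfg, dtype=dtype)
            state = {k: npz[k] for k in npz.files if k != "__meta__"}
        model.load_state_dict(state, strict=False)
        return model
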