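"""Training, evaluation and prediction orchestration.

The default recipe is the field-data one: 50 epochs at batch size 2 with
SGD (momentum 0.9, weight decay 1e-4), initial learning rate 0.01 decayed by
0.1 every 5,000 iterations, online mirror/rotation/crop/color augmentation
and multiscale resizing (short edge 640..800 step 32, long edge capped at
1,443 px).  The schedule is iteration-based and independent of epoch
bookkeeping.  The tested CPU path runs the identical loop on the test-scale
model with augmentation scaled to the synthetic scenes.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from . import nn
from .annotations import load_coco, rasterize_instance
from .augment import AugmentConfig, Instances, augment_sample, resize_multiscale
from .cocoeval import MetricsReport, evaluate
from .heads import TrainingDivergence
from .model import MaskRCNN, ModelConfig

__all__ = ["TrainConfig", "RunLog", "lr_schedule", "load_dataset", "train",
           "evaluate_model"]


@dataclass
class TrainConfig:
    """Optimization recipe; defaults follow the published training setup."""

    epochs: int = 50
    batch_size: int = 2
    initial_lr: float = 0.01
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 5000          # iterations
    weight_decay: float = 1e-4
    momentum: float = 0.9
    clip_grad_norm: float = 10.0
    augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    multiscale: bool = True
    short_edges: tuple = tuple(range(640, 801, 32))
    max_edge: int = 1443
    iterations: Optional[int] = None    # overrides epochs when set
    checkpoint_every: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr_decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.initial_lr <= 0 or self.lr_decay_factor <= 0:
            raise ValueError("learning-rate parameters must be positive")
        if self.multiscale and not self.short_edges:
            raise ValueError("short-edge set must be nonempty")


def lr_schedule(iteration: int, config: Optional[TrainConfig] = None) -> float:
    """Step schedule: lr = initial * factor^floor(iteration / every)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    c = config or TrainConfig()
    return c.initial_lr * c.lr_decay_factor ** (iteration // c.lr_decay_every)


@dataclass
class RunLog:
    """Per-iteration loss/lr trace plus the reproducibility envelope."""

    seed: int
    config: dict
    environment: dict = field(default_factory=dict)
    records: list = field(default_factory=list)

    def append(self, iteration: int, lr: float, breakdown) -> None:
        self.records.append({"iteration": iteration, "lr": lr,
                             **breakdown.as_dict()})

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")

    @staticmethod
    def environment_fingerprint() -> dict:
        return {"python": sys.version.split()[0],
                "numpy": np.__version__,
                "platform": platform.platform()}


def load_dataset(coco_json, image_dir) -> list:
    """Materialize a COCO dataset into training samples.

    Returns a list of dicts with image (uint8 HxWx3), instance polygon parts,
    xyxy boxes, full-image boolean masks, image_id and file_name.
    """
    doc = load_coco(coco_json)
    image_dir = Path(image_dir)
    anns_by_img = {}
    for a in doc["annotations"]:
        anns_by_img.setdefault(a["image_id"], []).append(a)
    samples = []
    for im in doc["images"]:
        arr = np.asarray(Image.open(image_dir / im["file_name"]).convert("RGB"))
        parts_per_inst, boxes, masks = [], [], []
        for a in anns_by_img.get(im["id"], []):
            parts = [np.asarray(p, dtype=float).reshape(-1, 2).tolist()
                     for p in a["segmentation"]]
            parts_per_inst.append(parts)
            x, y, w, h = a["bbox"]
            boxes.append([x, y, x + w, y + h])
            masks.append(rasterize_instance(parts, im["height"], im["width"]))
        samples.append({"image": arr,
                        "instances": Instances(parts=parts_per_inst),
                        "boxes": np.asarray(boxes, dtype=float).reshape(-1, 4),
                        "masks": masks,
                        "image_id": im["id"],
                        "file_name": im["file_name"]})
    return samples


def _prepare_batch(samples, config: TrainConfig, rng: np.random.Generator):
    images, boxes, masks = [], [], []
    for s in samples:
        img = s["image"]
        inst = s.get("instances")
        if (config.augment or config.multiscale) and inst is None:
            raise KeyError("augmentation requires polygon 'instances' in samples")
        if config.augment:
            img, inst, _ = augment_sample(img, inst, config.augment_config, rng)
        if config.multiscale:
            edge = int(rng.choice(config.short_edges))
            img, inst, _ = resize_multiscale(img, inst, edge, config.max_edge)
        if config.augment or config.multiscale:
            h, w = img.shape[:2]
            if inst.n:
                bxs = inst.bboxes_xyxy()
                msks = inst.masks(h, w)
            else:
                bxs = np.zeros((0, 4))
                msks = []
        else:
            bxs, msks = s["boxes"], s["masks"]
        images.append(img)
        boxes.append(bxs)
        masks.append(msks)
    return images, boxes, masks


def train(dataset: list, config: TrainConfig, model: Optional[MaskRCNN] = None,
          model_config: Optional[ModelConfig] = None,
          out_dir=None, log_every: int = 0):
    """SGD training of the three-term objective; returns (model, RunLog).

    Fully seeded: the same (dataset, config, model seed) reproduces the loss
    trace bit-for-bit.  On a non-finite loss the last stable checkpoint is
    written (if `out_dir` is given) and :class:`TrainingDivergence` is raised.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    model = model or MaskRCNN(model_config or ModelConfig.test_scale())
    rng = np.random.default_rng(config.seed)
    n_iters = config.iterations
    if n_iters is None:
        n_iters = config.epochs * max(len(dataset) // config.batch_size, 1)
    opt = nn.SGD(model.parameters(), lr=config.initial_lr,
                 momentum=config.momentum, weight_decay=config.weight_decay,
                 clip_grad_norm=config.clip_grad_norm)
    log = RunLog(seed=config.seed, config=asdict(config) | {"iterations_resolved": n_iters},
                 environment=RunLog.environment_fingerprint())
    out_dir = Path(out_dir) if out_dir is not None else None
    model.train()
    for it in range(n_iters):
        opt.lr = lr_schedule(it, config)
        idx = rng.choice(len(dataset), size=min(config.batch_size, len(dataset)),
                         replace=False)
        images, boxes, masks = _prepare_batch([dataset[i] for i in idx], config, rng)
        opt.zero_grad()
        loss, breakdown = model.training_losses(images, boxes, masks, rng)
        if not np.isfinite(breakdown.l_total):
            if out_dir is not None:
                model.save_checkpoint(out_dir / "last_stable.npz")
            raise TrainingDivergence(
                f"non-finite total loss at iteration {it}: {breakdown.as_dict()}")
        loss.backward()
        opt.step()
        log.append(it, opt.lr, breakdown)
        if log_every and it % log_every == 0:
            print(f"iter {it:5d}  lr {opt.lr:.5f}  total {breakdown.l_total:.4f}  "
                  f"(cls {breakdown.l_cls:.4f} box {breakdown.l_box:.4f} "
                  f"mask {breakdown.l_mask:.4f})")
        if out_dir is not None and config.checkpoint_every and \
                (it + 1) % config.checkpoint_every == 0:
            model.save_checkpoint(out_dir / f"checkpoint_{it + 1:06d}.npz")
    if out_dir is not None:
        model.save_checkpoint(out_dir / "final.npz")
        log.save(out_dir / "runlog.jsonl")
    return model, log


def evaluate_model(model: MaskRCNN, coco_gt, image_dir,
                   results_json=None) -> dict:
    """Predict over a COCO test set and report box + segm metrics.

    Returns {"box": MetricsReport, "segm": MetricsReport, "results": [...]}.
    """
    gt = load_coco(coco_gt)
    if not gt["images"]:
        raise ValueError("empty test set")
    image_dir = Path(image_dir)
    results = []
    for im in gt["images"]:
        arr = np.asarray(Image.open(image_dir / im["file_name"]).convert("RGB"))
        results.extend(model.predict_coco([arr], [im["id"]]))
    if results_json is not None:
        serializable = [{k: v for k, v in r.items() if k != "mask"}
                        for r in results]
        with open(results_json, "w") as fh:
            json.dump(serializable, fh)
    return {"box": evaluate(gt, results, "box"),
            "segm": evaluate(gt, results, "segm"),
            "results": results}
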