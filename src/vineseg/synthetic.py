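"""Synthetic vineyard scenes with occlusion-split, group-id-annotated clusters.

The generator does not aim at photorealism; its contract is the annotation
structure the real field data has: images with 1–20 cluster-shaped objects
built from overlapping berry discs, bar-shaped trunk/wire occluders that can
split a cluster into disjoint visible parts (which then share a group id,
exactly as an annotator would tag them), a near/far scale regime emulating
the two capture distances (50–100 cm vs 100–150 cm), and global photometric
jitter emulating down-light vs back-light shots.

Polygons are derived from the *visible* pixels by contour extraction — the
same thing an annotator traces — and each instance's stored ground-truth mask
is the rasterization of its polygons, so annotation fidelity (polygons ↔
masks) holds pixel-for-pixel by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import measure

from .annotations import PolygonShape, merge_group_instances, rasterize_instance

__all__ = ["SceneConfig", "SyntheticScene", "generate_scene", "generate_dataset",
           "scenes_to_coco", "scenes_to_samples"]

_BERRY_BASE = np.array([150.0, 165.0, 95.0])     # Chardonnay-ish green-gold
_OCCLUDER_COLOR = np.array([70.0, 50.0, 35.0])   # trunk / wire brown
_BG_BASE = np.array([60.0, 85.0, 55.0])          # foliage


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene family.

    ``scale_regime='near'`` emulates the close capture distance (fewer,
    larger clusters per frame); ``'far'`` the distant one (more, smaller).
    Passing explicit ranges overrides the regime presets.
    """

    image_height: int = 256
    image_width: int = 256
    n_clusters_range: tuple = None
    berries_per_cluster_range: tuple = (8, 16)
    berry_radius_range: tuple = None
    occluder_probability: float = 0.5
    occluder_width_range: tuple = (4, 9)
    scale_regime: str = "near"
    brightness_range: tuple = (0.75, 1.25)
    contrast_range: tuple = (0.85, 1.15)
    saturation_range: tuple = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if self.scale_regime not in ("near", "far"):
            raise ValueError(f"unknown scale_regime {self.scale_regime!r}")
        if self.n_clusters_range is None:
            self.n_clusters_range = (1, 5) if self.scale_regime == "near" else (6, 14)
        if self.berry_radius_range is None:
            self.berry_radius_range = (6, 11) if self.scale_regime == "near" else (3, 6)
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        for name in ("n_clusters_range", "berries_per_cluster_range",
                     "berry_radius_range", "occluder_width_range",
                     "brightness_range", "contrast_range", "saturation_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} must be a nonempty nonnegative range, got ({lo}, {hi})")
        if not (0.0 <= self.occluder_probability <= 1.0):
            raise ValueError("occluder_probability must be in [0, 1]")

    @classmethod
    def tiny(cls, seed: int = 0, **kw) -> "SceneConfig":
        """128x128, <=3 clusters — the CI / overfit preset."""
        kw.setdefault("image_height", 128)
        kw.setdefault("image_width", 128)
        kw.setdefault("n_clusters_range", (1, 3))
        kw.setdefault("berries_per_cluster_range", (6, 12))
        kw.setdefault("berry_radius_range", (5, 9))
        return cls(seed=seed, **kw)


@dataclass
class SyntheticScene:
    """One generated scene: image, traced polygons, per-instance GT masks."""

    image: np.ndarray                 # H x W x 3 uint8
    shapes: list                      # list[PolygonShape]; split parts share group_id
    masks: list                       # list[np.ndarray bool], one per instance
    instance_parts: list = field(default_factory=list)  # parts count per instance

    @property
    def n_instances(self) -> int:
        return len(self.masks)


def _draw_cluster(rng, img, radius_range, berry_range, h, w, occupied):
    """Scatter berry discs around an elliptical envelope; returns the painted
    boolean mask or None if no free location was found."""
    rmax = radius_range[1]
    n_berries = int(rng.integers(berry_range[0], berry_range[1] + 1))
    ax = float(rng.uniform(1.2, 2.2)) * rmax          # envelope semi-axes
    ay = float(rng.uniform(1.8, 3.0)) * rmax
    margin = int(np.ceil(max(ax, ay) + rmax)) + 1
    if 2 * margin >= min(h, w):
        margin = min(h, w) // 2 - 1
    for _ in range(30):                                # rejection sampling
        cx = float(rng.uniform(margin, w - margin))
        cy = float(rng.uniform(margin, h - margin))
        y0, y1 = int(cy - margin), int(cy + margin) + 1
        x0, x1 = int(cx - margin), int(cx + margin) + 1
        if not occupied[max(y0, 0):y1, max(x0, 0):x1].any():
            break
    else:
        return None
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_berries):
        t = float(rng.uniform(0, 2 * np.pi))
        rad = np.sqrt(float(rng.uniform(0, 1)))
        bx = cx + rad * ax * np.cos(t)
        by = cy + rad * ay * np.sin(t)
        br = int(rng.integers(radius_range[0], radius_range[1] + 1))
        disc = (yy - by) ** 2 + (xx - bx) ** 2 <= br * br
        color = np.clip(_BERRY_BASE + rng.normal(0, 12, 3), 0, 255)
        img[disc] = color
        mask |= disc
    if not mask.any():
        return None
    return mask


def _mask_to_polygons(mask: np.ndarray, h: int, w: int, min_area: int = 12) -> list:
    """Trace each filled connected component of a visible mask as one polygon
    (marching squares at level 0.5, coordinates clipped into bounds)."""
    lab, n = ndi.label(mask)
    polys = []
    for i in range(1, n + 1):
        comp = ndi.binary_fill_holes(lab == i)
        if comp.sum() < min_area:
            continue
        padded = np.pad(comp.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)               # outer contour
        pts = contour[:, ::-1] - 1.0                   # (row, col) -> (x, y), unpad
        pts[:, 0] = np.clip(pts[:, 0], 0.0, w - 0.5)
        pts[:, 1] = np.clip(pts[:, 1], 0.0, h - 0.5)
        if len(pts) >= 3:
            polys.append([(float(x), float(y)) for x, y in pts])
    return polys


def generate_scene(config: SceneConfig, seed: Optional[int] = None) -> SyntheticScene:
    """Render one scene; identical (config, seed) pairs are bit-identical."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.image_height, config.image_width
    img = np.empty((h, w, 3))
    img[:] = _BG_BASE
    img += rng.normal(0, 10, (h, w, 3))

    n_clusters = int(rng.integers(config.n_clusters_range[0],
                                  config.n_clusters_range[1] + 1))
    cluster_masks = []
    occupied = np.zeros((h, w), dtype=bool)
    for _ in range(n_clusters):
        m = _draw_cluster(rng, img, config.berry_radius_range,
                          config.berries_per_cluster_range, h, w, occupied)
        if m is not None:
            cluster_masks.append(m)
            occupied |= ndi.binary_dilation(m, iterations=2)

    # bar-shaped trunk / wire occluders, drawn AFTER the clusters
    occluder = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for m in cluster_masks:
        if rng.random() >= config.occluder_probability:
            continue
        ys, xs = np.nonzero(m)
        cy, cx = ys.mean(), xs.mean()
        vertical = bool(rng.random() < 0.5)
        width = int(rng.integers(config.occluder_width_range[0],
                                 config.occluder_width_range[1] + 1))
        offset = float(rng.uniform(-2.0, 2.0))
        slope = float(rng.uniform(-0.15, 0.15))
        if vertical:
            dist = np.abs(xx - (cx + offset) - slope * (yy - cy))
        else:
            dist = np.abs(yy - (cy + offset) - slope * (xx - cx))
        occluder |= dist <= width / 2.0
    img[occluder] = _OCCLUDER_COLOR + rng.normal(0, 4, 3)

    # trace visible parts; split parts share a fresh group id
    shapes, group_ids = [], []
    next_gid = 1
    for m in cluster_masks:
        visible = m & ~occluder
        polys = _mask_to_polygons(visible, h, w)
        if not polys:
            continue
        gid = None
        if len(polys) > 1:
            gid = next_gid
            next_gid += 1
        for p in polys:
            shapes.append(PolygonShape(label="grape", points=p, group_id=gid))

    # photometric jitter (image only — geometry already traced)
    bright = float(rng.uniform(*config.brightness_range))
    contrast = float(rng.uniform(*config.contrast_range))
    sat = float(rng.uniform(*config.saturation_range))
    img = img * bright
    img = (img - img.mean()) * contrast + img.mean()
    gray = img.mean(axis=2, keepdims=True)
    img = gray + (img - gray) * sat
    image = np.clip(img, 0, 255).astype(np.uint8)

    records = merge_group_instances(shapes)
    masks = [rasterize_instance(rec, h, w) for rec in records]
    parts = [rec.n_parts for rec in records]
    return SyntheticScene(image=image, shapes=shapes, masks=masks,
                          instance_parts=parts)


def scenes_to_coco(scenes) -> dict:
    """In-memory COCO ground truth for a list of scenes (ids start at 1)."""
    images, anns = [], []
    aid = 1
    for i, sc in enumerate(scenes):
        h, w = sc.image.shape[:2]
        images.append({"id": i + 1, "file_name": f"scene_{i:04d}.png",
                       "height": h, "width": w})
        for rec, m in zip(merge_group_instances(sc.shapes), sc.masks):
            anns.append({
                "id": aid, "image_id": i + 1, "category_id": 1,
                "segmentation": [[v for xy in p for v in xy] for p in rec.parts],
                "bbox": list(rec.bbox), "area": float(m.sum()), "iscrowd": 0})
            aid += 1
    return {"images": images, "annotations": anns,
            "categories": [{"id": 1, "name": "grape"}]}


def scenes_to_samples(scenes) -> list:
    """Training samples (image, xyxy boxes, masks) for a list of scenes."""
    samples = []
    for sc in scenes:
        recs = merge_group_instances(sc.shapes)
        boxes = np.array([[r.bbox[0], r.bbox[1], r.bbox[0] + r.bbox[2],
                           r.bbox[1] + r.bbox[3]] for r in recs]).reshape(-1, 4)
        samples.append({"image": sc.image, "boxes": boxes, "masks": sc.masks})
    return samples


def generate_dataset(config: SceneConfig, n_images: int, out_dir) -> dict:
    """Write ``n_images`` PNG + LabelMe-style JSON pairs plus a manifest.

    Per-image seeds are spawned deterministically from ``config.seed`` so the
    whole dataset is reproducible from (config, n_images).
    """
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(max(n_images, 1))
    entries = []
    for i in range(n_images):
        scene = generate_scene(config, seed=int(seeds[i] % (2 ** 31)))
        stem = f"scene_{i:04d}"
        img_name, json_name = f"{stem}.png", f"{stem}.json"
        Image.fromarray(scene.image).save(out_dir / img_name)
        doc = {
            "imagePath": img_name,
            "imageHeight": config.image_height,
            "imageWidth": config.image_width,
            "shapes": [
                {"label": s.label,
                 "points": [[round(x, 3), round(y, 3)] for x, y in s.points],
                 "group_id": s.group_id}
                for s in scene.shapes
            ],
        }
        with open(out_dir / json_name, "w") as fh:
            json.dump(doc, fh)
        entries.append({"image": img_name, "annotation": json_name,
                        "n_instances": scene.n_instances})
    manifest = {"config": {**asdict(config)}, "n_images": n_images, "images": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
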