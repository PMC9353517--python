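"""Online augmentation with exact geometry bookkeeping.

Geometric transforms (mirror, rotation, crop, multiscale resize) are applied
identically to the image and to the instance polygons; boxes are always
recomputed from the transformed polygons and masks re-rasterized, so geometry
can never drift out of sync with the pixels.  Photometric jitter (brightness,
contrast, saturation) touches the image only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon, box as shapely_box
from skimage.transform import rotate as sk_rotate, resize as sk_resize

from .annotations import polygon_to_bbox, rasterize_instance

__all__ = ["AugmentConfig", "Instances", "augment_sample", "resize_multiscale"]


@dataclass
class AugmentConfig:
    horizontal_mirror: bool = True
    vertical_mirror: bool = True
    rotation: bool = True
    rotation_deg: float = 15.0
    crop: bool = True
    crop_range: tuple = (0.8, 1.0)
    color: bool = True
    brightness_range: tuple = (0.75, 1.25)
    contrast_range: tuple = (0.85, 1.15)
    saturation_range: tuple = (0.8, 1.2)


@dataclass
class Instances:
    """Per-image instance geometry: polygon parts per instance (+ labels)."""

    parts: list                       # list per instance of list of point lists
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = ["grape"] * len(self.parts)

    @property
    def n(self) -> int:
        return len(self.parts)

    def bboxes_xywh(self) -> np.ndarray:
        return np.array([polygon_to_bbox(p) for p in self.parts]).reshape(-1, 4)

    def bboxes_xyxy(self) -> np.ndarray:
        b = self.bboxes_xywh()
        out = b.copy()
        out[:, 2] += b[:, 0]
        out[:, 3] += b[:, 1]
        return out

    def masks(self, height: int, width: int) -> list:
        return [rasterize_instance(p, height, width) for p in self.parts]


def _transform_points(parts, fn):
    return [[[tuple(fn(np.asarray(pt, dtype=float))) for pt in poly]
             for poly in inst] for inst in parts]


def _apply_color(image: np.ndarray, rng, cfg: AugmentConfig) -> np.ndarray:
    img = image.astype(np.float64)
    img *= rng.uniform(*cfg.brightness_range)
    m = img.mean()
    img = (img - m) * rng.uniform(*cfg.contrast_range) + m
    gray = img.mean(axis=2, keepdims=True)
    img = gray + (img - gray) * rng.uniform(*cfg.saturation_range)
    return np.clip(img, 0, 255).astype(np.uint8)


def _clip_instances(parts, width: float, height: float, min_area: float = 4.0):
    """Intersect every polygon part with the image window; instances whose
    every part vanishes are dropped.  Returns (clipped parts, kept indices)."""
    window = shapely_box(0.0, 0.0, width, height)
    kept_parts, kept_idx = [], []
    for i, inst in enumerate(parts):
        new_inst = []
        for poly in inst:
            try:
                sp = ShapelyPolygon(poly)
                if not sp.is_valid:
                    sp = sp.buffer(0)
                inter = sp.intersection(window)
            except Exception:
                continue
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if g.geom_type == "Polygon" and g.area >= min_area:
                    new_inst.append([(float(x), float(y))
                                     for x, y in g.exterior.coords[:-1]])
        if new_inst:
            kept_parts.append(new_inst)
            kept_idx.append(i)
    return kept_parts, kept_idx


def augment_sample(image: np.ndarray, instances: Instances,
                   config: AugmentConfig, rng: np.random.Generator):
    """Randomly mirror / rotate / crop / color-jitter one labelled sample.

    Returns (image, instances, info) where info records which transforms
    fired and which instances were dropped by the crop.
    """
    h, w = image.shape[:2]
    parts = instances.parts
    labels = list(instances.labels)
    info = {"dropped": []}

    if config.horizontal_mirror and rng.random() < 0.5:
        image = image[:, ::-1].copy()
        parts = _transform_points(parts, lambda p: (w - p[0], p[1]))
        info["hmirror"] = True
    if config.vertical_mirror and rng.random() < 0.5:
        image = image[::-1].copy()
        parts = _transform_points(parts, lambda p: (p[0], h - p[1]))
        info["vmirror"] = True

    if config.rotation and config.rotation_deg > 0 and rng.random() < 0.5:
        angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg))
        image = sk_rotate(image, angle, resize=False, order=1,
                          preserve_range=True).astype(np.uint8)
        # skimage rotates the image CCW (in display coords, y down);
        # the matching point map rotates coordinates by -angle around center
        a = np.deg2rad(angle)
        cx, cy = w / 2.0, h / 2.0
        ca, sa = np.cos(a), np.sin(a)

        def rot(p):
            x, y = p[0] - cx, p[1] - cy
            return (cx + ca * x + sa * y, cy - sa * x + ca * y)

        parts = _transform_points(parts, rot)
        parts, kept = _clip_instances(parts, w, h)
        info["dropped"] += [i for i in range(len(labels)) if i not in kept]
        labels = [labels[i] for i in kept]
        info["rotation_deg"] = angle

    if config.crop and rng.random() < 0.5:
        frac = float(rng.uniform(*config.crop_range))
        ch, cw = max(int(h * frac), 32), max(int(w * frac), 32)
        y0 = int(rng.integers(0, h - ch + 1))
        x0 = int(rng.integers(0, w - cw + 1))
        image = image[y0:y0 + ch, x0:x0 + cw].copy()
        parts = _transform_points(parts, lambda p: (p[0] - x0, p[1] - y0))
        n_before = len(labels)
        parts, kept = _clip_instances(parts, cw, ch)
        info["dropped"] += [i for i in range(n_before) if i not in kept]
        labels = [labels[i] for i in kept]
        info["crop"] = (x0, y0, cw, ch)

    if config.color:
        image = _apply_color(image, rng, config)
        info["color"] = True

    return image, Instances(parts=parts, labels=labels), info


def resize_multiscale(image: np.ndarray, instances: Optional[Instances],
                      short_edge: int, max_edge: int = 1443):
    """Isotropic rescale so the short edge hits `short_edge`, unless that
    would push the long edge past `max_edge`, in which case the long edge is
    scaled to exactly `max_edge`.  Geometry is scaled identically."""
    h, w = image.shape[:2]
    scale = short_edge / min(h, w)
    if scale * max(h, w) > max_edge:
        scale = max_edge / max(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    out = sk_resize(image, (nh, nw), order=1, preserve_range=True,
                    anti_aliasing=scale < 1.0).astype(np.uint8)
    if instances is None:
        return out, None, scale
    parts = _transform_points(instances.parts,
                              lambda p: (p[0] * scale, p[1] * scale))
    return out, Instances(parts=parts, labels=list(instances.labels)), scale
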