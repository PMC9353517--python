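"""Polygon annotations: LabelMe-style I/O, group-id merging, COCO conversion.

A grape cluster occluded by a trunk or wire is visible as several disjoint
blobs; annotators trace each blob as its own polygon and tag the parts with a
shared *group id*.  This module collapses such parts into single instances,
derives the tight outer box automatically from the polygon vertices, rasterizes
instances to binary masks, converts whole directories to standard COCO JSON,
and performs the deterministic 8:2 train/test split.

Conventions (fixed across the package): 0-based pixel coordinates; COCO
``(x, y, w, h)`` boxes; rasterization fills a pixel when its center ``(i+0.5,
j+0.5)`` is inside the polygon under the even-odd rule; a multi-part instance
is the union of its even-odd-filled parts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "PolygonShape",
    "InstanceRecord",
    "ZeroExtentError",
    "merge_group_instances",
    "polygon_to_bbox",
    "rasterize_polygon",
    "rasterize_instance",
    "load_labelme",
    "labelme_to_coco",
    "split_dataset",
    "load_coco",
]


class ZeroExtentError(ValueError):
    """All vertices collinear along an axis — the outer box has no area."""


@dataclass
class PolygonShape:
    """One labelled polygon: a closed contour given as an ordered point list."""

    label: str
    points: list  # [(x, y), ...] pixel coordinates
    group_id: Optional[int] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError(f"polygon needs >=3 (x, y) points, got shape {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("polygon coordinates must be finite")
        if (pts < 0).any():
            raise ValueError("polygon coordinates must be >= 0")
        self.points = [(float(x), float(y)) for x, y in pts]


@dataclass
class InstanceRecord:
    """A physical instance: >=1 polygon parts sharing one identity."""

    instance_id: int
    category: str
    parts: list  # list of point lists
    bbox: tuple  # (x, y, w, h)
    area: float  # set pixels in the rasterized mask

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def mask(self, height: int, width: int) -> np.ndarray:
        return rasterize_instance(self, height, width)


def polygon_to_bbox(parts: Sequence[Sequence]) -> tuple:
    """Tightest axis-aligned (x, y, w, h) box over every vertex of every part."""
    if not parts:
        raise ValueError("need at least one polygon part")
    pts = np.concatenate([np.asarray(p, dtype=float) for p in parts], axis=0)
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("each part needs (x, y) vertices")
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        raise ZeroExtentError(f"degenerate box ({x0},{y0})-({x1},{y1})")
    return (float(x0), float(y0), float(x1 - x0), float(y1 - y0))


def rasterize_polygon(points: Sequence, height: int, width: int,
                      out: np.ndarray | None = None) -> np.ndarray:
    """Even-odd scanline fill on pixel centers; clips to the image implicitly.

    A pixel (row r, col c) is set when the center (c+0.5, r+0.5) crosses an
    odd number of polygon edges when traced from x = -inf.
    """
    if height <= 0 or width <= 0:
        raise ValueError("image dimensions must be positive")
    mask = out if out is not None else np.zeros((height, width), dtype=bool)
    pts = np.asarray(points, dtype=float)
    x1s, y1s = pts[:, 0], pts[:, 1]
    x2s, y2s = np.roll(x1s, -1), np.roll(y1s, -1)
    keep = y1s != y2s                       # horizontal edges never cross a scanline
    x1s, y1s, x2s, y2s = x1s[keep], y1s[keep], x2s[keep], y2s[keep]
    if x1s.size == 0:
        return mask
    ylo = np.minimum(y1s, y2s)
    yhi = np.maximum(y1s, y2s)
    r0 = max(int(np.floor(ylo.min() - 0.5)), 0)
    r1 = min(int(np.ceil(yhi.max())), height - 1)
    xc = np.arange(width) + 0.5
    for r in range(r0, r1 + 1):
        yc = r + 0.5
        # half-open rule [ylo, yhi) so shared vertices count once
        hit = (ylo <= yc) & (yc < yhi)
        if not hit.any():
            continue
        xcross = x1s[hit] + (yc - y1s[hit]) * (x2s[hit] - x1s[hit]) / (y2s[hit] - y1s[hit])
        xcross.sort()
        inside = (np.searchsorted(xcross, xc, side="right") % 2).astype(bool)
        mask[r] |= inside
    return mask


def rasterize_instance(record: "InstanceRecord | Sequence", height: int,
                       width: int) -> np.ndarray:
    """Union of the even-odd fills of all parts of an instance."""
    parts = record.parts if isinstance(record, InstanceRecord) else record
    mask = np.zeros((height, width), dtype=bool)
    for part in parts:
        mask |= rasterize_polygon(part, height, width)
    return mask


def _instance_area(parts, bbox) -> float:
    """Pixel count of the union mask, computed in a local window around the
    box so the value is independent of the enclosing image size."""
    x, y, w, h = bbox
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    ww = int(np.ceil(x + w)) - x0 + 2
    hh = int(np.ceil(y + h)) - y0 + 2
    shifted = [[(px - x0, py - y0) for px, py in part] for part in parts]
    return float(rasterize_instance(shifted, hh, ww).sum())


def merge_group_instances(shapes: Iterable[PolygonShape]) -> list:
    """Collapse polygons sharing a (label, group id) into single instances.

    Shapes without a group id each become a single-part instance.  Output
    order is deterministic: by first appearance of the instance key.  Group
    ids are file-local — merging never crosses images.
    """
    order: list = []
    groups: dict = {}
    for i, s in enumerate(shapes):
        if not isinstance(s, PolygonShape):
            s = PolygonShape(**s) if isinstance(s, dict) else PolygonShape(*s)
        if s.group_id is None:
            key = ("__solo__", i)
        else:
            if not isinstance(s.group_id, (int, np.integer)):
                raise ValueError(f"group_id must be an integer, got {s.group_id!r}")
            key = ("__group__", int(s.group_id))
            for other_label, _ in groups.get(key, []):
                if other_label != s.label:
                    raise ValueError(
                        f"group_id {s.group_id} spans labels {other_label!r} and {s.label!r}")
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append((s.label, s.points))
    records = []
    for iid, key in enumerate(order):
        members = groups[key]
        label = members[0][0]
        parts = [pts for _, pts in members]
        bbox = polygon_to_bbox(parts)
        records.append(InstanceRecord(
            instance_id=iid, category=label, parts=parts, bbox=bbox,
            area=_instance_area(parts, bbox)))
    return records


# ---------------------------------------------------------------------------
# LabelMe-style / COCO I/O


def load_labelme(path) -> dict:
    """Read a LabelMe-style JSON file into {image_path, height, width, shapes}."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("imagePath", "imageHeight", "imageWidth", "shapes"):
        if key not in doc:
            raise ValueError(f"{path.name}: missing required field {key!r}")
    shapes = []
    for sh in doc["shapes"]:
        if "label" not in sh or "points" not in sh:
            raise ValueError(f"{path.name}: shape missing label/points")
        gid = sh.get("group_id")
        shapes.append(PolygonShape(label=sh["label"], points=sh["points"],
                                   group_id=None if gid is None else int(gid)))
    return {
        "image_path": doc["imagePath"],
        "height": int(doc["imageHeight"]),
        "width": int(doc["imageWidth"]),
        "shapes": shapes,
    }


def labelme_to_coco(input_dir, out_json=None, category: str = "grape") -> dict:
    """Convert a directory of image + LabelMe JSON pairs to one COCO dataset.

    Each merged instance becomes one annotation whose ``segmentation`` holds
    one flat [x1, y1, x2, y2, ...] list per polygon part (an occlusion-split
    cluster therefore keeps >=2 polygon lists under a single annotation id).
    ``iscrowd`` is always 0.  Field ordering is fixed for reproducible diffs.
    """
    input_dir = Path(input_dir)
    files = sorted(input_dir.glob("*.json"))
    files = [f for f in files if f.name != "manifest.json"]
    if not files:
        raise FileNotFoundError(f"no LabelMe JSON files in {input_dir}")
    images, annotations = [], []
    ann_id = 1
    for img_id, path in enumerate(files, start=1):
        doc = load_labelme(path)
        img_file = doc["image_path"]
        if not (input_dir / img_file).exists():
            raise FileNotFoundError(f"{path.name}: image file {img_file!r} not found")
        images.append({
            "id": img_id,
            "file_name": img_file,
            "height": doc["height"],
            "width": doc["width"],
        })
        for rec in merge_group_instances(doc["shapes"]):
            if rec.category != category:
                continue
            seg = [[float(v) for xy in part for v in xy] for part in rec.parts]
            annotations.append({
                "id": ann_id,
                "image_id": img_id,
                "category_id": 1,
                "segmentation": seg,
                "bbox": [round(v, 2) for v in rec.bbox],
                "area": rec.area,
                "iscrowd": 0,
            })
            ann_id += 1
    coco = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": category}],
    }
    if out_json is not None:
        with open(out_json, "w") as fh:
            json.dump(coco, fh, indent=1, sort_keys=False)
    coco["summary"] = {"n_images": len(images), "n_annotations": len(annotations)}
    return coco


def load_coco(path_or_dict) -> dict:
    """Load and minimally validate a COCO annotation dict."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            doc = json.load(fh)
    else:
        doc = path_or_dict
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"COCO document missing {key!r}")
    img_ids = {im["id"] for im in doc["images"]}
    orphans = [a["id"] for a in doc["annotations"] if a["image_id"] not in img_ids]
    if orphans:
        raise ValueError(f"annotations reference unknown images: {orphans[:5]}")
    return doc


def split_dataset(per_source: Mapping[str, Sequence], train_fraction: float = 0.8,
                  seed: int = 0):
    """Deterministic per-source shuffle-and-split.

    The test count per source is round-half-up of ``n * (1 - train_fraction)``
    (e.g. 218 images at 8:2 → 174 train / 44 test).  Returns two dicts keyed
    by source name.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = {}, {}
    for source in per_source:
        items = list(per_source[source])
        n = len(items)
        n_test = int(np.floor(n * (1.0 - train_fraction) + 0.5))
        perm = rng.permutation(n)
        test[source] = [items[i] for i in sorted(perm[:n_test])]
        train[source] = [items[i] for i in sorted(perm[n_test:])]
    return train, test
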