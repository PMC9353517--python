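"""Group-id merging, COCO conversion and the deterministic 8:2 split.

Shows the full annotation path: polygons of an occlusion-split cluster are
collapsed into one instance with an automatically derived outer box, a
directory becomes a standard COCO JSON, and image lists are split 8:2 per
source dataset.
"""

import tempfile
from pathlib import Path

from vineseg.annotations import (PolygonShape, labelme_to_coco,
                                 merge_group_instances, split_dataset)
from vineseg.synthetic import SceneConfig, generate_dataset

# --- merging: two polygons with one group id are one physical cluster
shapes = [
    PolygonShape("grape", [(10, 10), (40, 10), (40, 30), (10, 30)], group_id=1),
    PolygonShape("grape", [(10, 45), (40, 45), (40, 70), (10, 70)], group_id=1),
    PolygonShape("grape", [(60, 20), (90, 20), (75, 50)]),
]
records = merge_group_instances(shapes)
print(f"{len(shapes)} polygons -> {len(records)} instances")
for rec in records:
    print(f"  instance {rec.instance_id}: {rec.n_parts} part(s), "
          f"bbox={tuple(round(v, 1) for v in rec.bbox)}, area={rec.area:.0f} px")

# --- directory -> COCO
out_dir = Path(tempfile.mkdtemp(prefix="vineseg_coco_"))
generate_dataset(SceneConfig.tiny(seed=3, occluder_probability=0.8), 4, out_dir)
doc = labelme_to_coco(out_dir, out_dir / "coco.json")
multi = sum(1 for a in doc["annotations"] if len(a["segmentation"]) > 1)
print(f"\nCOCO: {doc['summary']['n_images']} images, "
      f"{doc['summary']['n_annotations']} annotations "
      f"({multi} with multi-polygon segmentation)")

# --- 8:2 split reproducing the field-data partition sizes
train, test = split_dataset({"grape_a": [f"im_{i:03d}" for i in range(218)]},
                            train_fraction=0.8, seed=0)
print(f"\nsplit of 218 images at 8:2 -> {len(train['grape_a'])} train / "
      f"{len(test['grape_a'])} test")
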