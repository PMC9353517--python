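"""Train the test-scale model on four synthetic scenes and evaluate it.

A short seeded SGD run (the full recipe, scaled down: same three-term loss,
same step LR schedule) on four 128x128 scenes, followed by COCO-style
evaluation of the model's own training images.  With the default 300
iterations (a few CPU-minutes) the model overfits to AP@0.5 = 1.0 on both
tasks; lower `ITERS` for a faster, weaker demo.
"""

import numpy as np

from vineseg.cocoeval import evaluate
from vineseg.model import MaskRCNN, ModelConfig
from vineseg.synthetic import (SceneConfig, generate_scene, scenes_to_coco,
                               scenes_to_samples)
from vineseg.train import TrainConfig, train

ITERS = 300

scenes = [generate_scene(SceneConfig.tiny(seed=100 + i)) for i in range(4)]
samples = scenes_to_samples(scenes)
print(f"training on {len(samples)} scenes, "
      f"{sum(len(s['masks']) for s in samples)} instances, {ITERS} iterations")

config = TrainConfig(iterations=ITERS, batch_size=2, initial_lr=0.02,
                     augment=False, multiscale=False, checkpoint_every=0, seed=0)
model = MaskRCNN(ModelConfig.test_scale(seed=0))
model, log = train(samples, config, model=model, log_every=50)

coco_gt = scenes_to_coco(scenes)
results = model.predict_coco([s["image"] for s in samples],
                             list(range(1, len(samples) + 1)))
print(f"\nfinal total loss {log.records[-1]['l_total']:.4f}; "
      f"{len(results)} detections on the training images\n")
for task in ("box", "segm"):
    print(evaluate(coco_gt, results, task).table())
    print()
# AP@0.5 = 1.0 on the training set demonstrates learnability (the model,
# losses and gradients are wired correctly), not field performance.
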