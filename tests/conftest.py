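import numpy as np
import pytest

from vineseg.synthetic import (SceneConfig, generate_scene, scenes_to_coco,
                               scenes_to_samples)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Four small labelled scenes used by annotation / training tests."""
    return [generate_scene(SceneConfig.tiny(seed=100 + i)) for i in range(4)]


@pytest.fixture(scope="session")
def tiny_coco(tiny_scenes):
    return scenes_to_coco(tiny_scenes)


@pytest.fixture(scope="session")
def eval_fixture_scenes():
    """20 scenes with occlusions for evaluator oracle-equivalence checks."""
    return [generate_scene(SceneConfig.tiny(seed=500 + i, occluder_probability=0.4))
            for i in range(20)]


def perturbed_results(scenes, coco_gt, seed=42):
    """Noisy COCO-style predictions derived from ground truth: jittered boxes,
    shifted masks, random scores, dropped instances and spurious detections."""
    rng = np.random.default_rng(seed)
    anns_by_img = {}
    for a in coco_gt["annotations"]:
        anns_by_img.setdefault(a["image_id"], []).append(a)
    results = []
    for i, sc in enumerate(scenes):
        h, w = sc.image.shape[:2]
        masks = sc.masks
        for j, a in enumerate(anns_by_img.get(i + 1, [])):
            if rng.random() < 0.15:
                continue                       # missed detection
            x, y, bw, bh = a["bbox"]
            jit = rng.normal(0, 4, 4)
            bb = [float(x + jit[0]), float(y + jit[1]),
                  float(max(bw + jit[2], 2)), float(max(bh + jit[3], 2))]
            shift = rng.integers(-5, 6, 2)
            pm = np.roll(np.roll(masks[j], shift[0], axis=0), shift[1], axis=1)
            results.append({"image_id": i + 1, "category_id": 1, "bbox": bb,
                            "score": float(rng.random()), "mask": pm})
        if rng.random() < 0.2:                 # false positive
            fm = np.zeros((h, w), dtype=bool)
            fm[20:40, 20:35] = True
            results.append({"image_id": i + 1, "category_id": 1,
                            "bbox": [20.0, 20.0, 15.0, 20.0],
                            "score": float(rng.random()), "mask": fm})
    return results


@pytest.fixture(scope="session")
def overfit_run(tiny_scenes):
    """Train the test-scale model to convergence on the four tiny scenes.

    Session-scoped: the ~minutes-long run is shared by every test that needs
    a converged model.  Returns (model, samples, coco ground truth, log).
    """
    from vineseg.model import MaskRCNN, ModelConfig
    from vineseg.train import TrainConfig, train

    samples = scenes_to_samples(tiny_scenes)
    cfg = TrainConfig(iterations=300, batch_size=2, initial_lr=0.02,
                      augment=False, multiscale=False, seed=0,
                      checkpoint_every=0)
    model = MaskRCNN(ModelConfig.test_scale(seed=0))
    model, log = train(samples, cfg, model=model)
    return model, samples, scenes_to_coco(tiny_scenes), log
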