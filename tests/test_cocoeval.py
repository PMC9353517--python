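"""Evaluator: IoU arithmetic, greedy matching, AP/AR protocol, oracle
equivalence with an independent brute-force implementation."""

import numpy as np
import pytest

from vineseg.cocoeval import (IOU_THRESHOLDS, average_precision, average_recall,
                              box_iou_matrix, evaluate, mask_iou_matrix,
                              match_predictions, pairwise_iou)
from naive_eval import naive_box_iou, naive_mask_iou, naive_metrics
from conftest import perturbed_results


class TestPairwiseIoU:
    def test_identical_and_disjoint(self):
        assert pairwise_iou([0, 0, 4, 4], [0, 0, 4, 4]) == 1.0
        assert pairwise_iou([0, 0, 4, 4], [10, 10, 4, 4]) == 0.0

    def test_partial_overlap_third(self):
        assert pairwise_iou([0, 0, 2, 2], [1, 0, 2, 2]) == pytest.approx(1 / 3)

    def test_mask_iou_and_mixed_kinds(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0:4, 0:4] = True
        b[2:6, 0:4] = True
        assert pairwise_iou(a, b) == pytest.approx(8 / 24)
        assert pairwise_iou(a, np.zeros((8, 8), bool)) == 0.0
        with pytest.raises(TypeError):
            pairwise_iou(a, [0, 0, 4, 4])


class TestMatching:
    def test_three_perfect_predictions(self):
        iou = np.eye(3)
        counts, match = match_predictions(iou, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (3, 0, 0)
        assert counts.precision == counts.recall == 1.0

    def test_one_perfect_one_disjoint(self):
        iou = np.array([[1.0, 0.0], [0.0, 0.0]])
        counts, _ = match_predictions(iou, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)
        assert counts.precision == 0.5 and counts.recall == 0.5

    def test_duplicate_prediction_cannot_rematch(self):
        iou = np.array([[1.0], [1.0]])
        counts, match = match_predictions(iou, 0.5)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)
        assert list(match) == [0, -1]


class TestProtocol:
    def test_primary_ap_averages_ten_thresholds(self):
        assert len(IOU_THRESHOLDS) == 10
        assert IOU_THRESHOLDS[0] == 0.5 and IOU_THRESHOLDS[-1] == 0.95
        per_image = [(np.array([[0.7]]), [0.9])]     # one det, IoU 0.7
        ap_mean, ap_t = average_precision(per_image)
        assert len(ap_t) == 10
        assert ap_mean == pytest.approx(ap_t.mean())
        # matched at the 5 thresholds 0.50..0.70 only -> 5 of 10 perfect curves
        assert ap_mean == pytest.approx(0.5, abs=1e-9)

    def test_perfect_and_empty_detectors(self):
        perfect = [(np.eye(3), [0.9, 0.8, 0.7])]
        ap, _ = average_precision(perfect)
        assert ap == pytest.approx(1.0)
        none = [(np.zeros((0, 3)), [])]
        ap0, _ = average_precision(none)
        assert ap0 == 0.0

    def test_ar_truncation_single_perfect_of_five(self):
        """5 ground truths, top-1 keeps one perfect prediction -> AR@1 = 0.2."""
        iou = np.zeros((3, 5))
        iou[0, 0] = 1.0
        per_image = [(iou, [0.9, 0.5, 0.4])]
        assert average_recall(per_image, 1) == pytest.approx(0.2)
        assert average_recall(per_image, 10) == pytest.approx(0.2)

    def test_ar_monotone_in_max_detections(self):
        rng = np.random.default_rng(0)
        per_image = [(rng.random((12, 6)), sorted(rng.random(12), reverse=True))
                     for _ in range(5)]
        a1 = average_recall(per_image, 1)
        a10 = average_recall(per_image, 10)
        a100 = average_recall(per_image, 100)
        assert a1 <= a10 <= a100

    def test_ap_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(1)
        per_image = [(rng.random((8, 4)), sorted(rng.random(8), reverse=True))
                     for _ in range(4)]
        _, ap_t = average_precision(per_image)
        assert all(a >= b - 1e-12 for a, b in zip(ap_t, ap_t[1:]))

    def test_no_ground_truth_sentinel(self):
        ap, _ = average_precision([(np.zeros((2, 0)), [0.5, 0.4])])
        assert ap == -1.0


class TestEvaluate:
    def test_ground_truth_against_itself_all_ones(self, tiny_coco, tiny_scenes):
        results = []
        for i, sc in enumerate(tiny_scenes):
            anns = [a for a in tiny_coco["annotations"] if a["image_id"] == i + 1]
            for a, m in zip(anns, sc.masks):
                results.append({"image_id": i + 1, "category_id": 1,
                                "bbox": a["bbox"], "score": 1.0, "mask": m})
        n_img = len(tiny_coco["images"])
        n_gt = len(tiny_coco["annotations"])
        for task in ("box", "segm"):
            rep = evaluate(tiny_coco, results, task)
            for k in ("ap", "ap50", "ap75", "ar10", "ar100"):
                assert rep.as_dict()[k] == pytest.approx(1.0), (task, k)
            # AR@1 keeps one detection per image: images / instances
            assert rep.ar1 == pytest.approx(n_img / n_gt)

    def test_empty_results_all_zero(self, tiny_coco):
        rep = evaluate(tiny_coco, [], "box")
        assert rep.ap == 0.0 and rep.ar100 == 0.0

    def test_orphan_image_ids_rejected(self, tiny_coco):
        bad = [{"image_id": 999, "category_id": 1, "bbox": [0, 0, 5, 5],
                "score": 0.5}]
        with pytest.raises(ValueError, match="999"):
            evaluate(tiny_coco, bad, "box")

    def test_image_order_permutation_invariance(self, tiny_coco, tiny_scenes):
        results = perturbed_results(tiny_scenes, tiny_coco, seed=3)
        rep_a = evaluate(tiny_coco, results, "box")
        shuffled = dict(tiny_coco)
        shuffled["images"] = list(reversed(tiny_coco["images"]))
        rep_b = evaluate(shuffled, results, "box")
        assert rep_a.as_dict() == rep_b.as_dict()

    @pytest.mark.parametrize("task", ["box", "segm"])
    def test_oracle_equivalence_on_randomized_scenes(
            self, task, eval_fixture_scenes):
        """All six metrics match the independent loop-based evaluator to 1e-6
        on 20 randomized synthetic images with perturbed predictions."""
        from vineseg.synthetic import scenes_to_coco
        gt = scenes_to_coco(eval_fixture_scenes)
        results = perturbed_results(eval_fixture_scenes, gt, seed=42)
        mine = evaluate(gt, results, task).as_dict()

        from vineseg.annotations import rasterize_instance
        gt_per_img, dt_per_img = [], []
        for im in gt["images"]:
            h, w = im["height"], im["width"]
            gts, dts = [], []
            for a in gt["annotations"]:
                if a["image_id"] != im["id"]:
                    continue
                if task == "box":
                    gts.append(tuple(a["bbox"]))
                else:
                    parts = [np.asarray(p).reshape(-1, 2)
                             for p in a["segmentation"]]
                    gts.append(rasterize_instance(parts, h, w))
            for r in results:
                if r["image_id"] != im["id"]:
                    continue
                dts.append((tuple(r["bbox"]) if task == "box" else r["mask"],
                            r["score"]))
            gt_per_img.append(gts)
            dt_per_img.append(dts)
        iou_fn = naive_box_iou if task == "box" else naive_mask_iou
        ref = naive_metrics(gt_per_img, dt_per_img, iou_fn)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=1e-6), k


def test_box_and_mask_matrix_consistency():
    rng = np.random.default_rng(5)
    boxes_a = np.concatenate([rng.uniform(0, 20, (4, 2)),
                              rng.uniform(5, 30, (4, 2))], axis=1)
    boxes_b = np.concatenate([rng.uniform(0, 20, (3, 2)),
                              rng.uniform(5, 30, (3, 2))], axis=1)
    m = box_iou_matrix(boxes_a, boxes_b)
    for i in range(4):
        for j in range(3):
            assert m[i, j] == pytest.approx(
                naive_box_iou(tuple(boxes_a[i]), tuple(boxes_b[j])))
    masks = [rng.random((10, 10)) > 0.5 for _ in range(3)]
    mm = mask_iou_matrix(masks, masks)
    assert np.allclose(np.diag(mm), 1.0)
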