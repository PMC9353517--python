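"""Anchor design, proposal mechanics, RoI pooling and the three-term loss."""

import numpy as np
import pytest

from vineseg import nn
from vineseg.backbone import BackboneED
from vineseg.heads import (AnchorTemplate, LossBreakdown, RPN,
                           TrainingDivergence, build_anchor_templates,
                           decode_boxes, encode_boxes, generate_level_anchors,
                           mask_loss, nms, total_loss)


class TestAnchorTemplates:
    def test_fifteen_benchmark_windows(self):
        templates = build_anchor_templates()
        assert len(templates) == 15
        assert len({(t.scale, t.aspect_ratio) for t in templates}) == 15

    def test_scale_major_order_and_level_assignment(self):
        templates = build_anchor_templates()
        scales = [t.scale for t in templates]
        assert scales == sorted(scales)
        by_level = {}
        for t in templates:
            by_level.setdefault(t.level, set()).add(t.scale)
        assert by_level == {"P2": {8}, "P3": {16}, "P4": {32}, "P5": {64},
                            "P6": {128}}

    def test_square_anchor_and_area_preservation(self):
        templates = build_anchor_templates()
        sq = [t for t in templates if t.scale == 8 and t.aspect_ratio == 1][0]
        assert (sq.width, sq.height) == (8, 8)
        for t in templates:
            assert t.width / t.height == pytest.approx(t.aspect_ratio, rel=0.3)
            assert t.width * t.height == pytest.approx(t.scale ** 2,
                                                       rel=0.15)  # rounding

    def test_validation(self):
        with pytest.raises(ValueError):
            build_anchor_templates(scales=())
        with pytest.raises(ValueError):
            build_anchor_templates(scales=(8, -16, 32, 64, 128))


class TestAnchorGrid:
    def test_count_is_hw_times_ratios(self):
        templates = build_anchor_templates()
        for (h, w, stride, name) in [(32, 32, 4, "P2"), (8, 16, 16, "P4")]:
            anchors = generate_level_anchors(templates, name, h, w, stride)
            assert anchors.shape == (h * w * 3, 4)

    def test_centers_on_stride_grid(self):
        templates = build_anchor_templates()
        anchors = generate_level_anchors(templates, "P3", 4, 4, 8)
        centers_x = (anchors[:, 0] + anchors[:, 2]) / 2
        assert set(np.round(centers_x, 3)) <= {(j + 0.5) * 8 for j in range(4)}


class TestBoxCoding:
    def test_encode_decode_roundtrip(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(10, 50, (20, 2))
        ref = np.concatenate([ref, ref + rng.uniform(5, 40, (20, 2))], axis=1)
        gt = rng.uniform(10, 50, (20, 2))
        gt = np.concatenate([gt, gt + rng.uniform(5, 40, (20, 2))], axis=1)
        back = decode_boxes(ref, encode_boxes(ref, gt))
        assert np.abs(back - gt).max() < 1e-9

    def test_nms_suppresses_duplicates(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [50, 50, 60, 60]],
                         dtype=float)
        keep = nms(boxes, np.array([0.9, 0.8, 0.7]), 0.5)
        assert list(keep) == [0, 2]


class TestMaskLoss:
    def test_saturated_correct_prediction_near_zero(self):
        m = 8
        target = np.zeros((m, m))
        target[2:6, 2:6] = 1
        logits = np.where(target > 0, 20.0, -20.0)
        full = nn.Tensor(np.stack([np.zeros((m, m)), logits]))
        assert mask_loss(full, target, 1).item() < 1e-6

    def test_zero_logits_give_ln2_exactly(self):
        m = 6
        logits = nn.Tensor(np.zeros((2, m, m)))
        for target in (np.zeros((m, m)), np.ones((m, m))):
            assert mask_loss(logits, target, 1).item() == pytest.approx(
                np.log(2.0), rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_cross_entropy(self, seed):
        rng = np.random.default_rng(seed)
        m = 7
        logits = rng.normal(size=(2, m, m))
        target = (rng.random((m, m)) > 0.5).astype(float)
        mine = mask_loss(nn.Tensor(logits), target, 1).item()
        total = 0.0
        for i in range(m):
            for j in range(m):
                p = 1.0 / (1.0 + np.exp(-logits[1, i, j]))
                y = target[i, j]
                total += -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert abs(mine - total / (m * m)) < 1e-7

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_loss(nn.Tensor(np.zeros((2, 8, 8))), np.zeros((6, 6)), 1)


class TestTotalLoss:
    def test_exact_sum(self):
        assert total_loss(0.0, 0.0, 0.0).l_total == 0.0
        bd = total_loss(0.5, 0.25, 0.25)
        assert bd.l_total == 1.0
        assert bd.l_total == bd.l_cls + bd.l_box + bd.l_mask

    def test_non_finite_term_named(self):
        with pytest.raises(TrainingDivergence, match="l_box"):
            total_loss(0.1, float("nan"), 0.2)

    def test_gradient_of_sum_is_sum_of_gradients(self):
        """Finite-difference check that d(total)/dw = sum of per-term grads."""
        w = nn.Tensor(np.array([0.3, -0.2]), requires_grad=True)
        t1 = (w * w).sum()
        t2 = (w * 2.0).sum()
        t3 = w.sum() * 0.5
        (t1 + t2 + t3).backward()
        combined = w.grad.copy()
        parts = np.zeros_like(combined)
        for term_fn in (lambda t: (t * t).sum(), lambda t: (t * 2.0).sum(),
                        lambda t: t.sum() * 0.5):
            tt = nn.Tensor(w.data.copy(), requires_grad=True)
            term_fn(tt).backward()
            parts += tt.grad
        assert np.allclose(combined, parts)


@pytest.fixture(scope="module")
def small_pyramid():
    bb = BackboneED.test_scale(rng=np.random.default_rng(0))
    x = nn.Tensor(np.random.default_rng(1).normal(size=(1, 3, 128, 128))
                  .astype(np.float32))
    return bb(x)


class TestRPN:
    def test_zeroed_head_uniform_half_scores_and_capped_proposals(self, small_pyramid):
        rpn = RPN(64, rng=np.random.default_rng(0))
        for p in (rpn.obj.weight, rpn.obj.bias, rpn.delta.weight, rpn.delta.bias):
            p.data[:] = 0.0
        out = rpn(small_pyramid)
        for name, (obj, _d) in out.items():
            assert np.all(obj.data == 0.0)       # sigmoid -> 0.5 everywhere
        templates = build_anchor_templates()
        anchors = {nm: generate_level_anchors(
            templates, nm, *small_pyramid[nm].shape[2:],
            small_pyramid.strides[nm]) for nm in small_pyramid.names}
        props = rpn.propose(out, anchors, (128, 128), pre_nms=500, post_nms=50,
                            nms_thresh=0.9)
        boxes, scores = props[0]
        assert len(boxes) == 50                  # post-NMS cap reached
        assert np.all(boxes[:, 0] >= 0) and np.all(boxes[:, 2] <= 128)
        assert np.all(boxes[:, 1] >= 0) and np.all(boxes[:, 3] <= 128)

    def test_anchor_enumeration_total(self, small_pyramid):
        templates = build_anchor_templates()
        total = 0
        for nm in small_pyramid.names:
            h, w = small_pyramid[nm].shape[2:]
            anchors = generate_level_anchors(templates, nm, h, w,
                                             small_pyramid.strides[nm])
            assert anchors.shape[0] == h * w * 3
            total += anchors.shape[0]
        expected = sum((128 // s) ** 2 * 3 for s in (4, 8, 16, 32, 64))
        assert total == expected
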