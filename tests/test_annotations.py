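"""Annotation pipeline: merging, boxes, rasterization, COCO export, splits."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vineseg.annotations import (PolygonShape, ZeroExtentError, labelme_to_coco,
                                 load_coco, merge_group_instances,
                                 polygon_to_bbox, rasterize_instance,
                                 rasterize_polygon, split_dataset)
from vineseg.synthetic import SceneConfig, generate_dataset

SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


def tri(x0, y0, s=2.0):
    return [(x0, y0), (x0 + s, y0), (x0, y0 + s)]


def brute_force_point_in_polygon(points, height, width):
    """O(H*W*E) even-odd membership scan — the independent fill oracle."""
    mask = np.zeros((height, width), dtype=bool)
    pts = list(points)
    n = len(pts)
    for r in range(height):
        for c in range(width):
            x, y = c + 0.5, r + 0.5
            inside = False
            for i in range(n):
                x1, y1 = pts[i]
                x2, y2 = pts[(i + 1) % n]
                if (y1 <= y < y2) or (y2 <= y < y1):
                    xc = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                    if xc > x:
                        inside = not inside
            mask[r, c] = inside
    return mask


class TestMerging:
    def test_shared_group_id_collapses_to_one_instance(self):
        """Two polygons of one occluded cluster + one whole cluster -> 2
        instances, the first with 2 parts."""
        shapes = [PolygonShape("grape", tri(0, 0), group_id=1),
                  PolygonShape("grape", tri(5, 5), group_id=1),
                  PolygonShape("grape", tri(10, 0))]
        recs = merge_group_instances(shapes)
        assert len(recs) == 2
        assert recs[0].n_parts == 2 and recs[1].n_parts == 1

    def test_no_group_ids_all_single(self):
        shapes = [PolygonShape("grape", tri(i * 5, 0)) for i in range(3)]
        recs = merge_group_instances(shapes)
        assert [r.n_parts for r in recs] == [1, 1, 1]
        assert [r.instance_id for r in recs] == [0, 1, 2]

    def test_merged_bbox_is_elementwise_extremes(self):
        shapes = [PolygonShape("grape", tri(2, 3, 2), group_id=7),
                  PolygonShape("grape", tri(8, 6, 2), group_id=7)]
        rec = merge_group_instances(shapes)[0]
        pts = np.array(tri(2, 3, 2) + tri(8, 6, 2), dtype=float)
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        assert rec.bbox == (x0, y0, x1 - x0, y1 - y0)

    def test_conflicting_labels_in_group_rejected(self):
        shapes = [PolygonShape("grape", tri(0, 0), group_id=1),
                  PolygonShape("leaf", tri(5, 5), group_id=1)]
        with pytest.raises(ValueError, match="group_id 1"):
            merge_group_instances(shapes)

    def test_polygon_validation(self):
        with pytest.raises(ValueError):
            PolygonShape("grape", [(0, 0), (1, 1)])
        with pytest.raises(ValueError):
            PolygonShape("grape", [(0, 0), (1, 1), (np.nan, 2)])
        with pytest.raises(ValueError):
            PolygonShape("grape", [(-1, 0), (1, 1), (2, 2)])


class TestBBox:
    def test_unit_square(self):
        assert polygon_to_bbox([SQUARE]) == (0, 0, 1, 1)

    def test_two_disjoint_triangles(self):
        parts = [[(2, 3), (4, 3), (2, 5)], [(7, 6), (10, 6), (10, 8)]]
        assert polygon_to_bbox(parts) == (2, 3, 8, 5)

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=3, max_size=12), st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_vertex_and_part_order(self, pts, rnd):
        pts = [(round(x, 3), round(y, 3)) for x, y in pts]
        xs, ys = [p[0] for p in pts], [p[1] for p in pts]
        if max(xs) - min(xs) <= 0 or max(ys) - min(ys) <= 0:
            return
        ref = polygon_to_bbox([pts])
        shuffled = list(pts)
        rnd.shuffle(shuffled)
        assert polygon_to_bbox([shuffled]) == ref

    def test_degenerate_collinear_raises(self):
        with pytest.raises(ZeroExtentError):
            polygon_to_bbox([[(1, 0), (1, 5), (1, 9)]])


class TestRasterize:
    def test_axis_aligned_square_has_exact_area(self):
        sq = [(0, 0), (10, 0), (10, 10), (0, 10)]
        mask = rasterize_polygon(sq, 20, 20)
        assert mask.sum() == 100
        assert np.array_equal(mask, brute_force_point_in_polygon(sq, 20, 20))

    @pytest.mark.parametrize("seed", range(4))
    def test_random_polygon_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = [(float(x), float(y)) for x, y in rng.uniform(0, 18, (7, 2))]
        mine = rasterize_polygon(pts, 18, 18)
        assert np.array_equal(mine, brute_force_point_in_polygon(pts, 18, 18))

    def test_disjoint_parts_add(self):
        a = [(0, 0), (4, 0), (4, 4), (0, 4)]
        b = [(10, 10), (14, 10), (14, 14), (10, 14)]
        m = rasterize_instance([a, b], 20, 20)
        assert m.sum() == rasterize_polygon(a, 20, 20).sum() + \
            rasterize_polygon(b, 20, 20).sum()

    def test_fully_clipped_polygon_is_empty(self):
        m = rasterize_polygon([(30, 30), (40, 30), (40, 40)], 20, 20)
        assert m.sum() == 0

    def test_merge_then_rasterize_equals_or_of_parts(self):
        parts = [[(0, 0), (6, 0), (6, 6)], [(3, 3), (9, 3), (9, 9), (3, 9)]]
        shapes = [PolygonShape("grape", p, group_id=4) for p in parts]
        rec = merge_group_instances(shapes)[0]
        ored = rasterize_polygon(parts[0], 12, 12) | rasterize_polygon(parts[1], 12, 12)
        assert np.array_equal(rec.mask(12, 12), ored)


@pytest.fixture(scope="module")
def converted(tmp_path_factory):
    d = tmp_path_factory.mktemp("labelme")
    generate_dataset(SceneConfig.tiny(seed=21, occluder_probability=0.9), 6, d)
    out = d / "coco.json"
    doc = labelme_to_coco(d, out)
    return d, out, doc


class TestCocoConversion:
    def test_counts_and_schema(self, converted):
        d, out, doc = converted
        n_expected = sum(e["n_instances"]
                         for e in json.loads((d / "manifest.json").read_text())["images"])
        assert doc["summary"]["n_images"] == 6
        assert doc["summary"]["n_annotations"] == n_expected
        reloaded = load_coco(out)       # round-trips through the COCO reader
        assert len(reloaded["annotations"]) == n_expected
        assert reloaded["categories"] == [{"id": 1, "name": "grape"}]
        assert all(a["iscrowd"] == 0 for a in reloaded["annotations"])

    def test_split_instances_have_multipolygon_segmentation(self, converted):
        *_, doc = converted
        multi = [a for a in doc["annotations"] if len(a["segmentation"]) >= 2]
        assert multi, "expected at least one occlusion-split instance"

    def test_areas_match_independent_mask_decoding(self, converted):
        *_, doc = converted
        dims = {im["id"]: (im["height"], im["width"]) for im in doc["images"]}
        for a in doc["annotations"][:10]:
            h, w = dims[a["image_id"]]
            parts = [np.asarray(p).reshape(-1, 2) for p in a["segmentation"]]
            area = rasterize_instance(parts, h, w).sum()
            assert area == a["area"]
            # stored bbox is the vertex hull of the polygon parts
            pts = np.concatenate(parts)
            assert a["bbox"][0] == pytest.approx(pts[:, 0].min(), abs=0.01)
            assert a["bbox"][1] == pytest.approx(pts[:, 1].min(), abs=0.01)

    def test_missing_fields_reported_with_filename(self, tmp_path):
        (tmp_path / "bad.json").write_text(json.dumps({"shapes": []}))
        with pytest.raises(ValueError, match="bad.json"):
            labelme_to_coco(tmp_path)


class TestSplit:
    def test_8_to_2_round_numbers(self):
        train, test = split_dataset({"s": list(range(10))}, 0.8, seed=0)
        assert len(train["s"]) == 8 and len(test["s"]) == 2

    def test_grape_a_partition(self):
        """218 field images at 8:2 -> 174 train / 44 test."""
        train, test = split_dataset({"grape_a": list(range(218))}, 0.8, seed=3)
        assert len(train["grape_a"]) == 174
        assert len(test["grape_a"]) == 44

    @given(st.integers(0, 300), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_union_and_disjointness(self, n, seed):
        items = list(range(n))
        train, test = split_dataset({"x": items}, 0.8, seed=seed)
        assert sorted(train["x"] + test["x"]) == items
        assert set(train["x"]).isdisjoint(test["x"])
        assert len(test["x"]) == int(np.floor(n * 0.2 + 0.5))

    def test_reproducible_and_fraction_validated(self):
        a = split_dataset({"x": list(range(50))}, 0.8, seed=9)
        b = split_dataset({"x": list(range(50))}, 0.8, seed=9)
        assert a == b
        with pytest.raises(ValueError):
            split_dataset({"x": [1]}, 1.0)
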