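import json
import math

import pytest
from hypothesis import given, settings, strategies as st

from fusedet import (
    Box,
    Detection,
    DetectionSet,
    ValidationError,
    csv_to_detections,
    denormalize_boxes,
    detections_to_csv,
    normalize_boxes,
    read_coco_detections,
    read_coco_ground_truth,
    write_coco_detections,
    write_coco_ground_truth,
)
from conftest import make_dataset, make_dets


class TestBox:
    def test_xywh_conversion(self):
        b = Box.from_xywh(10, 20, 30, 40)
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (10, 20, 40, 60)
        assert b.as_xywh() == (10, 20, 30, 40)

    @given(
        x=st.floats(0, 1000), y=st.floats(0, 1000),
        w=st.floats(0.001, 500), h=st.floats(0.001, 500),
    )
    @settings(max_examples=50, derandomize=True)
    def test_xywh_roundtrip_is_identity(self, x, y, w, h):
        b = Box.from_xywh(x, y, w, h)
        x2, y2, w2, h2 = b.as_xywh()
        assert (x2, y2) == (x, y)
        assert math.isclose(w2, w, abs_tol=1e-9)
        assert math.isclose(h2, h, abs_tol=1e-9)

    @pytest.mark.parametrize(
        "coords", [(5, 5, 5, 10), (5, 5, 10, 5), (10, 0, 5, 5)]
    )
    def test_degenerate_box_rejected(self, coords):
        with pytest.raises(ValidationError):
            Box(*coords)

    def test_normalized_box_bounds_enforced(self):
        with pytest.raises(ValidationError):
            Box(0.0, 0.0, 1.5, 0.5, normalized=True)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            Detection(1, Box(0, 0, 1, 1), 1.2, 1, "m")


class TestCocoJson:
    def test_ground_truth_read(self, tmp_path):
        raw = {
            "images": [{"id": 1, "width": 100, "height": 80}],
            "annotations": [
                {"id": 1, "image_id": 1, "category_id": 1,
                 "bbox": [10, 20, 30, 40]}
            ],
            "categories": [{"id": 1, "name": "fracture"}],
        }
        path = tmp_path / "gt.json"
        path.write_text(json.dumps(raw))
        ds = read_coco_ground_truth(str(path))
        b = ds.ground_truth[0].box
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (10, 20, 40, 60)
        assert ds.images[0].width == 100

    def test_empty_annotations(self, tmp_path):
        raw = {"images": [{"id": 1, "width": 10, "height": 10}],
               "annotations": [], "categories": [{"id": 1, "name": "x"}]}
        path = tmp_path / "gt.json"
        path.write_text(json.dumps(raw))
        assert read_coco_ground_truth(str(path)).ground_truth == []

    def test_ground_truth_roundtrip(self, tmp_path, toy_dataset):
        path = tmp_path / "gt.json"
        write_coco_ground_truth(toy_dataset, str(path))
        ds = read_coco_ground_truth(str(path))
        assert ds.images == toy_dataset.images
        assert ds.ground_truth == toy_dataset.ground_truth
        assert ds.categories == toy_dataset.categories

    def test_unknown_image_reference_rejected(self, tmp_path):
        raw = {"images": [{"id": 1, "width": 10, "height": 10}],
               "annotations": [{"id": 1, "image_id": 99, "category_id": 1,
                                "bbox": [1, 1, 2, 2]}],
               "categories": [{"id": 1, "name": "x"}]}
        path = tmp_path / "gt.json"
        path.write_text(json.dumps(raw))
        with pytest.raises(ValidationError):
            read_coco_ground_truth(str(path))

    def test_detections_roundtrip(self, tmp_path):
        dets = make_dets("m1", [(1, 5.5, 6.25, 20.0, 30.0, 0.75),
                                (2, 0.0, 0.0, 3.0, 4.0, 0.5)])
        path = tmp_path / "dets.json"
        write_coco_detections(dets, str(path))
        back = read_coco_detections(str(path), "m1")
        assert back.model_id == "m1"
        assert [d.score for d in back.detections] == [0.75, 0.5]
        assert back.detections == dets.detections

    def test_empty_detections(self, tmp_path):
        path = tmp_path / "dets.json"
        path.write_text("[]")
        assert len(read_coco_detections(str(path), "m")) == 0

    @pytest.mark.parametrize(
        "bad", [{"image_id": 1, "category_id": 1, "bbox": [0, 0, -2, 5],
                 "score": 0.5},
                {"image_id": 1, "category_id": 1, "bbox": [0, 0, 2, 5],
                 "score": 1.5}]
    )
    def test_invalid_detection_rejected(self, tmp_path, bad):
        path = tmp_path / "dets.json"
        path.write_text(json.dumps([bad]))
        with pytest.raises(ValidationError):
            read_coco_detections(str(path), "m")


class TestCsv:
    def test_row_count_and_header(self, tmp_path):
        dets = make_dets("m1", [(1, 1, 2, 3, 4, 0.9), (2, 5, 6, 7, 8, 0.1)])
        path = tmp_path / "d.csv"
        detections_to_csv(dets, str(path))
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3
        assert lines[0] == ("image_id,model_id,category_id,"
                            "x_min,y_min,x_max,y_max,score")

    def test_empty_set_header_only(self, tmp_path):
        path = tmp_path / "d.csv"
        detections_to_csv(DetectionSet("m", []), str(path))
        assert path.read_text().strip().splitlines() == [
            "image_id,model_id,category_id,x_min,y_min,x_max,y_max,score"
        ]

    def test_roundtrip(self, tmp_path):
        dets = make_dets(
            "m1", [(1, 5.125, 6.0, 20.5, 30.75, 0.123456789),
                   (3, 0.0, 1.0, 2.5, 4.0, 0.999)]
        )
        path = tmp_path / "d.csv"
        detections_to_csv(dets, str(path))
        assert csv_to_detections(str(path)).detections == dets.detections


class TestNormalization:
    def test_full_image_box(self):
        ds = make_dataset([(1, 800, 800)], [])
        dets = make_dets("m", [(1, 0, 0, 800, 800, 0.5)])
        b = normalize_boxes(dets, ds).detections[0].box
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (0, 0, 1, 1)
        assert b.normalized

    def test_division(self):
        ds = make_dataset([(1, 800, 800)], [])
        dets = make_dets("m", [(1, 400, 200, 800, 400, 0.5)])
        b = normalize_boxes(dets, ds).detections[0].box
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (0.5, 0.25, 1.0, 0.5)

    def test_denormalize_is_inverse(self):
        ds = make_dataset([(1, 640, 480), (2, 800, 800)], [])
        dets = make_dets("m", [(1, 12.5, 7.25, 300.0, 401.5, 0.3),
                               (2, 3.0, 4.0, 750.0, 799.0, 0.9)])
        back = denormalize_boxes(normalize_boxes(dets, ds), ds)
        for orig, rt in zip(dets.detections, back.detections):
            for a, b in zip(
                (orig.box.x_min, orig.box.y_min, orig.box.x_max, orig.box.y_max),
                (rt.box.x_min, rt.box.y_min, rt.box.x_max, rt.box.y_max),
            ):
                assert abs(a - b) < 1e-9

    def test_out_of_bounds_box_clipped_with_warning(self, caplog):
        ds = make_dataset([(1, 100, 100)], [])
        dets = make_dets("m", [(1, -5, 10, 120, 90, 0.5)])
        with caplog.at_level("WARNING", logger="fusedet"):
            b = normalize_boxes(dets, ds).detections[0].box
        assert (b.x_min, b.x_max) == (0.0, 1.0)
        assert any("clipping" in r.message for r in caplog.records)
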