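import numpy as np
import pytest

from fusedet import (
    Box,
    Detection,
    DetectionSet,
    MetricsConfig,
    ap50,
    ar,
    evaluate,
    lrp,
    match,
    olrp,
    precision_recall,
)
from conftest import make_dataset, make_dets, random_eval_scene


# ---------------------------------------------------------------------------
# Independent oracles (own IoU arithmetic, no shared code with the package)
# ---------------------------------------------------------------------------

def oracle_iou(a, b):
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter) if inter else 0.0


def oracle_match_counts(dataset, dets, thr):
    """Greedy-by-score matching re-implemented naively per image."""
    tp = fp = 0
    gt_pool = {}
    for i, g in enumerate(dataset.ground_truth):
        gt_pool.setdefault((g.image_id, g.category_id), []).append(
            (i, (g.box.x_min, g.box.y_min, g.box.x_max, g.box.y_max))
        )
    taken = set()
    order = sorted(enumerate(dets.detections),
                   key=lambda kv: (-kv[1].score, kv[0]))
    flags = {}
    for seq, d in order:
        cand = gt_pool.get((d.image_id, d.category_id), [])
        box = (d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max)
        best, best_i = 0.0, None
        for i, g in cand:
            if i in taken:
                continue
            v = oracle_iou(box, g)
            if v > best:
                best, best_i = v, i
        if best_i is not None and best >= thr:
            taken.add(best_i)
            tp += 1
            flags[seq] = (True, best)
        else:
            fp += 1
            flags[seq] = (False, 0.0)
    return tp, fp, len(dataset.ground_truth) - tp, flags


def oracle_ap_staircase(scored_flags, n_gt):
    """Exact area under the monotone precision envelope, from scratch."""
    if n_gt == 0 or not scored_flags:
        return 0.0
    scored_flags = sorted(scored_flags, key=lambda sf: (-sf[0], sf[2]))
    points = []
    tp = fp = 0
    for s, flag, _ in scored_flags:
        tp += flag
        fp += not flag
        points.append((tp / n_gt, tp / (tp + fp)))
    area = 0.0
    prev_r = 0.0
    for i, (r, _) in enumerate(points):
        p_env = max(p for (rr, p) in points[i:])
        area += (r - prev_r) * p_env
        prev_r = r
    return area


def oracle_ap_101(scored_flags, n_gt):
    if n_gt == 0 or not scored_flags:
        return 0.0
    scored_flags = sorted(scored_flags, key=lambda sf: (-sf[0], sf[2]))
    rs, ps = [], []
    tp = fp = 0
    for s, flag, _ in scored_flags:
        tp += flag
        fp += not flag
        rs.append(tp / n_gt)
        ps.append(tp / (tp + fp))
    total = 0.0
    for k in range(101):
        r_thr = k / 100
        vals = [max(ps[i:]) for i in range(len(rs)) if rs[i] >= r_thr][:1]
        total += vals[0] if vals else 0.0
    return total / 101


# ---------------------------------------------------------------------------
# Matching and precision/recall
# ---------------------------------------------------------------------------

class TestMatch:
    def test_single_perfect_pair(self):
        ds = make_dataset([(1, 100, 100)], [(1, 10, 10, 40, 40)])
        dets = make_dets("m", [(1, 10, 10, 40, 40, 0.9)])
        m = match(dets, ds, 0.5)
        assert (m.n_tp, m.n_fp, m.n_fn) == (1, 0, 0)
        assert m.records[0].iou == pytest.approx(1.0)

    def test_no_detections_all_fn(self, toy_dataset):
        m = match(DetectionSet("m", []), toy_dataset, 0.5)
        assert (m.n_tp, m.n_fp, m.n_fn) == (0, 0, 3)

    @pytest.mark.parametrize("seed", range(30))
    def test_counts_match_naive_oracle(self, seed):
        ds, dets = random_eval_scene(seed)
        m = match(dets, ds, 0.5)
        tp, fp, fn, _ = oracle_match_counts(ds, dets, 0.5)
        assert (m.n_tp, m.n_fp, m.n_fn) == (tp, fp, fn)
        assert m.n_tp + m.n_fn == len(ds.ground_truth)
        assert m.n_tp + m.n_fp == len(dets)

    def test_precision_recall_arithmetic(self):
        ds = make_dataset(
            [(1, 200, 200)],
            [(1, 0, 0, 20, 20), (1, 40, 40, 60, 60), (1, 80, 80, 100, 100),
             (1, 120, 120, 140, 140), (1, 160, 160, 180, 180)],
        )
        # 3 TPs, 1 FP, 2 FNs
        dets = make_dets("m", [
            (1, 0, 0, 20, 20, 0.9), (1, 40, 40, 60, 60, 0.8),
            (1, 80, 80, 100, 100, 0.7), (1, 0, 100, 20, 120, 0.6),
        ])
        p, r = precision_recall(match(dets, ds, 0.5))
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.6)

    def test_empty_case_conventions(self, toy_dataset):
        p, r = precision_recall(match(DetectionSet("m", []), toy_dataset, 0.5))
        assert (p, r) == (1.0, 0.0)
        empty_ds = make_dataset([(1, 10, 10)], [])
        dets = make_dets("m", [(1, 1, 1, 5, 5, 0.5)])
        p, r = precision_recall(match(dets, empty_ds, 0.5))
        assert (p, r) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# AP50
# ---------------------------------------------------------------------------

class TestAp50:
    def test_perfect_detector(self, toy_dataset):
        dets = make_dets("m", [
            (1, 10, 10, 40, 40, 0.9), (1, 60, 60, 90, 90, 0.8),
            (2, 20, 20, 50, 50, 0.7),
        ])
        assert ap50(dets, toy_dataset) == pytest.approx(1.0)

    def test_no_detections(self, toy_dataset):
        assert ap50(DetectionSet("m", []), toy_dataset) == 0.0

    @pytest.mark.parametrize("interp", ["coco_101_point", "all_point"])
    def test_toy_scene_matches_pr_integration_oracle(self, interp):
        # 3 GT, 5 detections: TP, FP, TP, FP, TP in score order
        ds = make_dataset(
            [(1, 200, 200)],
            [(1, 0, 0, 20, 20), (1, 50, 50, 70, 70), (1, 100, 100, 130, 130)],
        )
        dets = make_dets("m", [
            (1, 0, 0, 20, 20, 0.95), (1, 150, 0, 170, 20, 0.85),
            (1, 50, 50, 70, 70, 0.75), (1, 0, 150, 20, 170, 0.65),
            (1, 100, 100, 130, 130, 0.55),
        ])
        got = ap50(dets, ds, MetricsConfig(ap_interpolation=interp))
        _, _, _, flags = oracle_match_counts(ds, dets, 0.5)
        scored = [(d.score, flags[i][0], i)
                  for i, d in enumerate(dets.detections)]
        oracle = (oracle_ap_101 if interp == "coco_101_point"
                  else oracle_ap_staircase)(scored, 3)
        assert got == pytest.approx(oracle)

    @pytest.mark.parametrize("seed", range(20))
    def test_all_point_equals_staircase_oracle(self, seed):
        ds, dets = random_eval_scene(seed)
        if not ds.ground_truth:
            return
        got = ap50(dets, ds, MetricsConfig(ap_interpolation="all_point"))
        _, _, _, flags = oracle_match_counts(ds, dets, 0.5)
        scored = [(d.score, flags[i][0], i)
                  for i, d in enumerate(dets.detections)]
        assert got == pytest.approx(oracle_ap_staircase(scored, len(ds.ground_truth)))

    def test_adding_high_score_fp_never_increases_ap(self):
        for seed in range(10):
            ds, dets = random_eval_scene(seed)
            if not ds.ground_truth:
                continue
            base = ap50(dets, ds)
            worse = DetectionSet("m", dets.detections + [
                Detection(ds.images[0].image_id, Box(0, 90, 5, 99), 0.99, 1, "m")
            ])
            assert ap50(worse, ds) <= base + 1e-12


# ---------------------------------------------------------------------------
# AR
# ---------------------------------------------------------------------------

class TestAr:
    def test_perfect_localization(self, toy_dataset):
        dets = make_dets("m", [
            (1, 10, 10, 40, 40, 0.9), (1, 60, 60, 90, 90, 0.8),
            (2, 20, 20, 50, 50, 0.7),
        ])
        assert ar(dets, toy_dataset) == pytest.approx(1.0)

    def test_no_detections(self, toy_dataset):
        assert ar(DetectionSet("m", []), toy_dataset) == 0.0

    def test_step_function_at_iou_070(self):
        # detection covers 70% of its GT -> IoU exactly 0.7:
        # recall 1 for grid thresholds 0.5..0.7, 0 above -> AR = 5/10
        ds = make_dataset([(1, 100, 100)], [(1, 0, 0, 10, 10)])
        dets = make_dets("m", [(1, 0, 0, 10, 7, 0.9)])
        assert ar(dets, ds) == pytest.approx(0.5)

    def test_max_dets_cap(self):
        ds = make_dataset([(1, 400, 400)], [(1, 0, 0, 10, 10)])
        # the only true positive is the lowest-scoring of 3 detections
        specs = [(1, 100 + 20 * i, 100, 110 + 20 * i, 110, 0.9 - 0.1 * i)
                 for i in range(2)] + [(1, 0, 0, 10, 10, 0.1)]
        dets = make_dets("m", specs)
        assert ar(dets, ds, MetricsConfig(max_dets_per_image=2)) == 0.0
        assert ar(dets, ds, MetricsConfig(max_dets_per_image=3)) == 1.0


# ---------------------------------------------------------------------------
# LRP family
# ---------------------------------------------------------------------------

class TestLrp:
    def test_perfect_detections(self, toy_dataset):
        dets = make_dets("m", [
            (1, 10, 10, 40, 40, 0.9), (1, 60, 60, 90, 90, 0.8),
            (2, 20, 20, 50, 50, 0.7),
        ])
        assert lrp(dets, toy_dataset, 0.0) == pytest.approx((0, 0, 0, 0))

    def test_all_fn_case(self, toy_dataset):
        total, _, _, fn = lrp(DetectionSet("m", []), toy_dataset, 0.0)
        assert total == 1.0
        assert fn == 1.0

    def test_hand_computed_mixed_case(self):
        # 1 TP at IoU 0.75, 1 FP, 1 FN, tau 0.5:
        # lrp = (0.5 + 1 + 1)/3, components all 0.5
        ds = make_dataset(
            [(1, 100, 100)],
            [(1, 0, 0, 20, 20), (1, 60, 60, 80, 80)],
        )
        dets = make_dets("m", [
            (1, 0, 0, 20, 15, 0.9),   # IoU 300/400 = 0.75
            (1, 0, 50, 10, 60, 0.8),  # FP
        ])
        total, loc, fpv, fnv = lrp(dets, ds, score_thr=0.0, tau=0.5)
        assert total == pytest.approx(2.5 / 3)
        assert (loc, fpv, fnv) == (pytest.approx(0.5), pytest.approx(0.5),
                                   pytest.approx(0.5))

    def test_empty_gt_and_dets_zero(self):
        ds = make_dataset([(1, 10, 10)], [])
        assert lrp(DetectionSet("m", []), ds, 0.0) == (0, 0, 0, 0)


class TestOlrp:
    def test_single_perfect_detection(self):
        ds = make_dataset([(1, 100, 100)], [(1, 10, 10, 40, 40)])
        dets = make_dets("m", [(1, 10, 10, 40, 40, 0.9)])
        total, loc, fpv, fnv, thr = olrp(dets, ds)
        assert total == 0.0
        assert thr <= 0.9

    def test_fp_tail_pushed_past_optimal_threshold(self):
        ds = make_dataset([(1, 200, 200)],
                          [(1, 0, 0, 20, 20), (1, 50, 50, 70, 70)])
        dets = make_dets("m", [
            (1, 0, 0, 20, 20, 0.9), (1, 50, 50, 70, 70, 0.8),
            (1, 100, 0, 120, 20, 0.3), (1, 0, 100, 20, 120, 0.25),
            (1, 140, 140, 160, 160, 0.2),
        ])
        total, _, _, _, thr = olrp(dets, ds)
        assert thr > 0.3

    @pytest.mark.parametrize("seed", range(20))
    def test_minimum_property_and_component_identities(self, seed):
        ds, dets = random_eval_scene(seed)
        total, loc, fpv, fnv, thr = olrp(dets, ds)
        # oLRP is a minimum over thresholds (checks sweep vs direct route)
        for t in [0.0, 0.25, 0.5, 0.75, 1.0, thr]:
            assert total <= lrp(dets, ds, t)[0] + 1e-12
        # at the optimal threshold: FP term = 1 - precision, FN = 1 - recall
        kept = DetectionSet("m", [d for d in dets.detections
                                  if d.score >= thr])
        p, r = precision_recall(match(kept, ds, 0.5))
        if kept.detections or ds.ground_truth:
            assert fpv == pytest.approx(1 - p)
            assert fnv == pytest.approx(1 - r)

    def test_degrading_a_tp_increases_localization_error(self):
        ds = make_dataset([(1, 100, 100)], [(1, 0, 0, 20, 20)])
        good = make_dets("m", [(1, 0, 0, 20, 18, 0.9)])   # IoU 0.9
        bad = make_dets("m", [(1, 0, 0, 20, 12, 0.9)])    # IoU 0.6
        g = olrp(good, ds)
        b = olrp(bad, ds)
        assert b[1] > g[1]
        ds_counts_g = match(good, ds, 0.5)
        ds_counts_b = match(bad, ds, 0.5)
        assert (ds_counts_g.n_tp, ds_counts_g.n_fp) == \
            (ds_counts_b.n_tp, ds_counts_b.n_fp)


class TestEvaluate:
    def test_report_composition_consistency(self):
        ds, dets = random_eval_scene(11)
        rep = evaluate(dets, ds)
        assert rep.ap50 == pytest.approx(ap50(dets, ds))
        assert rep.ar == pytest.approx(ar(dets, ds))
        o = olrp(dets, ds)
        assert (rep.olrp, rep.olrp_loc, rep.olrp_fp, rep.olrp_fn,
                rep.lrp_opt_threshold) == o
        for v in (rep.ap50, rep.ar, rep.olrp, rep.olrp_loc, rep.olrp_fp,
                  rep.olrp_fn):
            assert 0.0 <= v <= 1.0

    def test_empty_detector_limits(self, toy_dataset):
        rep = evaluate(DetectionSet("m", []), toy_dataset)
        assert (rep.ap50, rep.ar, rep.olrp) == (0.0, 0.0, 1.0)
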