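"""Detection metrics: IoU, matching, AP, mAP — checked against
independent brute-force restatements of each definition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holotrack.detect import Detection
from holotrack.evaluate import (
    MAP_THRESHOLDS,
    average_precision,
    evaluate_detections,
    iou,
    match_detections,
    mean_average_precision,
)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_corner_overlap_one_seventh(self):
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_zero_area_box_rejected(self):
        with pytest.raises(ValueError, match="zero-area"):
            iou((0, 0, 0, 2), (0, 0, 2, 2))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(st.floats(0, 50), st.floats(0, 50),
                     st.floats(1, 30), st.floats(1, 30)),
           st.tuples(st.floats(0, 50), st.floats(0, 50),
                     st.floats(1, 30), st.floats(1, 30)))
    def test_symmetric_and_bounded(self, a, b):
        A = (a[0], a[1], a[0] + a[2], a[1] + a[3])
        B = (b[0], b[1], b[0] + b[2], b[1] + b[3])
        v = iou(A, B)
        assert v == iou(B, A)
        assert 0.0 <= v <= 1.0


def _match_bruteforce(dets, gts, thr):
    """Independent restatement: confidence-descending greedy, each
    detection claims the best unmatched truth at IoU ≥ thr."""
    order = sorted(dets, key=lambda d: (-d.confidence, d.x_center, d.y_center, d.width))
    free = list(range(len(gts)))
    labels = []
    for d in order:
        ious = [(iou(d, gts[j]), j) for j in free]
        if ious:
            best_iou, best_j = max(ious, key=lambda t: t[0])
            if best_iou >= thr:
                free.remove(best_j)
                labels.append((d, True))
                continue
        labels.append((d, False))
    return labels, len(free)


def _ap_bruteforce(labels, n_gt):
    """101-point interpolation computed from explicit threshold sweeps."""
    if not labels:
        return 0.0
    order = sorted(labels, key=lambda t: -t[0])
    points = []
    tp = fp = 0
    for _, is_tp in order:
        tp += is_tp
        fp += not is_tp
        points.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for r in np.linspace(0, 1, 101):
        cands = [p for rec, p in points if rec >= r]
        total += max(cands) if cands else 0.0
    return total / 101


def _random_scenario(seed, n_gt_max=8, n_det_max=12):
    rng = np.random.default_rng(seed)
    gts = [
        Detection(rng.uniform(20, 180), rng.uniform(20, 180),
                  rng.uniform(8, 40), rng.uniform(8, 40), frame_index=0)
        for _ in range(rng.integers(1, n_gt_max))
    ]
    dets = []
    for _ in range(rng.integers(0, n_det_max)):
        if gts and rng.uniform() < 0.7:
            base = gts[rng.integers(len(gts))]
            dets.append(Detection(
                base.x_center + rng.normal(scale=4),
                base.y_center + rng.normal(scale=4),
                max(base.width + rng.normal(scale=4), 2),
                max(base.height + rng.normal(scale=4), 2),
                confidence=round(float(rng.uniform(0.05, 1.0)), 3), frame_index=0))
        else:
            dets.append(Detection(rng.uniform(20, 180), rng.uniform(20, 180),
                                  rng.uniform(5, 30), rng.uniform(5, 30),
                                  confidence=round(float(rng.uniform(0.05, 1.0)), 3),
                                  frame_index=0))
    return dets, gts


class TestMatching:
    def test_exact_hit_is_tp(self):
        gt = Detection(50, 50, 20, 20)
        det = Detection(50, 50, 20, 20, confidence=0.8)
        labelled, fn = match_detections([det], [gt], 0.5)
        assert labelled == [(det, True)] and fn == 0

    def test_double_detection_yields_one_tp_one_fp(self):
        gt = Detection(50, 50, 20, 20)
        hi = Detection(50, 50, 20, 20, confidence=0.9)
        lo = Detection(51, 50, 20, 20, confidence=0.7)
        labelled, fn = match_detections([lo, hi], [gt], 0.5)
        assert dict((id(d), tp) for d, tp in labelled) == {id(hi): True, id(lo): False}
        assert fn == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_sets(self, seed):
        dets, gts = _random_scenario(seed)
        got, fn_got = match_detections(dets, gts, 0.5)
        exp, fn_exp = _match_bruteforce(dets, gts, 0.5)
        assert [(id(d), tp) for d, tp in got] == [(id(d), tp) for d, tp in exp]
        assert fn_got == fn_exp


class TestAveragePrecision:
    def test_perfect_detections_ap_one(self):
        labels = [(0.9, True), (0.8, True), (0.7, True)]
        assert average_precision(labels, 3) == pytest.approx(1.0)

    def test_no_correct_detections_ap_zero(self):
        labels = [(0.9, False), (0.8, False)]
        assert average_precision(labels, 4) == 0.0

    def test_small_mixed_set_matches_bruteforce(self):
        labels = [(0.95, True), (0.9, False), (0.8, True), (0.7, True),
                  (0.6, False), (0.5, True), (0.4, False)]
        assert average_precision(labels, 5) == pytest.approx(_ap_bruteforce(labels, 5))

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision([(0.9, True)], 0)

    def test_appending_lowest_confidence_fp_never_raises_ap(self):
        for seed in range(5):
            dets, gts = _random_scenario(seed)
            labelled, _ = _match_bruteforce(dets, gts, 0.5)
            labels = [(d.confidence, tp) for d, tp in labelled]
            n_gt = len(gts)
            base = average_precision(labels, n_gt)
            worse = average_precision(labels + [(0.001, False)], n_gt)
            assert worse <= base + 1e-12


class TestMeanAP:
    def test_perfect_detections_give_unit_map(self):
        gts = [Detection(50, 50, 20, 20), Detection(120, 120, 30, 30)]
        dets = [Detection(50, 50, 20, 20, confidence=0.9),
                Detection(120, 120, 30, 30, confidence=0.8)]
        aps = mean_average_precision(dets, gts)
        assert all(v == pytest.approx(1.0) for v in aps.values())

    def test_iou_exactly_0p6_scenario(self):
        """Boxes overlapping at IoU exactly 0.6 pass thresholds 0.50,
        0.55, 0.60 only: mAP(0.5:0.95) = 3/10 exactly."""
        gts, dets = [], []
        for i in range(4):
            x = 100.0 + 40 * i
            gts.append(Detection(x, 50.0, 10.0, 10.0, frame_index=0))
            # shift by 2.5 px: inter = 75, union = 125, IoU = 0.6
            dets.append(Detection(x + 2.5, 50.0, 10.0, 10.0,
                                  confidence=0.9, frame_index=0))
        aps = mean_average_precision(dets, gts)
        for thr, ap in aps.items():
            assert ap == (1.0 if thr <= 0.6 else 0.0)
        assert np.mean(list(aps.values())) == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_scenarios_match_per_threshold_bruteforce(self, seed):
        dets, gts = _random_scenario(seed)
        aps = mean_average_precision(dets, gts)
        for thr in MAP_THRESHOLDS:
            labels, _ = _match_bruteforce(dets, gts, thr)
            labels = [(d.confidence, tp) for d, tp in labels]
            assert aps[float(thr)] == pytest.approx(
                _ap_bruteforce(labels, len(gts)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_map_50_95_never_exceeds_map_50(self, seed):
        dets, gts = _random_scenario(seed + 100)
        report = evaluate_detections(dets, gts)
        assert report.map_50_95 <= report.map_50 + 1e-12


class TestEvaluateDetections:
    def test_report_counts_and_bounds(self):
        dets, gts = _random_scenario(3)
        rep = evaluate_detections(dets, gts, confidence_threshold=0.3)
        for v in (rep.precision, rep.recall, rep.map_50, rep.map_50_95,
                  rep.precision_best_f1, rep.recall_best_f1):
            assert 0.0 <= v <= 1.0
        if rep.tp + rep.fp:
            assert rep.precision == pytest.approx(rep.tp / (rep.tp + rep.fp))
        assert rep.recall == pytest.approx(rep.tp / (rep.tp + rep.fn))

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detections([], [])

    def test_json_serialization(self, tmp_path):
        dets, gts = _random_scenario(4)
        rep = evaluate_detections(dets, gts)
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json
        d = json.loads(path.read_text())
        assert set(d) >= {"Precision", "Recall", "mAP(0.5)", "mAP(0.5:0.95)"}
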