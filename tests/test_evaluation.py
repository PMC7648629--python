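import warnings

import numpy as np
import pytest

from dentopt.evaluation import (
    MatchOutcome,
    average_precision,
    evaluate_dataset,
    evaluate_folds,
    f1,
    iou,
    match_image,
    precision_recall,
)
from dentopt.model import BoundingBox, ValidationError
from .conftest import make_box, make_candidate


class TestIou:
    def test_identical_boxes(self):
        b = BoundingBox(0, 0, 10, 10)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 30, 30)) == 0.0

    def test_half_overlap_geometry(self):
        # intersection 50, union 150
        a = BoundingBox(0, 0, 10, 10)
        b = BoundingBox(5, 0, 15, 10)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            a = make_box(float(rng.uniform(0, 500)), w=60, h=100)
            b = make_box(float(rng.uniform(0, 500)), w=80, h=90)
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0.0 <= v <= 1.0
            assert (v == 1.0) == (a == b)


class TestMatching:
    def test_perfect_detections(self):
        gts = [(x, make_box(100.0 * x)) for x in range(1, 6)]
        dets = [make_candidate(x, 100.0 * x + 3.0, 0.9) for x in range(1, 6)]
        m = match_image(dets, gts)
        assert (m.tp, m.fp, m.fn) == (5, 0, 0)

    def test_duplicate_on_matched_gt_is_fp(self):
        gts = [(1, make_box(100.0))]
        dets = [make_candidate(1, 100.0, 0.9), make_candidate(1, 103.0, 0.6)]
        m = match_image(dets, gts)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        # highest-confidence detection claims the box
        assert m.matched_pairs[0][0].confidence == 0.9

    def test_low_iou_detection_is_fp_and_leaves_fn(self):
        gts = [(1, BoundingBox(0, 0, 10, 10))]
        dets = [make_candidate(1, 0, 0.9)]
        dets = [dets[0].__class__(tooth=1, box=BoundingBox(6, 0, 16, 10),
                                  confidence=0.9, rank=1)]  # IOU = 4/16 = 0.25
        m = match_image(dets, gts)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_wrong_class_never_matches(self):
        gts = [(1, make_box(100.0))]
        dets = [make_candidate(2, 100.0, 0.9)]
        m = match_image(dets, gts)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_counting_identities(self, rng):
        gts = [(int(t), make_box(float(rng.uniform(100, 900))))
               for t in rng.integers(1, 33, size=20)]
        dets = [make_candidate(int(t), float(rng.uniform(100, 900)), float(rng.uniform(0, 1)))
                for t in rng.integers(1, 33, size=15)]
        m = match_image(dets, gts)
        assert m.tp + m.fn == len(gts)
        assert m.tp + m.fp == len(dets)


class TestRatios:
    def test_precision_recall_basic(self):
        p, r = precision_recall(MatchOutcome(tp=3, fp=1, fn=0))
        assert (p, r) == (0.75, 1.0)

    def test_zero_over_zero_convention(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r = precision_recall(MatchOutcome(tp=0, fp=0, fn=5))
        assert p == 0.0 and r == 0.0

    def test_ratio_arithmetic(self):
        p, r = precision_recall(MatchOutcome(tp=97, fp=3, fn=1))
        assert p == pytest.approx(0.97)
        assert r == pytest.approx(97 / 98)

    @pytest.mark.parametrize(
        "p,r,expected",
        [(0.975, 0.978, 0.976), (0.988, 0.978, 0.983), (0.7, 0.7, 0.7)],
    )
    def test_f1_values(self, p, r, expected):
        assert round(f1(p, r), 3) == expected

    def test_f1_degenerate(self):
        assert f1(0.0, 0.0) == 0.0


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([(0.9, True), (0.8, True)], n_gt=2) == 1.0

    def test_tp_fp_tp_ranking(self):
        # precision envelope: 1.0 up to recall 0.5, then 2/3
        ap = average_precision([(0.9, True), (0.8, False), (0.7, True)], n_gt=2)
        assert ap == pytest.approx(5 / 6)

    def test_no_detections(self):
        assert average_precision([], n_gt=3) == 0.0

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError):
            average_precision([(0.9, True)], n_gt=0)

    def test_invariant_to_monotone_confidence_rescaling(self, rng):
        outcomes = [(float(c), bool(o)) for c, o in
                    zip(rng.uniform(0.01, 1, 20), rng.random(20) < 0.6)]
        ap1 = average_precision(outcomes, n_gt=12)
        squashed = [(c ** 3 / 2, o) for c, o in outcomes]
        assert average_precision(squashed, n_gt=12) == pytest.approx(ap1)

    def test_11_point_close_to_all_point_on_ideal_curve(self):
        outcomes = [(1 - 0.01 * i, True) for i in range(10)]
        assert average_precision(outcomes, 10, style="11_point") == 1.0


class TestDatasetEvaluation:
    def _perfect(self, n_images=4):
        gt, det = {}, {}
        for i in range(n_images):
            img = f"img{i}"
            gt[img] = {x: make_box(100.0 * x) for x in range(1, 33)}
            det[img] = [make_candidate(x, 100.0 * x + 2.0, 0.95) for x in range(1, 33)]
        return det, gt

    def test_perfect_dataset(self):
        det, gt = self._perfect()
        report = evaluate_dataset(det, gt)
        assert report.f1 == 1.0 and report.map == 1.0
        assert report.fp == 0 and report.fn == 0

    def test_injected_fp_lowers_precision_only(self):
        det, gt = self._perfect()
        clean = evaluate_dataset(det, gt)
        noisy = {img: list(d) + [make_candidate(1, 5000.0, 0.5)] for img, d in det.items()}
        report = evaluate_dataset(noisy, gt)
        assert report.precision < clean.precision
        assert report.recall == clean.recall

    def test_orphan_images_rejected(self):
        det, gt = self._perfect()
        del gt["img0"]
        with pytest.raises(ValidationError, match="img0"):
            evaluate_dataset(det, gt)

    def test_fold_table_shape(self):
        det, gt = self._perfect(n_images=10)
        folds = {f"K{i+1}": [f"img{2*i}", f"img{2*i+1}"] for i in range(5)}
        reports, table = evaluate_folds(det, gt, folds)
        assert len(reports) == 5
        assert list(table.index[:5]) == [f"K{i+1}" for i in range(5)]
        assert {"mean", "min", "max"} <= set(table.index)
        assert table.loc["mean", "f1"] == 1.0
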