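"""Detection metrics against brute-force oracles.

The AP oracle below re-derives the 101-point interpolated AP by scanning
every score cutoff explicitly and, for each of the 101 recall points,
searching the maximum precision among cutoffs achieving at least that
recall — no sorting/cumsum machinery shared with the implementation.
"""

import numpy as np
import pytest

from dsadet.evaluation import (
    average_precision,
    box_iou,
    evaluate_detections,
    match_detections,
    precision_recall_f1,
)


def brute_force_ap_101(dets, gts, class_id, iou_thresh):
    """All-cutoff enumeration oracle for 101-point interpolated AP."""
    n_gt = sum(1 for _, c, _ in gts if c == class_id)
    if n_gt == 0:
        return float("nan")
    cls_dets = [d for d in dets if d[1] == class_id]
    cutoffs = sorted({d[2] for d in cls_dets}, reverse=True)
    pr_points = []  # (recall, precision) at every cutoff
    for cut in cutoffs:
        tp = fp = 0
        img_ids = {d[0] for d in cls_dets} | {g[0] for g in gts if g[1] == class_id}
        for img in img_ids:
            dd = [
                (class_id, s, b)
                for (i, c, s, b) in cls_dets
                if i == img and s >= cut
            ]
            gg = [(c, b) for (i, c, b) in gts if i == img and c == class_id]
            t, f, _ = match_detections(dd, gg, iou_thresh)
            tp += t
            fp += f
        rec = tp / n_gt
        pre = tp / (tp + fp) if tp + fp else 0.0
        pr_points.append((rec, pre))
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        candidates = [p for rr, p in pr_points if rr >= r - 1e-12]
        ap += max(candidates) if candidates else 0.0
    return ap / 101.0


def random_instance(rng, n_images=3, n_classes=2, n_dets=10, n_gts=6):
    gts, dets = [], []
    for _ in range(n_gts):
        x1, y1 = rng.uniform(0, 60, 2)
        w, h = rng.uniform(10, 30, 2)
        gts.append((int(rng.integers(n_images)), int(rng.integers(n_classes)),
                    (x1, y1, x1 + w, y1 + h)))
    for _ in range(n_dets):
        if rng.random() < 0.6 and gts:
            img, c, (x1, y1, x2, y2) = gts[rng.integers(len(gts))]
            jitter = rng.uniform(-8, 8, 4)
            box = (x1 + jitter[0], y1 + jitter[1], max(x1 + jitter[0] + 2, x2 + jitter[2]),
                   max(y1 + jitter[1] + 2, y2 + jitter[3]))
        else:
            img = int(rng.integers(n_images))
            c = int(rng.integers(n_classes))
            x1, y1 = rng.uniform(0, 60, 2)
            w, h = rng.uniform(10, 30, 2)
            box = (x1, y1, x1 + w, y1 + h)
        dets.append((img, c, float(rng.random()), box))
    return dets, gts


class TestMatching:
    def test_perfect_detections(self):
        gts = [(0, (0, 0, 10, 10)), (1, (20, 20, 40, 40))]
        dets = [(c, 0.9, b) for c, b in gts]
        assert match_detections(dets, gts, 0.5) == (2, 0, 0)

    def test_no_detections_all_missed(self):
        gts = [(0, (0, 0, 10, 10)), (0, (20, 20, 30, 30))]
        assert match_detections([], gts, 0.5) == (0, 0, 2)

    def test_two_detections_one_gt_greedy(self):
        """Higher-scoring det takes the gt; the second becomes a FP."""
        gt = [(0, (0.0, 0.0, 10.0, 10.0))]
        dets = [
            (0, 0.8, (0.0, 0.0, 10.0, 8.0)),   # IoU 0.8
            (0, 0.9, (0.0, 0.0, 10.0, 9.0)),   # IoU 0.9, matched first
        ]
        assert match_detections(dets, gt, 0.5) == (1, 1, 0)

    def test_class_mismatch_never_matches(self):
        gt = [(0, (0, 0, 10, 10))]
        dets = [(1, 0.99, (0, 0, 10, 10))]
        assert match_detections(dets, gt, 0.5) == (0, 1, 1)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            match_detections([], [], 0.0)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,want",
        [
            (9, 1, 1, (0.9, 0.9, 0.9)),
            (0, 0, 0, (0.0, 0.0, 0.0)),
            (1, 3, 0, (0.25, 1.0, 0.4)),
        ],
    )
    def test_closed_forms(self, tp, fp, fn, want):
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        assert (p, r, f1) == pytest.approx(want)

    def test_f1_is_harmonic_mean(self):
        p, r, f1 = precision_recall_f1(7, 3, 5)
        assert f1 == pytest.approx(2 * p * r / (p + r))


class TestAveragePrecision:
    def test_perfect_detections_ap_one(self):
        gts = [(0, 0, (0, 0, 10, 10)), (1, 0, (5, 5, 25, 25))]
        dets = [(i, c, 0.9, b) for i, c, b in gts]
        assert average_precision(dets, gts, 0) == pytest.approx(1.0)

    def test_wrong_class_only_gives_zero(self):
        gts = [(0, 0, (0, 0, 10, 10))]
        dets = [(0, 1, 0.9, (0, 0, 10, 10))]
        assert average_precision(dets, gts, 0) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_cutoff_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        dets, gts = random_instance(rng)
        for c in (0, 1):
            want = brute_force_ap_101(dets, gts, c, 0.5)
            got = average_precision(dets, gts, c, 0.5)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-6)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(3)
        dets, gts = random_instance(rng)
        squashed = [(i, c, s**3 * 0.5 + 0.1, b) for i, c, s, b in dets]
        for c in (0, 1):
            a = average_precision(dets, gts, c)
            b = average_precision(squashed, gts, c)
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)

    def test_extra_lowest_false_positive_never_raises_ap(self):
        rng = np.random.default_rng(4)
        dets, gts = random_instance(rng)
        worse = dets + [(0, 0, 1e-6, (500.0, 500.0, 550.0, 550.0))]
        assert average_precision(worse, gts, 0) <= average_precision(dets, gts, 0) + 1e-12

    def test_top_scoring_true_positive_never_lowers_ap(self):
        rng = np.random.default_rng(5)
        dets, gts = random_instance(rng)
        extra_gt = gts + [(9, 0, (0.0, 0.0, 20.0, 20.0))]
        better = dets + [(9, 0, 1.0, (0.0, 0.0, 20.0, 20.0))]
        assert average_precision(better, extra_gt, 0) >= average_precision(
            dets, extra_gt, 0
        ) - 1e-12

    def test_all_point_variant_close_to_101point(self):
        rng = np.random.default_rng(6)
        dets, gts = random_instance(rng, n_dets=30, n_gts=12)
        a = average_precision(dets, gts, 0, interpolation="101point")
        b = average_precision(dets, gts, 0, interpolation="all_point")
        assert abs(a - b) < 0.1


class TestEvaluateDetections:
    def test_map5095_never_exceeds_map50(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            dets, gts = random_instance(rng, n_dets=15, n_gts=8)
            res = evaluate_detections(dets, gts, num_classes=2)
            assert res.map5095 <= res.map50 + 1e-12

    def test_perfect_detections_full_scores(self):
        gts = [(0, c, (10.0 * c, 0.0, 10.0 * c + 8, 8.0)) for c in range(3)]
        dets = [(i, c, 0.9, b) for i, c, b in gts]
        res = evaluate_detections(dets, gts, num_classes=3)
        assert res.map50 == pytest.approx(1.0)
        assert res.map5095 == pytest.approx(1.0)
        assert res.precision == pytest.approx(1.0)
        assert res.recall == pytest.approx(1.0)
        assert res.f1 == pytest.approx(1.0)

    def test_operating_point_maximizes_f1(self):
        gts = [(0, 0, (0.0, 0.0, 10.0, 10.0))]
        dets = [
            (0, 0, 0.9, (0.0, 0.0, 10.0, 10.0)),
            (0, 0, 0.5, (30.0, 30.0, 40.0, 40.0)),  # FP filtered by threshold
        ]
        res = evaluate_detections(dets, gts, num_classes=1)
        assert res.precision == 1.0 and res.recall == 1.0

    def test_iou_matrix_basics(self):
        a = np.array([[0, 0, 10, 10]])
        b = np.array([[0, 0, 10, 10], [5, 0, 15, 10], [20, 20, 30, 30]])
        ious = box_iou(a, b)[0]
        assert ious == pytest.approx([1.0, 1 / 3, 0.0])
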