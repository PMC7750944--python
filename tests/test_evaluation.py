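"""Missing/split/added matching, border correction, summary metrics."""

import numpy as np
import pytest

import beadspot as bs
from beadspot.evaluation import MatchTable, evaluate_image


def brute_force_report(gt_centroids, pred_centroids, shape, halfwidth=3, margin=4):
    """Independent raster-walk implementation of the whole evaluation.

    Builds the enlarged-region label raster pixel by pixel from first
    principles (nearest centroid among those whose enlargement square covers
    the pixel), assigns every prediction by direct lookup, and computes the
    metrics from explicit counts.
    """
    h, w = shape
    gt = np.asarray(gt_centroids, float).reshape(-1, 2)
    side = 2 * halfwidth + 2
    labels = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            best = 0
            best_d = None
            for i, (gr, gc) in enumerate(gt):
                r0 = int(np.ceil(gr - (side - 1) / 2 - 0.5))
                c0 = int(np.ceil(gc - (side - 1) / 2 - 0.5))
                if r0 <= r < r0 + side and c0 <= c < c0 + side:
                    d = (r - gr) ** 2 + (c - gc) ** 2
                    if best_d is None or d < best_d - 1e-12:
                        best, best_d = i + 1, d
            labels[r, c] = best
    seeds = np.zeros(len(gt), dtype=int)
    added = border = 0
    for pr, pc in np.asarray(pred_centroids, float).reshape(-1, 2):
        rr, cc = int(np.floor(pr + 0.5)), int(np.floor(pc + 0.5))
        if not (0 <= rr < h and 0 <= cc < w):
            border += 1
        elif labels[rr, cc] > 0:
            seeds[labels[rr, cc] - 1] += 1
        elif rr < margin or rr >= h - margin or cc < margin or cc >= w - margin:
            border += 1
        else:
            added += 1
    miss = int((seeds == 0).sum())
    split = int((seeds >= 2).sum())
    extra = int(np.maximum(seeds - 1, 0).sum())
    tp, fp, fn = len(gt) - miss, added + extra, miss
    qp = tp / (tp + fp) if tp + fp else 0.0
    qr = tp / (tp + fn)
    qf = 2 * qp * qr / (qp + qr) if tp else 0.0
    return {
        "Q_F": qf, "Q_P": qp, "Q_R": qr,
        "Q_split": 100 * split / len(gt), "Q_miss": 100 * miss / len(gt),
        "Q_add": 100 * added / len(gt),
        "detections": 100 * (tp + extra + added) / len(gt),
    }


class TestEnlargeGT:
    def test_single_seed_grows_to_8x8(self):
        labels = bs.enlarge_gt(np.array([[15.5, 15.5]]), (32, 32))
        assert (labels == 1).sum() == 64
        rows = np.nonzero(labels.any(axis=1))[0]
        assert rows.min() == 12 and rows.max() == 19

    def test_far_apart_seeds_equal_disjoint_regions(self):
        labels = bs.enlarge_gt(np.array([[8.0, 8.0], [24.0, 24.0]]), (40, 40))
        assert (labels == 1).sum() == (labels == 2).sum() == 64

    def test_overlapping_regions_split_by_nearest_centroid(self):
        cents = np.array([[16.0, 14.0], [16.0, 18.0]])
        labels = bs.enlarge_gt(cents, (32, 32))
        assert (labels > 0).any()
        for r, c in np.argwhere(labels > 0):
            d = np.hypot(r - cents[:, 0], c - cents[:, 1])
            nearest = d.argmin() + 1
            if abs(d[0] - d[1]) > 1e-9:  # ties go to the lower index
                assert labels[r, c] == nearest
            else:
                assert labels[r, c] == 1

    def test_regions_clip_at_image_edge(self):
        labels = bs.enlarge_gt(np.array([[1.0, 1.0]]), (16, 16))
        assert (labels == 1).sum() < 64
        assert labels[0, 0] == 1


class TestMatchDetections:
    def test_perfect_predictions_match_one_to_one(self):
        gt = np.array([[10.0, 10.0], [20.0, 24.0]])
        regions = bs.enlarge_gt(gt, (32, 32))
        table = bs.match_detections(regions, gt)
        assert table.seeds_per_bead.tolist() == [1, 1]
        assert table.n_added == 0

    def test_border_prediction_ignored(self):
        gt = np.array([[16.0, 16.0]])
        regions = bs.enlarge_gt(gt, (32, 32))
        preds = np.array([[16.0, 16.0], [2.0, 2.0]])  # corner, within margin 4
        table = bs.match_detections(regions, preds, border_margin=4)
        assert table.n_border_ignored == 1 and table.n_added == 0

    def test_two_predictions_in_one_bead_is_split(self):
        gt = np.array([[16.0, 16.0]])
        regions = bs.enlarge_gt(gt, (32, 32))
        preds = np.array([[15.0, 15.0], [17.0, 17.0]])
        table = bs.match_detections(regions, preds)
        assert table.seeds_per_bead.tolist() == [2]

    def test_background_prediction_away_from_border_is_added(self):
        gt = np.array([[8.0, 8.0]])
        regions = bs.enlarge_gt(gt, (32, 32))
        table = bs.match_detections(regions, np.array([[24.0, 24.0]]))
        assert table.n_added == 1

    def test_out_of_raster_prediction_counts_as_border(self):
        regions = bs.enlarge_gt(np.array([[8.0, 8.0]]), (16, 16))
        table = bs.match_detections(regions, np.array([[40.0, 2.0]]))
        assert table.n_border_ignored == 1

    def test_total_prediction_conservation(self, rng):
        gt = rng.uniform(4, 60, size=(6, 2))
        preds = rng.uniform(0, 64, size=(30, 2))
        regions = bs.enlarge_gt(gt, (64, 64))
        t = bs.match_detections(regions, preds)
        assert t.seeds_per_bead.sum() + t.n_added + t.n_border_ignored == 30


class TestComputeMetrics:
    # reconstructed error counts for a 670-bead test set (counts, expected)
    WORKED_EXAMPLES = [
        # (miss, split, added) -> (Q_F, Q_P, Q_R, detections)
        ((54, 0, 26), (0.939, 0.960, 0.919, 95.82)),    # LoG-based seeding
        ((79, 0, 14), (0.927, 0.977, 0.882, 90.30)),    # circular Hough
        ((290, 14, 102), (0.652, 0.766, 0.567, 74.03)), # Otsu + EDT
    ]

    @pytest.mark.parametrize("counts,expected", WORKED_EXAMPLES)
    def test_error_count_worked_examples(self, counts, expected):
        miss, split, added = counts
        table = MatchTable.from_error_counts(670, miss, split, added)
        rep = bs.compute_metrics(table)
        qf, qp, qr, det = expected
        assert rep.Q_F == pytest.approx(qf, abs=5e-4)
        assert rep.Q_P == pytest.approx(qp, abs=5e-4)
        assert rep.Q_R == pytest.approx(qr, abs=5e-4)
        assert rep.detections == pytest.approx(det, abs=5e-3)

    def test_perfect_detection(self):
        rep = bs.compute_metrics(MatchTable.from_error_counts(100, 0, 0, 0))
        assert rep.Q_F == rep.Q_P == rep.Q_R == 1.0
        assert rep.detections == 100.0 and rep.Q_miss == 0.0

    def test_detections_identity_for_two_seed_splits(self, rng):
        # detections = 100 - Q_miss + Q_add + Q_split when every split bead
        # has exactly two seeds
        for _ in range(20):
            n = int(rng.integers(10, 200))
            miss = int(rng.integers(0, n // 2))
            split = int(rng.integers(0, n // 4))
            added = int(rng.integers(0, n))
            rep = bs.compute_metrics(MatchTable.from_error_counts(n, miss, split, added))
            assert rep.detections == pytest.approx(
                100 - rep.Q_miss + rep.Q_add + rep.Q_split, abs=1e-9
            )

    def test_added_background_prediction_degrades_precision_only(self):
        t0 = MatchTable.from_error_counts(50, 5, 2, 0)
        t1 = MatchTable.from_error_counts(50, 5, 2, 3)
        r0, r1 = bs.compute_metrics(t0), bs.compute_metrics(t1)
        assert r1.Q_P < r0.Q_P
        assert r1.Q_R == r0.Q_R

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            bs.compute_metrics(MatchTable(np.empty(0, dtype=int)))

    def test_all_missed_gives_zero_f(self):
        rep = bs.compute_metrics(MatchTable.from_error_counts(10, 10, 0, 5))
        assert rep.Q_F == 0.0 and rep.Q_R == 0.0


class TestOracleEquivalence:
    def test_matches_raster_walk_on_random_scenes(self, rng):
        """Implementation vs independent brute-force on random scenes."""
        for _ in range(25):
            n_gt = int(rng.integers(1, 8))
            gt = rng.uniform(2, 46, size=(n_gt, 2))
            n_pred = int(rng.integers(0, 14))
            preds = rng.uniform(-1, 49, size=(n_pred, 2))
            table = evaluate_image(gt, preds, (48, 48))
            rep = bs.compute_metrics(table).as_dict()
            expected = brute_force_report(gt, preds, (48, 48))
            for key, val in expected.items():
                assert rep[key] == pytest.approx(val, abs=1e-9), key


class TestEvaluateDetector:
    def test_single_image_equals_direct_metrics(self):
        image = np.zeros((16, 16))
        gt = np.array([[8.0, 8.0]])
        det = lambda img: bs.DetectionSet(bs.map_centroid_up(gt, 4).reshape(-1, 2), [1])
        rep, tables = bs.evaluate_detector([(image, gt)], det)
        assert rep.Q_F == 1.0 and len(tables) == 1

    def test_pooling_differs_from_mean_of_per_image_metrics(self):
        # image A: 1 bead, missed; image B: 9 beads, all found.
        # pooled recall = 9/10; mean of per-image recalls = 0.5
        img = np.zeros((16, 16))
        gt_a = np.array([[4.0, 4.0]])
        gt_b = np.array([[float(r), float(c)] for r in (4, 8, 12) for c in (4, 8, 12)])

        def det(image_in):
            if det.calls == 0:
                det.calls += 1
                return bs.DetectionSet()
            return bs.DetectionSet(bs.map_centroid_up(gt_b, 4).reshape(-1, 2), np.ones(9))

        det.calls = 0
        rep, _ = bs.evaluate_detector([(img, gt_a), (img, gt_b)], det)
        assert rep.Q_R == pytest.approx(0.9)

    def test_no_images_rejected(self):
        with pytest.raises(ValueError):
            bs.evaluate_detector([], lambda img: bs.DetectionSet())
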