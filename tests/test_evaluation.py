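"""Detection metrics: IoU, greedy matching, interpolated AP, AR."""

import json

import numpy as np
import pytest

from abfp.evaluation import (
    IOU_THRESHOLDS,
    BoxSet,
    average_precision,
    boxsets_to_coco,
    evaluate,
    iou,
    iou_matrix,
    load_coco_detections,
    load_coco_ground_truth,
    match_and_pr,
)

from .oracles import oracle_average_precision


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 2, 2), (5, 5, 7, 7)) == 0.0

    def test_half_overlap_integer_grid(self):
        # intersection 50, union 150 (pixel-count oracle on the integer grid)
        assert iou((0, 0, 10, 10), (5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 4), (0, 0, 2, 2))

    def test_matrix_agrees_with_scalar(self, rng):
        a = np.sort(rng.uniform(0, 20, (5, 2, 2)), axis=2).reshape(5, 4)[:, [0, 2, 1, 3]]
        b = np.sort(rng.uniform(0, 20, (4, 2, 2)), axis=2).reshape(4, 4)[:, [0, 2, 1, 3]]
        a[:, 2:] += 1.0
        b[:, 2:] += 1.0
        mat = iou_matrix(a, b)
        for i in range(len(a)):
            for j in range(len(b)):
                assert mat[i, j] == pytest.approx(iou(a[i], b[j]))


class TestMatching:
    def test_single_perfect_detection(self):
        gts = [BoxSet(boxes=[[0, 0, 4, 4]], image_id=0)]
        dets = [BoxSet(boxes=[[0, 0, 4, 4]], scores=[0.9], image_id=0)]
        pr = match_and_pr(dets, gts, 0.5)
        np.testing.assert_allclose(pr, [[1.0, 1.0]])

    def test_tp_then_fp(self):
        gts = [BoxSet(boxes=[[0, 0, 4, 4]], image_id=0)]
        dets = [BoxSet(boxes=[[0, 0, 4, 4], [10, 10, 14, 14]],
                       scores=[0.9, 0.8], image_id=0)]
        pr = match_and_pr(dets, gts, 0.5)
        np.testing.assert_allclose(pr, [[1.0, 1.0], [1.0, 0.5]])

    def test_partial_recall(self):
        gts = [BoxSet(boxes=[[0, 0, 4, 4], [10, 10, 14, 14]], image_id=0)]
        dets = [BoxSet(boxes=[[0, 0, 4, 4]], scores=[0.9], image_id=0)]
        pr = match_and_pr(dets, gts, 0.5)
        np.testing.assert_allclose(pr, [[0.5, 1.0]])

    def test_each_gt_matched_once(self):
        gts = [BoxSet(boxes=[[0, 0, 4, 4]], image_id=0)]
        dets = [BoxSet(boxes=[[0, 0, 4, 4], [0, 0, 4, 4]],
                       scores=[0.9, 0.8], image_id=0)]
        pr = match_and_pr(dets, gts, 0.5)
        np.testing.assert_allclose(pr, [[1.0, 1.0], [1.0, 0.5]])

    def test_empty_ground_truth_gives_zero_ap(self):
        gts = [BoxSet(boxes=np.zeros((0, 4)), image_id=0)]
        dets = [BoxSet(boxes=[[0, 0, 4, 4]], scores=[0.9], image_id=0)]
        assert average_precision(match_and_pr(dets, gts, 0.5)) == 0.0


class TestAveragePrecision:
    def test_perfect_detector(self):
        assert average_precision([[1.0, 1.0]]) == 1.0

    def test_envelope_recovers_full_precision(self):
        # (1, 1) then (1, 0.5): max precision per recall is 1 everywhere
        assert average_precision([[1.0, 1.0], [1.0, 0.5]]) == 1.0

    def test_empty_detections(self):
        assert average_precision(np.zeros((0, 2))) == 0.0

    def test_half_recall_plateau(self):
        # precision 1 up to recall 0.5, nothing beyond: grid gives 51/101
        assert average_precision([[0.5, 1.0]]) == pytest.approx(51 / 101)

    def test_matches_integration_oracle_on_random_curves(self, rng):
        for _ in range(50):
            n = rng.integers(1, 12)
            tp = rng.random(n) < 0.6
            cum_tp = np.cumsum(tp)
            n_gt = max(1, cum_tp[-1] + rng.integers(0, 3))
            recall = cum_tp / n_gt
            precision = cum_tp / (np.arange(n) + 1)
            pr = np.stack([recall, precision], axis=1)
            assert average_precision(pr) == pytest.approx(
                oracle_average_precision(pr), abs=1e-9
            )


class TestEvaluate:
    def _uniform_iou_setup(self, n=8):
        """Detections whose IoU with each GT is exactly 0.6 (75 over 125)."""
        gts, dets = [], []
        for i in range(n):
            gts.append(BoxSet(boxes=[[0, 0, 10, 10]], image_id=i))
            dets.append(BoxSet(boxes=[[2.5, 0, 12.5, 10]], scores=[0.9], image_id=i))
        return dets, gts

    def test_perfect_detections_score_one_everywhere(self):
        gts = [BoxSet(boxes=[[0, 0, 4, 4], [8, 8, 12, 12]], image_id=0)]
        dets = [BoxSet(boxes=[[0, 0, 4, 4], [8, 8, 12, 12]],
                       scores=[0.9, 0.8], image_id=0)]
        res = evaluate(dets, gts)
        assert res.AP == res.AP50 == res.AP75 == res.AR == 1.0

    def test_uniform_iou_06_gives_ap_three_tenths(self):
        dets, gts = self._uniform_iou_setup()
        res = evaluate(dets, gts)
        # thresholds 0.50, 0.55, 0.60 pass; the other seven fail
        assert res.AP == pytest.approx(3 / 10, abs=1e-9)
        assert res.AP50 == 1.0
        assert res.AP75 == 0.0
        assert res.AR == pytest.approx(3 / 10, abs=1e-9)

    def test_empty_detections_score_zero(self):
        gts = [BoxSet(boxes=[[0, 0, 4, 4]], image_id=0)]
        dets = [BoxSet(boxes=np.zeros((0, 4)), scores=np.zeros(0), image_id=0)]
        res = evaluate(dets, gts)
        assert res.AP == res.AP50 == res.AP75 == res.AR == 0.0

    def test_no_images_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])

    def test_ap_monotone_in_iou_threshold(self, rng):
        dets, gts = _random_cases(rng, n_images=6)
        aps = [average_precision(match_and_pr(dets, gts, float(t))) for t in IOU_THRESHOLDS]
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))

    def test_low_score_fp_never_increases_ap(self, rng):
        dets, gts = _random_cases(rng, n_images=5)
        base = evaluate(dets, gts)
        worst = [
            BoxSet(boxes=np.vstack([d.boxes, [[90, 90, 95, 95]]]),
                   scores=np.concatenate([d.scores, [1e-4]]), image_id=d.image_id)
            for d in dets
        ]
        res = evaluate(worst, gts)
        for t_base, t_new in zip(base.per_threshold_AP, res.per_threshold_AP):
            assert t_new <= t_base + 1e-12

    def test_invariants_between_summary_metrics(self, rng):
        dets, gts = _random_cases(rng, n_images=8)
        res = evaluate(dets, gts)
        assert res.AP <= res.AP50 + 1e-12
        assert res.AP75 <= res.AP50 + 1e-12
        assert res.AP == pytest.approx(np.mean(res.per_threshold_AP))


def _random_cases(rng, n_images=5, max_gt=3, max_det=5):
    gts, dets = [], []
    for i in range(n_images):
        n_gt = rng.integers(0, max_gt + 1)
        g = []
        for _ in range(n_gt):
            x, y = rng.uniform(0, 60, 2)
            w, h = rng.uniform(4, 20, 2)
            g.append([x, y, x + w, y + h])
        gts.append(BoxSet(boxes=np.asarray(g).reshape(-1, 4), image_id=i))
        n_det = rng.integers(0, max_det + 1)
        d, s = [], []
        for _ in range(n_det):
            if n_gt and rng.random() < 0.6:
                base = np.asarray(g[rng.integers(0, n_gt)], dtype=float)
                jitter = rng.uniform(-4, 4, 4)
                cand = base + jitter
                if cand[2] - cand[0] > 1 and cand[3] - cand[1] > 1:
                    d.append(cand)
                    s.append(rng.random())
                    continue
            x, y = rng.uniform(0, 60, 2)
            w, h = rng.uniform(4, 20, 2)
            d.append([x, y, x + w, y + h])
            s.append(rng.random())
        dets.append(BoxSet(boxes=np.asarray(d).reshape(-1, 4),
                           scores=np.asarray(s), image_id=i))
    return dets, gts


class TestCocoIO:
    def test_round_trip_through_json(self, tmp_path, rng):
        dets, gts = _random_cases(rng, n_images=3)
        gt_json = {
            "images": [{"id": g.image_id, "width": 100, "height": 100} for g in gts],
            "annotations": [
                {"id": k, "image_id": g.image_id, "category_id": 1,
                 "bbox": [b[0], b[1], b[2] - b[0], b[3] - b[1]], "iscrowd": 0,
                 "area": float((b[2] - b[0]) * (b[3] - b[1]))}
                for k, (g, b) in enumerate(
                    [(g, b) for g in gts for b in g.boxes]
                )
            ],
            "categories": [{"id": 1, "name": "lesion"}],
        }
        gt_path = tmp_path / "gt.json"
        det_path = tmp_path / "dets.json"
        gt_path.write_text(json.dumps(gt_json))
        det_path.write_text(json.dumps(boxsets_to_coco(dets)))
        gts2 = load_coco_ground_truth(gt_path)
        dets2 = load_coco_detections(det_path)
        res = evaluate(dets, gts)
        res2 = evaluate(dets2, gts2)
        assert res2.AP == pytest.approx(res.AP, abs=1e-12)
        assert res2.AR == pytest.approx(res.AR, abs=1e-12)
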