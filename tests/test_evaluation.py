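"""OKS and AP/AR: closed forms, matching protocol, oracle equivalence.

The oracle here is an independent brute-force evaluator written with
plain loops and a literal reading of the COCO protocol (greedy per-image
matching, global score ranking, 101-point interpolated AP); it shares no
code with the package implementation.
"""

import numpy as np
import pytest

import structpose as sp
from structpose.decode import DecodedPose
from structpose.evaluation import OKS_THRESHOLDS, match_and_score, oks

from conftest import random_pose


def _pred_from(gt, offset=(0.0, 0.0), score=0.9, image_id=0):
    kps = gt.keypoints[:, :2] + np.asarray(offset)
    return DecodedPose(keypoints=kps, score=score, center=tuple(kps.mean(axis=0)),
                       image_id=image_id)


class TestOKS:
    def test_identity_is_one(self, worm_schema):
        gt = random_pose(np.random.default_rng(0), worm_schema)
        assert oks(_pred_from(gt), gt, worm_schema) == pytest.approx(1.0)

    def test_one_sigma_displacement(self, worm_schema):
        """d = s*k on one visible keypoint gives exp(-1/2)."""
        kps = np.array([[50.0, 50.0, 2.0]] + [[0, 0, 0]] * 4)
        gt = sp.PoseInstance(keypoints=kps)
        gt.scale_s = 20.0
        pred = _pred_from(gt)
        pred.keypoints[0, 0] += 20.0 * 0.1  # d = s * k
        assert oks(pred, gt, worm_schema) == pytest.approx(np.exp(-0.5), abs=1e-9)
        assert oks(pred, gt, worm_schema) == pytest.approx(0.6065, abs=1e-4)

    def test_two_keypoint_mean(self, worm_schema):
        kps = np.array([[50.0, 50.0, 2.0], [80.0, 50.0, 2.0]] + [[0, 0, 0]] * 3)
        gt = sp.PoseInstance(keypoints=kps)
        gt.scale_s = 20.0
        pred = _pred_from(gt)
        pred.keypoints[1, 1] += 2.0  # d = s*k on the second keypoint
        val = oks(pred, gt, worm_schema)
        assert val == pytest.approx((1 + np.exp(-0.5)) / 2, abs=1e-9)
        assert val == pytest.approx(0.8033, abs=1e-4)

    def test_only_labeled_keypoints_count(self, worm_schema):
        rng = np.random.default_rng(1)
        gt = random_pose(rng, worm_schema)
        gt.keypoints[3:, 2] = 0.0
        pred = _pred_from(gt)
        pred.keypoints[3:] += 1e6  # absent keypoints may be arbitrarily wrong
        assert oks(pred, gt, worm_schema) == pytest.approx(1.0)

    def test_joint_translation_invariance(self, worm_schema):
        rng = np.random.default_rng(2)
        gt = random_pose(rng, worm_schema)
        pred = _pred_from(gt, offset=(3.0, -2.0))
        base = oks(pred, gt, worm_schema)
        gt2 = sp.PoseInstance(keypoints=gt.keypoints + [17.0, -9.0, 0.0])
        gt2.scale_s = gt.scale_s
        pred2 = DecodedPose(keypoints=pred.keypoints + [17.0, -9.0], score=0.9, center=(0, 0))
        assert oks(pred2, gt2, worm_schema) == pytest.approx(base, rel=1e-12)

    def test_undefined_without_labeled_keypoints(self, worm_schema):
        gt = sp.PoseInstance(keypoints=np.zeros((5, 3)))
        with pytest.raises(ValueError, match="no labeled"):
            oks(_pred_from(gt), gt, worm_schema)


class TestMatching:
    def test_perfect_predictions_all_tp(self, worm_schema):
        rng = np.random.default_rng(3)
        gts = [random_pose(rng, worm_schema, center=c) for c in [(30, 30), (90, 90)]]
        preds = [_pred_from(g, score=s) for g, s in zip(gts, (0.9, 0.8))]
        res = match_and_score(preds, gts, worm_schema, threshold=0.99)
        assert res["tp"].all() and res["n_fp"] == 0 and res["n_fn"] == 0

    def test_no_predictions_all_fn(self, worm_schema):
        rng = np.random.default_rng(4)
        gts = [random_pose(rng, worm_schema)]
        res = match_and_score([], gts, worm_schema, threshold=0.5)
        assert res["n_fn"] == 1

    def test_two_preds_one_gt_higher_score_wins(self, worm_schema):
        rng = np.random.default_rng(5)
        gt = random_pose(rng, worm_schema)
        good_low = _pred_from(gt, score=0.3)
        worse_high = _pred_from(gt, offset=(1.0, 0.0), score=0.9)
        res = match_and_score([good_low, worse_high], [gt], worm_schema, threshold=0.5)
        assert res["tp"].tolist() == [True, False]  # score order: worse_high first
        assert res["n_fp"] == 1


class TestEvaluate:
    def test_perfect_detector(self, worm_schema):
        rng = np.random.default_rng(6)
        preds, gts = {}, {}
        for i in range(10):
            g = [random_pose(rng, worm_schema, center=(40 + 5 * j, 60)) for j in range(2)]
            gts[i] = g
            preds[i] = [_pred_from(x, score=rng.uniform(0.5, 1), image_id=i) for x in g]
        res = sp.evaluate(preds, gts, worm_schema)
        assert res.ap == res.ap50 == res.ap75 == res.ar == 1.0

    def test_empty_detector(self, worm_schema):
        gts = {0: [random_pose(np.random.default_rng(7), worm_schema)]}
        res = sp.evaluate({0: []}, gts, worm_schema)
        assert res.ap == res.ap50 == res.ar == 0.0

    def test_one_tp_one_higher_scored_fp_gives_half(self, worm_schema):
        """PR curve (0, 1/2) under 101-point interpolation -> AP = 0.5."""
        rng = np.random.default_rng(8)
        gt = random_pose(rng, worm_schema)
        fp = _pred_from(gt, offset=(500.0, 0.0), score=0.9)
        tp = _pred_from(gt, score=0.5)
        res = sp.evaluate({0: [fp, tp]}, {0: [gt]}, worm_schema, thresholds=[0.5])
        assert res.ap == pytest.approx(0.5)

    def test_zero_gt_rejected(self, worm_schema):
        with pytest.raises((ValueError, TypeError)):
            sp.evaluate({0: []}, {0: []}, worm_schema)

    def test_adding_tp_never_lowers_ar(self, worm_schema):
        rng = np.random.default_rng(9)
        gts = {0: [random_pose(rng, worm_schema, center=c) for c in [(30, 40), (90, 80)]]}
        p1 = [_pred_from(gts[0][0], score=0.8, image_id=0)]
        r1 = sp.evaluate({0: p1}, gts, worm_schema)
        p2 = p1 + [_pred_from(gts[0][1], score=0.4, image_id=0)]
        r2 = sp.evaluate({0: p2}, gts, worm_schema)
        assert r2.ar >= r1.ar


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence


def _oracle_evaluate(preds_by_img, gts_by_img, schema, thresholds, max_det=30):
    """Independent loop-based COCO-style evaluator."""

    def oks_bf(pred_kps, gt):
        num = den = 0.0
        for i in range(len(gt.keypoints)):
            if gt.keypoints[i, 2] > 0:
                dx = pred_kps[i, 0] - gt.keypoints[i, 0]
                dy = pred_kps[i, 1] - gt.keypoints[i, 1]
                kk = schema.keypoints[i].oks_k
                num += np.exp(-(dx * dx + dy * dy) / (2 * gt.scale_s**2 * kk * kk))
                den += 1
        return num / den

    aps, recalls = [], []
    for thr in thresholds:
        records = []  # (score, is_tp)
        total_gt = 0
        for img in sorted(gts_by_img):
            gts = [g for g in gts_by_img[img] if (g.keypoints[:, 2] > 0).any()]
            total_gt += len(gts)
            preds = sorted(preds_by_img.get(img, []), key=lambda p: -p.score)[:max_det]
            taken = set()
            for p in preds:
                best, best_val = None, thr
                for j, g in enumerate(gts):
                    if j in taken:
                        continue
                    val = oks_bf(p.keypoints, g)
                    if val >= best_val:
                        best, best_val = j, val
                if best is None:
                    records.append((p.score, False))
                else:
                    taken.add(best)
                    records.append((p.score, True))
        records.sort(key=lambda r: -r[0])
        # brute-force 101-point AP: for each grid recall, the best
        # precision among prefixes achieving at least that recall
        ap_sum = 0.0
        for r_target in np.linspace(0, 1, 101):
            best_p = 0.0
            tp = fp = 0
            for score, is_tp in records:
                tp += is_tp
                fp += not is_tp
                if total_gt and tp / total_gt >= r_target - 1e-12:
                    best_p = max(best_p, tp / (tp + fp))
            ap_sum += best_p
        aps.append(ap_sum / 101)
        n_tp = sum(1 for _, t in records if t)
        recalls.append(n_tp / total_gt if total_gt else 0.0)
    return float(np.mean(aps)), float(np.mean(recalls)), aps


def test_matches_brute_force_oracle_on_random_fixtures(worm_schema):
    """50 randomized detection/GT sets: AP and AR agree with the
    independent loop evaluator to 1e-6."""
    rng = np.random.default_rng(42)
    for trial in range(50):
        n_img = rng.integers(1, 4)
        gts, preds = {}, {}
        for img in range(n_img):
            k_gt = rng.integers(1, 4)
            gts[img] = [
                random_pose(rng, worm_schema, center=rng.uniform(30, 100, 2))
                for _ in range(k_gt)
            ]
            plist = []
            for g in gts[img]:
                if rng.uniform() < 0.85:  # noisy detection of this GT
                    plist.append(
                        _pred_from(g, offset=rng.normal(0, 3, 2),
                                   score=rng.uniform(0.1, 1.0), image_id=img)
                    )
            for _ in range(rng.integers(0, 3)):  # spurious detections
                plist.append(
                    DecodedPose(
                        keypoints=rng.uniform(0, 128, (5, 2)),
                        score=rng.uniform(0.1, 1.0), center=(0, 0), image_id=img,
                    )
                )
            preds[img] = plist
        thr = [0.5, 0.75, 0.9]
        res = sp.evaluate(preds, gts, worm_schema, thresholds=thr)
        ap_bf, ar_bf, aps_bf = _oracle_evaluate(preds, gts, worm_schema, thr)
        assert res.ap == pytest.approx(ap_bf, abs=1e-6), trial
        assert res.ar == pytest.approx(ar_bf, abs=1e-6), trial
        for (t, a), b in zip(res.per_threshold, aps_bf):
            assert a == pytest.approx(b, abs=1e-6), (trial, t)
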