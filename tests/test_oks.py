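"""OKS scoring against closed forms, enumeration oracles and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from calfface import CALF_FACE_10, classify_at_threshold, compute_oks, evaluate, f1_score
from calfface.oks import DEFAULT_THRESHOLDS, OksRecord, UndefinedOksError
from calfface.schema import KeypointFrame


def frame_from_array(xy, vis=None, bbox=(0.0, 0.0, 100.0, 100.0), size=(10000, 10000)):
    labels = list(CALF_FACE_10)
    vis = vis if vis is not None else [2] * len(labels)
    return KeypointFrame(
        frame_index=0,
        points={l: (float(x), float(y)) for l, (x, y) in zip(labels, xy)},
        visibility=dict(zip(labels, vis)),
        image_size=size,
        bbox=bbox,
    )


def random_frame(rng, lo=100.0, hi=900.0):
    xy = rng.uniform(lo, hi, size=(10, 2))
    return frame_from_array(xy)


class TestComputeOks:
    def test_identical_frames_score_one(self):
        rng = np.random.default_rng(0)
        truth = random_frame(rng)
        rec = compute_oks(truth, truth, schema=CALF_FACE_10)
        assert rec.oks == pytest.approx(1.0)
        assert rec.n_visible == 10

    @pytest.mark.parametrize("k,area,d2_factor", [(0.05, 2500.0, 2.0), (0.1, 900.0, 0.5)])
    def test_single_visible_keypoint_matches_closed_form(self, k, area, d2_factor):
        # displacement chosen so d^2 = factor * 2 s^2 k^2 -> oks = exp(-factor)
        d = math.sqrt(d2_factor * 2.0 * area * k * k)
        xy = np.full((10, 2), 50.0)
        truth = frame_from_array(xy, vis=[2] + [0] * 9)
        pred_xy = xy.copy()
        pred_xy[0, 0] += d
        pred = frame_from_array(pred_xy)
        rec = compute_oks(pred, truth, kappas=k, area=area, schema=CALF_FACE_10)
        assert rec.oks == pytest.approx(math.exp(-d2_factor), abs=1e-9)

    def test_perfect_plus_far_keypoint_averages_to_half(self):
        xy = np.full((10, 2), 500.0)
        truth = frame_from_array(xy, vis=[2, 2] + [0] * 8)
        pred_xy = xy.copy()
        pred_xy[1] = (1e7, 1e7)
        pred = frame_from_array(pred_xy)
        rec = compute_oks(pred, truth, schema=CALF_FACE_10)
        assert rec.oks == pytest.approx(0.5, abs=1e-12)

    def test_invisible_truth_keypoints_excluded(self):
        rng = np.random.default_rng(1)
        truth_xy = rng.uniform(100, 900, (10, 2))
        truth = frame_from_array(truth_xy, vis=[2] * 5 + [0] * 5)
        pred_xy = truth_xy.copy()
        pred_xy[5:] += 1e6  # garbage where truth is unlabeled
        rec = compute_oks(frame_from_array(pred_xy), truth, schema=CALF_FACE_10)
        assert rec.oks == pytest.approx(1.0)
        assert rec.n_visible == 5

    def test_all_invisible_raises(self):
        truth = frame_from_array(np.zeros((10, 2)), vis=[0] * 10)
        with pytest.raises(UndefinedOksError):
            compute_oks(truth, truth, schema=CALF_FACE_10)

    def test_nonpositive_area_rejected(self):
        rng = np.random.default_rng(2)
        f = random_frame(rng)
        with pytest.raises(ValueError, match="area"):
            compute_oks(f, f, area=0.0, schema=CALF_FACE_10)

    @given(st.integers(0, 500))
    def test_translation_and_scale_invariance(self, i):
        rng = np.random.default_rng(i)
        truth = random_frame(rng)
        pred_xy = np.array([truth.points[l] for l in CALF_FACE_10]) + rng.normal(
            0, 5, (10, 2)
        )
        pred = frame_from_array(pred_xy)
        base = compute_oks(pred, truth, schema=CALF_FACE_10).oks

        shift = rng.uniform(-50, 50, 2)
        t_truth = frame_from_array(
            np.array([truth.points[l] for l in CALF_FACE_10]) + shift
        )
        t_pred = frame_from_array(pred_xy + shift)
        assert compute_oks(t_pred, t_truth, schema=CALF_FACE_10).oks == pytest.approx(
            base, abs=1e-12
        )

        c = rng.uniform(0.5, 3.0)
        s_truth = frame_from_array(
            np.array([truth.points[l] for l in CALF_FACE_10]) * c,
            bbox=(0.0, 0.0, 100.0 * c, 100.0 * c),
        )
        s_pred = frame_from_array(pred_xy * c)
        assert compute_oks(s_pred, s_truth, schema=CALF_FACE_10).oks == pytest.approx(
            base, rel=1e-9
        )

    def test_monotone_decrease_in_single_displacement(self):
        xy = np.full((10, 2), 500.0) + np.arange(20).reshape(10, 2) * 10
        truth = frame_from_array(xy)
        last = 1.0 + 1e-15
        for d in (1.0, 5.0, 20.0, 80.0):
            pred_xy = xy.copy()
            pred_xy[3, 1] += d
            score = compute_oks(frame_from_array(pred_xy), truth, schema=CALF_FACE_10).oks
            assert score < last
            last = score


def records(scores):
    return [OksRecord(str(i), s, {}, 1.0, 1) for i, s in enumerate(scores)]


class TestClassifyAtThreshold:
    def test_enumeration_example(self):
        m = classify_at_threshold(records([0.9, 0.8, 0.6]), 0.75)
        assert (m.tp, m.fp) == (2, 1)
        assert m.precision == pytest.approx(2 / 3)

    def test_zero_threshold_all_true_positive(self):
        m = classify_at_threshold(records([0.1, 0.5]), 0.0)
        assert m.fp == 0 and m.precision == 1.0

    def test_score_equal_to_threshold_is_true_positive(self):
        m = classify_at_threshold(records([0.75]), 0.75)
        assert m.tp == 1

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_at_threshold([], 0.5)

    def test_precision_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        recs = records(rng.uniform(0, 1, 50))
        precisions = [classify_at_threshold(recs, t).precision for t in DEFAULT_THRESHOLDS]
        assert all(a >= b for a, b in zip(precisions, precisions[1:]))


class TestEvaluate:
    def test_perfect_pairs_give_unit_metrics(self):
        rng = np.random.default_rng(4)
        pairs = [(f, f) for f in (random_frame(rng) for _ in range(5))]
        rep = evaluate(pairs, schema=CALF_FACE_10)
        assert rep.ap_mean == rep.ar_mean == rep.f1 == 1.0
        assert rep.ap_at[0.75] == 1.0 and rep.ar_at[0.95] == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        pairs = []
        for _ in range(40):
            truth = random_frame(rng)
            xy = np.array([truth.points[l] for l in CALF_FACE_10])
            pairs.append((frame_from_array(xy + rng.normal(0, 4, (10, 2))), truth))
        rep = evaluate(pairs, schema=CALF_FACE_10)
        scores = [
            compute_oks(p, t, schema=CALF_FACE_10).oks for p, t in pairs
        ]
        for m in rep.per_threshold:
            assert m.tp == sum(1 for s in scores if s >= m.threshold)
        assert rep.ap_mean == pytest.approx(
            np.mean([m.precision for m in rep.per_threshold])
        )

    def test_extra_labels_in_frames_ignored(self):
        rng = np.random.default_rng(6)
        truth = random_frame(rng)
        pred = frame_from_array(np.array([truth.points[l] for l in CALF_FACE_10]))
        for f in (pred, truth):
            f.points["extra_landmark"] = (0.0, 0.0)
            f.visibility["extra_landmark"] = 2
        rec = compute_oks(pred, truth, schema=CALF_FACE_10)
        assert rec.n_visible == 10 and rec.oks == pytest.approx(1.0)

    def test_precision_tracks_designed_exceedance_rate(self):
        # displacements drawn so that a known fraction of instances score
        # above the 0.75 cut; measured precision agrees to binomial error
        rng = np.random.default_rng(7)
        k, area, n = 0.05, 2500.0, 1000
        d_pass = math.sqrt(2 * area * k * k * (-math.log(0.80)))  # oks ~ 0.8/kp
        d_fail = math.sqrt(2 * area * k * k * (-math.log(0.50)))
        bbox = (0.0, 0.0, 50.0, 50.0)  # bbox area equals the area used for d
        pairs = []
        for i in range(n):
            xy = np.random.default_rng(1000 + i).uniform(2000.0, 8000.0, (10, 2))
            truth = frame_from_array(xy, bbox=bbox)
            d = d_pass if rng.random() < 0.8 else d_fail
            direc = rng.normal(0, 1, (10, 2))
            direc /= np.linalg.norm(direc, axis=1, keepdims=True)
            pairs.append((frame_from_array(xy + d * direc), truth))
        rep = evaluate(pairs, kappas=k, schema=CALF_FACE_10)
        assert rep.ap_at[0.75] == pytest.approx(0.8, abs=3 * math.sqrt(0.8 * 0.2 / n))


class TestF1:
    @pytest.mark.parametrize(
        "p,r,expect",
        [(0.958, 0.958, 0.958), (1.0, 0.0, 0.0), (0.5, 1.0, 2 / 3), (0.0, 0.0, 0.0)],
    )
    def test_harmonic_mean(self, p, r, expect):
        assert f1_score(p, r) == pytest.approx(expect, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_score(1.2, 0.5)
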