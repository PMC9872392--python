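import itertools

import numpy as np
import pytest

from conftest import make_track
from pftrack import metrics
from pftrack.imgio import ImageStack
from pftrack.tracks import Spot


def brute_force_max_matching(gt, det, radius):
    """Oracle: maximum number of one-to-one pairs within the gate, and the
    minimum total squared distance among maximum matchings."""
    best_n, best_cost = 0, np.inf
    n, m = len(gt), len(det)
    k = min(n, m)
    for det_subset in itertools.permutations(range(m), k):
        for gt_subset in itertools.combinations(range(n), k):
            pairs = [(i, j) for i, j in zip(gt_subset, det_subset)
                     if np.linalg.norm(np.subtract(gt[i], det[j])) <= radius]
            cost = sum(np.sum(np.subtract(gt[i], det[j]) ** 2) for i, j in pairs)
            if len(pairs) > best_n or (len(pairs) == best_n and cost < best_cost):
                best_n, best_cost = len(pairs), cost
    return best_n, best_cost


class TestSNR:
    def test_equal_means_give_zero(self):
        frame = np.array([[5.0, 5.0], [4.0, 6.0]])
        res = metrics.snr(frame, np.array([[1, 1], [0, 0]], bool),
                          np.array([[0, 0], [1, 1]], bool))
        assert res.snr == 0.0

    def test_hand_computed_value(self):
        # FG all 5; BG = {0, 2, 0, 2}: mean 1, population std 1 -> snr = 4
        frame = np.array([[5.0, 5.0, 0.0], [2.0, 0.0, 2.0]])
        fg = np.zeros_like(frame, bool)
        fg[0, :2] = True
        bg = ~fg
        bg[0, :2] = False
        res = metrics.snr(frame, fg, bg)
        assert res.snr == pytest.approx(4.0)
        assert res.bg_std == pytest.approx(1.0)

    def test_constant_background_rejected(self):
        frame = np.array([[5.0, 1.0], [1.0, 1.0]])
        fg = np.array([[1, 0], [0, 0]], bool)
        with pytest.raises(ValueError, match="constant"):
            metrics.snr(frame, fg, ~fg)

    def test_overlapping_masks_rejected(self):
        frame = np.ones((2, 2))
        m = np.ones((2, 2), bool)
        with pytest.raises(ValueError):
            metrics.snr(frame, m, m)

    def test_shift_and_gain_invariance(self):
        # (fg - bg)/std is unchanged by adding a constant, and a multiplicative
        # gain cancels between numerator and denominator
        rng = np.random.default_rng(5)
        frame = rng.random((20, 20)) * 50
        fg = np.zeros((20, 20), bool)
        fg[5:8, 5:8] = True
        bg = ~fg
        base = metrics.snr(frame, fg, bg).snr
        assert metrics.snr(frame + 17.3, fg, bg).snr == pytest.approx(base)
        assert metrics.snr(frame * 3.7, fg, bg).snr == pytest.approx(base)


class TestMatchDetections:
    @staticmethod
    def _spots(points):
        return [Spot(frame=0, x_um=float(x), y_um=float(y)) for x, y in points]

    def test_identical_sets(self):
        pts = [(0, 0), (10, 10), (30, 5)]
        res = metrics.match_detections(self._spots(pts), self._spots(pts), 8.0)
        assert (res.tpr, res.fpr, res.fnr) == (1.0, 0.0, 0.0)

    def test_partial_detection(self):
        gt = self._spots([(0, 0), (20, 0), (40, 0)])
        det = self._spots([(0, 0), (20, 0)])
        res = metrics.match_detections(gt, det, 8.0)
        assert (res.tp, res.fn, res.fp) == (2, 1, 0)
        assert res.tpr == pytest.approx(2 / 3)

    def test_one_to_one_constraint(self):
        gt = self._spots([(0, 0)])
        det = self._spots([(1, 0), (0, 1)])
        res = metrics.match_detections(gt, det, 8.0)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            gt = [tuple(p) for p in rng.random((rng.integers(0, 5), 2)) * 30]
            det = [tuple(p) for p in rng.random((rng.integers(0, 5), 2)) * 30]
            res = metrics.match_detections(self._spots(gt), self._spots(det), 10.0)
            oracle_n, _ = brute_force_max_matching(gt, det, 10.0)
            assert res.tp == oracle_n, (gt, det)

    def test_rates_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            gt = self._spots(rng.random((int(rng.integers(1, 6)), 2)) * 20)
            det = self._spots(rng.random((int(rng.integers(0, 6)), 2)) * 20)
            res = metrics.match_detections(gt, det, 5.0)
            assert res.tpr + res.fnr == pytest.approx(1.0)
            assert 0.0 <= res.fpr <= 1.0


class TestMotaMotp:
    def test_perfect_tracking(self):
        gt = [make_track(0, range(3), [0] * 3, [0] * 3),
              make_track(1, range(3), [10] * 3, [0] * 3)]
        res = metrics.mota_motp(gt, gt, 8.0)
        assert res.mota == 1.0
        assert res.motp_score(8.0) == 1.0

    def test_hand_counted_toy_scenario(self):
        # 2 objects x 3 frames = 6 gt spots; object B is missed in frame 1 and
        # re-found by a NEW estimate id in frame 2 -> 1 miss + 1 id switch
        gt = [make_track(0, range(3), [0] * 3, [0] * 3),
              make_track(1, range(3), [10] * 3, [0] * 3)]
        est = [make_track(0, range(3), [0] * 3, [0] * 3),
               make_track(1, [0], [10], [0]),
               make_track(2, [2], [10], [0])]
        res = metrics.mota_motp(gt, est, 4.0)
        assert (res.misses, res.false_positives, res.id_switches) == (1, 0, 1)
        assert res.mota == pytest.approx(1 - 2 / 6)

    def test_match_at_exact_radius_gives_zero_score(self):
        gt = [make_track(0, [0], [0.0], [0.0])]
        est = [make_track(0, [0], [4.0], [0.0])]
        res = metrics.mota_motp(gt, est, 4.0)
        assert res.misses == 0
        assert res.motp_score(4.0) == 0.0

    def test_removing_one_spot_costs_one_over_gt_count(self):
        gt = [make_track(0, range(4), [0] * 4, [0] * 4),
              make_track(1, range(4), [20] * 4, [0] * 4)]
        est_full = [make_track(0, range(4), [0] * 4, [0] * 4),
                    make_track(1, range(4), [20] * 4, [0] * 4)]
        est_miss = [make_track(0, range(4), [0] * 4, [0] * 4),
                    make_track(1, [0, 1, 2], [20] * 3, [0] * 3)]
        full = metrics.mota_motp(gt, est_full, 8.0).mota
        miss = metrics.mota_motp(gt, est_miss, 8.0).mota
        assert full - miss == pytest.approx(1 / 8)

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            metrics.mota_motp([], [make_track(0, [0], [0], [0])], 8.0)


class TestIntensityDecay:
    def test_constant_stack_is_flat(self):
        labels = np.zeros((4, 10, 10), dtype=int)
        labels[:, 2:5, 2:5] = 1
        stack = ImageStack(np.full((4, 10, 10), 60.0), 1.0, 1.0)
        np.testing.assert_allclose(metrics.intensity_decay(stack, labels), 1.0)

    def test_exponential_half_life(self):
        t = np.arange(11.0)
        data = np.ones((11, 8, 8)) * (100.0 * np.exp(-t / (10.0 / np.log(2))))[:, None, None]
        labels = np.ones((11, 8, 8), dtype=int)
        r = metrics.intensity_decay(ImageStack(data, 1.0, 1.0), labels)
        assert r[0] == pytest.approx(1.0)
        assert r[-1] == pytest.approx(0.5, rel=1e-6)

    def test_zero_initial_intensity_rejected(self):
        labels = np.ones((2, 4, 4), dtype=int)
        with pytest.raises(ValueError):
            metrics.intensity_decay(ImageStack(np.zeros((2, 4, 4)), 1.0, 1.0), labels)


class TestTrackDurations:
    def test_full_video_track_is_100_percent(self):
        # 11 frames at 20 s: track spans 10 intervals = 200 s of a 220 s video?
        # no - duration counts last-first frames; use video = span for 100%
        tr = make_track(0, range(11), range(11), range(11))
        stats = metrics.track_duration_stats([tr], video_duration_s=200.0,
                                             frame_interval_s=20.0)
        assert stats.percent_of_video[0] == pytest.approx(100.0)

    def test_300s_of_6h_video(self):
        tr = make_track(0, [0, 15], [0, 1], [0, 1])
        stats = metrics.track_duration_stats([tr], video_duration_s=21600.0,
                                             frame_interval_s=20.0)
        assert stats.percent_of_video[0] == pytest.approx(1.389, abs=1e-3)

    def test_empty_track_list(self):
        stats = metrics.track_duration_stats([], 100.0, 1.0)
        assert stats.n_tracks == 0
        assert stats.mean_s == 0.0

    def test_mann_whitney_separated_samples(self):
        u, p = metrics.mann_whitney([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert p < 0.01


class TestShiftBenchmark:
    class OnesModel:
        class config:
            input_px = 56
            norm_span_floor = 0.0

        def predict(self, x):
            return np.ones(x.shape[:3], dtype=np.float32)

    def test_all_ones_prediction_vs_half_mask(self):
        from pftrack.simulate import TrainingPair

        mask = np.zeros((56, 56), np.uint8)
        mask[:28] = 1
        pairs = [TrainingPair(np.full((56, 56), 0.5, np.float32), mask)]
        table = metrics.intensity_shift_benchmark(self.OnesModel(), pairs, shifts=[0])
        assert table.iloc[0]["iou"] == pytest.approx(0.5)
        assert table.iloc[0]["pixel_difference"] == pytest.approx(0.5)

    def test_one_row_per_shift(self):
        from pftrack.simulate import TrainingPair

        pairs = [TrainingPair(np.random.default_rng(0).random((56, 56)).astype(np.float32),
                              np.zeros((56, 56), np.uint8))]
        shifts = np.linspace(0, 232, 32)
        table = metrics.intensity_shift_benchmark(self.OnesModel(), pairs, shifts)
        assert len(table) == 32
        np.testing.assert_allclose(table["shift"], shifts)


class TestBorderDecay:
    def test_distance_transform_profile_increases_inward(self):
        from scipy.ndimage import distance_transform_edt

        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        prob = distance_transform_edt(mask)
        prob = prob / prob.max()
        res = metrics.border_decay_profile(prob, mask)
        inside = res.distance_px > 0
        assert (np.diff(res.mean_probability[inside]) > 0).all()
        assert res.spearman_inside > 0.99

    def test_uniform_map_is_flat(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        res = metrics.border_decay_profile(np.full((20, 20), 0.4), mask)
        np.testing.assert_allclose(res.mean_probability, 0.4)
        assert res.spearman_inside == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            metrics.border_decay_profile(np.ones((5, 5)), np.zeros((5, 5), bool))
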