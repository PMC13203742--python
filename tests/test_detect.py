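import numpy as np
import pytest

from astrocal import DetectorConfig, FrameSequence, fit_gmm, run_detection
from astrocal.detect import (
    Segment,
    bright_fraction,
    build_segments,
    compose_event_mask,
    effective_duration_threshold,
    filter_components,
    frame_stats,
    instantaneous_mask,
    jaccard,
    mask_snr,
    segment_mask,
    temporal_mask,
    update_count_matrix,
    update_estimation_period,
    update_global_threshold,
    update_local_threshold,
    window_transform,
)


class TestFrameStats:
    def test_constant(self):
        s = frame_stats(np.full((4, 4), 9.0))
        assert s.mu == 9.0 and s.sigma == 0.0

    def test_hand_computed(self):
        s = frame_stats(np.array([[0, 0], [10, 10]], dtype=float))
        assert s.mu == 5.0 and s.sigma == 5.0  # population std

    def test_matches_two_pass_oracle(self, rng):
        f = rng.uniform(0, 1000, size=(16, 16))
        s = frame_stats(f)
        mu = f.sum() / f.size
        var = ((f - mu) ** 2).sum() / f.size
        assert s.mu == pytest.approx(mu)
        assert s.sigma == pytest.approx(np.sqrt(var))


class TestInstantaneousMask:
    def test_constant_frame_empty(self):
        f = np.full((8, 8), 5.0)
        assert not instantaneous_mask(f, frame_stats(f), 2.0).any()

    def test_small_outlier_below_threshold(self):
        f = np.array([[0, 0], [0, 100.0]])
        # mu=25, sigma~43.3 -> threshold ~111.6: even the bright pixel is off
        assert not instantaneous_mask(f, frame_stats(f), 2.0).any()

    def test_strong_outlier_detected(self):
        f = np.zeros(100)
        f[-1] = 1000.0
        f = f.reshape(10, 10)
        m = instantaneous_mask(f, frame_stats(f), 2.0)
        assert m[-1, -1] and m.sum() == 1

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            f = rng.uniform(0, 100, size=(16, 16))
            s = frame_stats(f)
            m = instantaneous_mask(f, s, 1.5)
            np.testing.assert_array_equal(m, f > f.mean() + 1.5 * f.std())


class TestCountMatrix:
    def test_streak_counting(self):
        C = np.zeros((2, 2), dtype=int)
        on = np.ones((2, 2), dtype=bool)
        for _ in range(5):
            C = update_count_matrix(C, on)
        assert (C == 5).all()

    def test_reset_on_gap(self):
        C = np.full((2, 2), 4)
        C = update_count_matrix(C, np.zeros((2, 2), dtype=bool))
        assert (C == 0).all()

    def test_alternating_caps_at_one(self):
        C = np.zeros((1, 1), dtype=int)
        for i in range(6):
            C = update_count_matrix(C, np.full((1, 1), i % 2 == 0))
            assert C.max() <= 1


class TestDurationThreshold:
    @pytest.mark.parametrize("theta_l,expect", [(0.5, 5), (0.2, 2), (0.34, 3)])
    def test_mapping(self, theta_l, expect):
        assert effective_duration_threshold(theta_l, 10) == expect

    def test_temporal_mask_inclusive(self):
        C = np.array([[5, 4], [6, 0]])
        m = temporal_mask(C, 5)
        np.testing.assert_array_equal(m, [[True, False], [True, False]])

    def test_threshold_one(self):
        C = np.array([[0, 1], [2, 0]])
        np.testing.assert_array_equal(temporal_mask(C, 1), C >= 1)


class TestGmm:
    def test_constant_frame_degenerates(self):
        fit = fit_gmm(np.full((32, 32), 77, dtype=np.uint16))
        assert fit.K == 1
        assert fit.means[0] == 77
        assert fit.weights[0] == 1.0

    def test_two_distinct_values(self):
        f = np.zeros((8, 8), dtype=np.uint16)
        f[:, 4:] = 100
        fit = fit_gmm(f)
        assert fit.K == 2
        np.testing.assert_allclose(fit.means, [0, 100], atol=1e-6)

    def test_weights_sum_to_one(self, rng):
        f = rng.integers(0, 3000, size=(64, 64)).astype(np.uint16)
        fit = fit_gmm(f)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(fit.means) >= 0).all()

    def test_two_component_recovery(self):
        rng = np.random.default_rng(42)
        n = 65536
        vals = np.where(
            rng.uniform(size=n) < 0.7,
            rng.normal(100, 10, size=n),
            rng.normal(1000, 20, size=n),
        )
        frame = np.clip(np.round(vals), 0, 65535).astype(np.uint16).reshape(256, 256)
        fit = fit_gmm(frame)
        assert fit.K == 2
        assert fit.means[0] == pytest.approx(100, rel=0.02)
        assert fit.means[1] == pytest.approx(1000, rel=0.02)
        assert fit.weights[0] == pytest.approx(0.7, abs=0.02)

    def test_bic_selects_true_k_on_separated_mixtures(self):
        hits = 0
        trials = 20
        for s in range(trials):
            rng = np.random.default_rng(1000 + s)
            n = 16384
            comp = rng.uniform(size=n)
            vals = np.where(comp < 0.6, rng.normal(200, 15, n), rng.normal(900, 25, n))
            frame = np.clip(np.round(vals), 0, 65535).astype(np.uint16).reshape(128, 128)
            if fit_gmm(frame).K == 2:
                hits += 1
        assert hits >= 0.95 * trials

    def test_matches_sklearn_oracle(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(7)
        n = 30000
        vals = np.where(
            rng.uniform(size=n) < 0.5, rng.normal(300, 20, n), rng.normal(1500, 40, n)
        )
        ints = np.clip(np.round(vals), 0, 65535).astype(np.uint16)
        fit = fit_gmm(ints.reshape(150, 200))
        gm = sklearn.GaussianMixture(
            n_components=2, init_params="kmeans", tol=1e-3, max_iter=100, random_state=0
        ).fit(ints.reshape(-1, 1).astype(float))
        ref_means = np.sort(gm.means_.ravel())
        np.testing.assert_allclose(fit.means, ref_means, rtol=0.01)


class TestSegments:
    def test_signal_thresholds(self):
        fit = fit_gmm(np.zeros((4, 4), dtype=np.uint16))
        fit.K = 2
        fit.means = np.array([10.0, 200.0])
        fit.stds = np.array([2.0, 10.0])
        fit.weights = np.array([0.8, 0.2])
        segs = build_segments(fit, 29, (0.0, 400.0))
        sig = segs[-1]
        assert sig.is_signal
        assert sig.tau_g == max(2.0, 0.5 * 10.0) == 5.0
        assert sig.tau_a == 29
        assert sig.H == 400.0  # extends to gray max

    def test_background_thresholds(self):
        fit = fit_gmm(np.zeros((4, 4), dtype=np.uint16))
        fit.K = 2
        fit.means = np.array([10.0, 500.0])
        fit.stds = np.array([0.5, 20.0])
        fit.weights = np.array([0.9, 0.1])
        segs = build_segments(fit, 29, (0.0, 600.0))
        bg = segs[0]
        assert not bg.is_signal
        assert bg.tau_g == 2.0  # floor: max(2, 2*0.5)
        assert bg.tau_a == 290
        assert bg.L == 9.0 and bg.H == 11.0

    def test_truncation_to_gray_range(self):
        fit = fit_gmm(np.zeros((4, 4), dtype=np.uint16))
        fit.K = 1
        fit.means = np.array([60000.0])
        fit.stds = np.array([5000.0])
        fit.weights = np.array([1.0])
        segs = build_segments(fit, 29, (0.0, 65535.0))
        assert segs[0].H == 65535.0
        assert segs[0].L == 50000.0

    def test_exactly_one_signal_segment(self, rng):
        f = rng.integers(0, 3000, size=(64, 64)).astype(np.uint16)
        segs = build_segments(fit_gmm(f), 29, (float(f.min()), float(f.max())))
        assert sum(s.is_signal for s in segs) == 1


class TestSegmentMask:
    def test_inclusive_bounds(self):
        seg = Segment(L=10, H=20, tau_g=2, tau_a=29, beta=0.5, is_signal=True)
        f = np.array([[9, 10], [20, 21]], dtype=float)
        np.testing.assert_array_equal(
            segment_mask(f, seg), [[False, True], [True, False]]
        )

    def test_matches_brute_force(self, rng):
        seg = Segment(L=100, H=900, tau_g=2, tau_a=29, beta=0.5, is_signal=True)
        f = rng.uniform(0, 1000, size=(16, 16))
        np.testing.assert_array_equal(segment_mask(f, seg), (f >= 100) & (f <= 900))


class TestFilterComponents:
    def _seg(self, tau_a, L=0.0, tau_g=2.0):
        return Segment(L=L, H=1e9, tau_g=tau_g, tau_a=tau_a, beta=0.5, is_signal=True)

    def test_area_rule(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:8, 2:7] = True  # 30 px
        frame = np.where(mask, 1000.0, 0.0)
        out = filter_components(mask, self._seg(29), frame)
        np.testing.assert_array_equal(out, mask)
        mask28 = np.zeros((16, 16), dtype=bool)
        mask28[2:9, 2:6] = True  # 28 px
        out = filter_components(mask28, self._seg(29), np.where(mask28, 1000.0, 0.0))
        assert not out.any()

    def test_intensity_rule(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2:8, 2:8] = True
        dim = np.where(mask, 1.0, 0.0)  # mean 1 < L + tau_g = 2
        assert not filter_components(mask, self._seg(1), dim).any()

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2] = mask[3, 3] = True
        frame = np.where(mask, 100.0, 0.0)
        out = filter_components(mask, self._seg(2), frame)
        assert out.sum() == 2  # 8-connectivity joins them; area 2 >= tau_a 2

    def test_compose_subtracts_background_structures(self):
        sig = np.zeros((8, 8), dtype=bool)
        sig[2:6, 2:6] = True
        bg = np.zeros((8, 8), dtype=bool)
        bg[4:8, 4:8] = True
        out = compose_event_mask(sig, bg)
        assert not out[4:6, 4:6].any()
        assert out[2:4, 2:4].all()
        assert compose_event_mask(np.zeros_like(sig), bg).sum() == 0


class TestAdaptiveUpdates:
    def test_bright_fraction(self):
        assert bright_fraction(np.zeros((4, 4), dtype=bool)) == 0.0
        assert bright_fraction(np.ones((4, 4), dtype=bool)) == 1.0
        m = np.zeros((256, 256), dtype=bool)
        m.ravel()[:64] = True
        assert bright_fraction(m) == pytest.approx(64 / 65536)

    def test_theta_g_relaxes_when_stable(self):
        # stable prevalence lowers the threshold to recover weak signal
        assert update_global_threshold(2.0, 0.0005, (0.5, 6.0)) == pytest.approx(1.6)

    def test_theta_g_tightens_on_fluctuation(self):
        assert update_global_threshold(2.0, 0.01, (0.5, 6.0)) == pytest.approx(2.4)
        assert update_global_threshold(2.0, -0.01, (0.5, 6.0)) == pytest.approx(2.4)

    def test_theta_g_clamped(self):
        assert update_global_threshold(5.8, 0.01, (0.5, 6.0)) == 6.0
        assert update_global_threshold(0.55, 0.0, (0.5, 6.0)) == 0.5

    def test_jaccard(self):
        a = np.zeros((10, 10), dtype=bool)
        a[:5] = True
        assert jaccard(a, a) == pytest.approx(1.0, abs=1e-6)
        b = ~a
        assert jaccard(a, b) == 0.0
        empty = np.zeros_like(a)
        assert jaccard(empty, empty) == 0.0

    @pytest.mark.parametrize(
        "theta_l,J,expect",
        [(0.5, 0.9, 0.5), (0.3, 0.5, 0.27), (0.21, 0.1, 0.2), (0.3, 0.8, 0.39)],
    )
    def test_theta_l_update(self, theta_l, J, expect):
        assert update_local_threshold(theta_l, J) == pytest.approx(expect)

    def test_mask_snr(self):
        f = np.zeros((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:2] = True
        f[mask] = 100.0
        f[~mask] = np.tile([0, 100], 40)  # outside std 50
        assert mask_snr(f, mask) == pytest.approx(2.0)

    def test_mask_snr_degenerate(self):
        f = np.ones((4, 4))
        assert mask_snr(f, np.zeros((4, 4), dtype=bool)) == 1.0
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = True
        assert mask_snr(f, m) == 1e6  # constant outside

    @pytest.mark.parametrize("snr,expect", [(2.0, 7), (1000.0, 100), (0.5, 7)])
    def test_estimation_period(self, snr, expect):
        assert update_estimation_period(snr) == expect


class TestWindowTransform:
    def test_full_scale(self):
        f = np.full((4, 4), 3315, dtype=np.uint16)
        out = window_transform(f, np.ones((4, 4), dtype=bool), 13)
        assert (out == 255).all()

    def test_background_zeroed(self):
        f = np.full((4, 4), 3000, dtype=np.uint16)
        out = window_transform(f, np.zeros((4, 4), dtype=bool), 13)
        assert (out == 0).all()

    def test_midpoint_rounding(self):
        f = np.full((1, 1), 1658, dtype=np.uint16)
        out = window_transform(f, np.ones((1, 1), dtype=bool), 13)
        assert out[0, 0] == 128

    def test_monotone_within_mask(self, rng):
        f = rng.integers(0, 3315, size=(16, 16)).astype(np.uint16)
        mask = np.ones((16, 16), dtype=bool)
        out = window_transform(f, mask, 13)
        order = np.argsort(f.ravel(), kind="stable")
        assert (np.diff(out.ravel()[order].astype(int)) >= 0).all()


class TestRunDetection:
    def test_constant_video_empty_output(self):
        seq = FrameSequence(
            np.full((30, 32, 32), 500, dtype=np.uint16), bit_depth=16
        )
        out, masks, trace = run_detection(seq)
        assert (out.frames == 0).all()
        assert not masks.any()

    def test_trace_invariants_on_noise(self, rng):
        frames = rng.integers(0, 2000, size=(300, 48, 48)).astype(np.uint16)
        seq = FrameSequence(frames, bit_depth=16)
        out, masks, trace = run_detection(seq)
        assert len(trace) == 300
        assert trace.theta_l.between(0.2, 0.5).all()
        assert trace.theta_g.between(0.5, 6.0).all()
        assert trace.period_N.between(7, 100).all()
        assert trace.duration_threshold.between(2, 5).all()
        assert trace.rho.between(0, 1).all()

    def test_mask_nesting(self, pipeline_run):
        _, pre, _, _ = pipeline_run
        sub = FrameSequence(pre.frames[:120], bit_depth=16)
        out, masks, trace = run_detection(sub)
        support = out.frames > 0
        assert (support <= masks).all()  # output inside detection mask

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            FrameSequence(np.zeros((0, 4, 4), dtype=np.uint16), bit_depth=16)
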