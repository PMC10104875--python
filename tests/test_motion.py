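"""Trace filtering, smoothing, segmentation and motion statistics."""

import numpy as np
import pytest

from cmgmotion.motion import (
    SegmentFit,
    apply_filters,
    classify_static_mobile,
    direction_persistence,
    drift_correct,
    fit_linear_segments,
    fold_to_center_distance,
    initial_position,
    kalman_smooth,
    truncate_on_force_jump,
    velocity_and_processivity,
)
from cmgmotion.synthetic import SimulationConfig, simulate_force, simulate_traces


class TestForceTruncation:
    def test_constant_force_unchanged(self):
        x = np.arange(50.0)
        out, jf = truncate_on_force_jump(x, simulate_force(50, 0.0, seed=0))
        assert jf is None and out.size == 50

    def test_large_jump_truncates_before_jump(self):
        x = np.arange(50.0)
        f = simulate_force(50, 0.1, jump_frame=20, jump_size=0.5, seed=1)
        out, jf = truncate_on_force_jump(x, f, 0.1)
        assert jf == 20
        assert out.size == 20  # frames 0..19 kept

    def test_subthreshold_jump_ignored(self):
        x = np.arange(50.0)
        f = simulate_force(50, 0.0, jump_frame=20, jump_size=0.15, seed=1)
        out, jf = truncate_on_force_jump(x, f, 0.1)
        assert jf is None and out.size == 50

    def test_clean_noisy_force_rarely_truncates(self):
        hits = sum(
            truncate_on_force_jump(np.arange(50.0), simulate_force(50, 0.1, seed=s), 0.1)[1] is not None
            for s in range(100)
        )
        assert hits <= 2


class TestFilters:
    def _run(self, traces, **kw):
        defaults = dict(frame_interval=5.0, dna_length_bp=23600.0)
        defaults.update(kw)
        return apply_filters(traces, **defaults)

    def test_good_trace_kept_minus_last_frame(self):
        kept, rep = self._run({0: np.full(20, 10_000.0)})
        assert kept[0].size == 19
        assert rep.dispositions[0] == "kept"

    def test_aggregate_dropped(self):
        kept, rep = self._run({0: np.full(20, 10_000.0)}, n_fluors={0: 6})
        assert 0 not in kept
        assert rep.dispositions[0] == "dropped_aggregate"

    def test_near_bead_dropped(self):
        kept, rep = self._run({0: np.full(20, 500.0)})
        assert rep.dispositions[0] == "dropped_near_bead"

    def test_late_start_dropped(self):
        kept, rep = self._run({0: np.full(20, 10_000.0)}, start_frames={0: 4})
        assert rep.dispositions[0] == "dropped_late_start"

    def test_fourteen_frames_is_too_short_after_last_frame_omission(self):
        kept, rep = self._run({0: np.full(14, 10_000.0), 1: np.full(15, 10_000.0)})
        assert rep.dispositions[0] == "dropped_short"
        assert kept[1].size == 14

    def test_ledger_conserves_every_trace(self):
        rng = np.random.default_rng(0)
        traces = {i: np.full(int(rng.integers(5, 40)), float(rng.uniform(0, 23600)))
                  for i in range(50)}
        kept, rep = self._run(traces, n_fluors={i: int(rng.integers(1, 8)) for i in range(50)})
        assert rep.n_input == 50
        c = rep.counts
        assert c["kept"] + c["dropped_aggregate"] + c["dropped_near_bead"] + \
            c["dropped_late_start"] + c["dropped_short"] == c["input"]
        assert set(rep.dispositions) == set(traces)


class TestKalman:
    def test_constant_series_unchanged(self):
        out = kalman_smooth(np.full(25, 1000.0), 5.0)
        assert np.allclose(out, 1000.0, atol=1e-6)

    def test_reduces_residual_noise_on_line(self):
        rng = np.random.default_rng(1)
        t = np.arange(60) * 5.0
        truth = 5.0 * t
        noisy = truth + rng.normal(0, 72, 60)
        sm = kalman_smooth(noisy, 5.0)
        assert np.std(sm - truth) < np.std(noisy - truth)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 50, 30).cumsum() + 5000
        assert np.allclose(kalman_smooth(x + 1000.0, 5.0), kalman_smooth(x, 5.0) + 1000.0,
                           atol=1e-6)


class TestSegments:
    def test_exact_line_single_segment(self):
        t = np.arange(30) * 5.0
        fit = fit_linear_segments(5.0 * t, 5.0)
        assert fit.n_segments == 1
        assert fit.slopes[0] == pytest.approx(5.0, abs=1e-9)
        assert np.allclose(fit.v_cpa, 5.0)

    def test_short_series_degenerate(self):
        fit = fit_linear_segments(np.array([1.0, 2.0]), 5.0)
        assert fit.degenerate and fit.n_segments == 1 and fit.slopes[0] == 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_recovers_velocity_reversal(self, seed):
        """Two joined lines (+5 then -5 bp/s): breakpoint within 3 frames,
        slopes within 1 bp/s."""
        rng = np.random.default_rng(seed)
        n, dt = 30, 5.0
        t = np.arange(2 * n) * dt
        x = np.where(np.arange(2 * n) < n, 5.0 * t, 5.0 * t[n - 1] - 5.0 * (t - t[n - 1]))
        fit = fit_linear_segments(kalman_smooth(x + rng.normal(0, 20, 2 * n), dt), dt)
        assert fit.n_segments == 2
        assert abs(fit.breakpoints[0] - n) <= 3
        assert fit.slopes[0] == pytest.approx(5.0, abs=1.0)
        assert fit.slopes[1] == pytest.approx(-5.0, abs=1.0)

    def test_penalty_robustness_of_classification(self):
        """Halving/doubling the segmentation penalty changes static/mobile
        calls on a mixed 200-trace population by < 5%."""
        cfg_s = SimulationConfig(motion_model="static", fixed_length=25, n_traces=100, seed=3)
        cfg_d = SimulationConfig(motion_model="diffusive", fixed_length=25, n_traces=100, seed=4)
        traces = [tr.observed for tr in simulate_traces(cfg_s) + simulate_traces(cfg_d)]
        smoothed = [kalman_smooth(x, 5.0) for x in traces]
        labels = {}
        for pen in (0.15, 0.3, 0.6):
            fits = [fit_linear_segments(x, 5.0, penalty=pen) for x in smoothed]
            labels[pen] = [classify_static_mobile(f, 0.0, 2.0) for f in fits]
        for pen in (0.15, 0.6):
            flips = sum(a != b for a, b in zip(labels[0.3], labels[pen]))
            assert flips / 200 < 0.05


class TestClassification:
    def _fit(self, slopes):
        slopes = np.asarray(slopes, dtype=float)
        return SegmentFit(breakpoints=np.arange(1, slopes.size) * 3, slopes=slopes,
                          intercepts=np.zeros(slopes.size),
                          v_cpa=np.repeat(slopes, 3), n_frames=3 * slopes.size)

    def test_all_slopes_at_drift_is_static(self):
        assert classify_static_mobile(self._fit([0.38, 0.38]), 0.38, 2.0) == "static"

    def test_one_fast_segment_is_mobile(self):
        assert classify_static_mobile(self._fit([0.38, 3.38]), 0.38, 2.0) == "mobile"

    def test_false_mobile_rate_under_static_null(self):
        cfg = SimulationConfig(motion_model="static", fixed_length=25, n_traces=200, seed=21)
        false_mobile = 0
        for tr in simulate_traces(cfg):
            fit = fit_linear_segments(kalman_smooth(tr.observed, 5.0), 5.0)
            if classify_static_mobile(fit, 0.0, 2.0) == "mobile":
                false_mobile += 1
        assert false_mobile / 200 <= 0.05

    def test_false_mobile_rate_decreases_with_cutoff(self):
        cfg = SimulationConfig(motion_model="static", fixed_length=25, n_traces=150, seed=22)
        fits = [fit_linear_segments(kalman_smooth(tr.observed, 5.0), 5.0)
                for tr in simulate_traces(cfg)]
        rates = []
        for cutoff in (3 * 0.4, 5 * 0.4, 7 * 0.4):
            rates.append(np.mean([classify_static_mobile(f, 0.0, cutoff) == "mobile" for f in fits]))
        assert rates[0] >= rates[1] >= rates[2]


class TestDriftCorrect:
    def test_zero_drift_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(drift_correct(x, 0.0, 5.0), x)

    def test_pure_drift_cancels(self):
        t = np.arange(20) * 5.0
        assert np.allclose(drift_correct(0.38 * t, 0.38, 5.0), 0.0)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 10, 15)
        assert np.allclose(drift_correct(drift_correct(x, 0.38, 5.0), -0.38, 5.0), x)


class TestPersistence:
    def _fit(self, slopes):
        slopes = np.asarray(slopes, dtype=float)
        return SegmentFit(breakpoints=np.arange(1, slopes.size) * 3, slopes=slopes,
                          intercepts=np.zeros(slopes.size),
                          v_cpa=np.repeat(slopes, 3), n_frames=3 * slopes.size)

    def test_monotone_traces_give_one(self):
        p, se, n = direction_persistence([self._fit([5.0, 3.0, 4.0])])
        assert p == 1.0 and n == 2

    def test_alternating_traces_give_zero(self):
        p, _, _ = direction_persistence([self._fit([5.0, -3.0, 4.0, -2.0])])
        assert p == 0.0

    def test_no_pairs_is_undefined(self):
        p, se, n = direction_persistence([self._fit([5.0])])
        assert p is None and n == 0

    def test_bounded_and_reflection_invariant(self):
        rng = np.random.default_rng(5)
        fits = [self._fit(rng.normal(0, 3, rng.integers(2, 5))) for _ in range(20)]
        p, _, _ = direction_persistence(fits)
        reflected = [self._fit(-f.slopes) for f in fits]
        pr, _, _ = direction_persistence(reflected)
        assert 0.0 <= p <= 1.0
        assert p == pr


class TestVelocityProcessivity:
    def test_constant_velocity_arithmetic(self):
        # 5 bp/s for 100 s -> mean velocity 5 bp/s, processivity 0.5 kbp
        t = np.arange(21) * 5.0
        x = 5.0 * t
        fit = fit_linear_segments(x, 5.0)
        out = velocity_and_processivity(x, fit, 5.0)
        assert out["mean_velocity"] == pytest.approx(5.0)
        assert out["processivity_kbp"] == pytest.approx(0.5)
        assert np.allclose(out["instantaneous"], 5.0)

    def test_static_trace_processivity_near_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(5000, 72, 25)
        fit = fit_linear_segments(kalman_smooth(x, 5.0), 5.0)
        out = velocity_and_processivity(x, fit, 5.0)
        assert out["processivity_kbp"] * 1000 < 3 * 72 / np.sqrt(25) * 5  # loose null bound


class TestPosition:
    def test_initial_position_mean_of_first_three(self):
        assert initial_position(np.array([100.0, 110.0, 120.0, 500.0])) == 110.0

    def test_fold_to_center(self):
        assert fold_to_center_distance(20_000.0, 23_600.0) == pytest.approx(8.2)
        assert fold_to_center_distance(11_800.0, 23_600.0) == 0.0
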