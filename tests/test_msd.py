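"""MSD computation, anomalous-exponent fitting and diffusion coefficients."""

import numpy as np
import pytest

from cmgmotion.msd import (
    MsdCurve,
    classify_alpha,
    compute_msd,
    estimate_D,
    fit_alpha,
    max_lag,
)
from cmgmotion.synthetic import SimulationConfig, simulate_trace, simulate_traces


def brute_force_msd(x, k):
    return np.mean([(x[i + k] - x[i]) ** 2 for i in range(len(x) - k)])


def power_law_curve(alpha, D_alpha, sigma_x, n=150, dt=5.0):
    lags = np.arange(1, 51)
    taus = lags * dt
    msd = D_alpha * taus**alpha + 2 * sigma_x**2
    return MsdCurve(lags=lags, taus=taus, msd=msd, n_pairs=np.full(50, n),
                    frame_interval=dt, trace_length=n)


class TestComputeMsd:
    def test_hand_example(self):
        c = compute_msd(np.array([0.0, 10.0, 20.0, 30.0]), 1.0)
        assert np.allclose(c.msd, [100.0, 400.0, 900.0])
        assert np.array_equal(c.n_pairs, [3, 2, 1])

    def test_constant_series_all_zero(self):
        assert np.allclose(compute_msd(np.full(10, 7.0), 1.0).msd, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 50, int(rng.integers(5, 51))).cumsum()
        c = compute_msd(x, 5.0)
        for k in c.lags:
            assert c.msd[k - 1] == pytest.approx(brute_force_msd(x, k), rel=1e-12)

    def test_brownian_ensemble_slope_is_2D(self):
        # 1-D diffusion: MSD = 2*D*tau (not 4*D*tau)
        cfg = SimulationConfig(motion_model="diffusive", sigma_x=0.0, fixed_length=8,
                               dna_length=1e8)
        rng = np.random.default_rng(3)
        msds = np.array([compute_msd(simulate_trace(cfg, rng).positions, 5.0).msd
                         for _ in range(4000)])
        D_bp2, dt = cfg.D * 1e6, 5.0
        for k in (1, 2, 3):
            vals = msds[:, k - 1]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - 2 * D_bp2 * k * dt) < 3 * se

    def test_lag_invariants(self):
        c = compute_msd(np.arange(20.0), 1.0)
        assert c.lags[0] == 1 and np.all(np.diff(c.lags) == 1)
        assert np.all(np.diff(c.n_pairs) < 0)
        assert np.all(c.msd >= 0)


class TestFitAlpha:
    def test_ballistic_noiseless_clips_to_two(self):
        t = np.arange(60) * 5.0
        c = compute_msd(5.0 * t, 5.0)
        assert fit_alpha(c, 0.0).alpha == 2.0

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5, 2.0])
    def test_exact_power_law_recovery(self, alpha):
        c = power_law_curve(alpha, 7.0, 72.0)
        fit = fit_alpha(c, 72.0)
        assert fit.alpha_raw == pytest.approx(alpha, rel=1e-6)
        assert fit.D_alpha == pytest.approx(7.0, rel=1e-6)

    def test_degenerate_when_below_noise_floor(self):
        c = power_law_curve(1.0, 1e-9, 72.0)
        c.msd[:] = 2 * 72.0**2 - 1.0  # every lag below the noise floor
        fit = fit_alpha(c, 72.0)
        assert fit.degenerate and fit.alpha == 0.0

    def test_max_lag_rule(self):
        assert max_lag(14) == 5  # floor of the clamp
        assert max_lag(100) == 33
        assert max_lag(1000) == 50  # ceiling of the clamp


class TestClassify:
    @pytest.mark.parametrize("alpha,expected", [
        (0.3, "confined"),
        (0.49999, "confined"),
        (0.5, "free_diffusive"),
        (1.0, "free_diffusive"),
        (1.5, "unidirectional"),
        (2.0, "unidirectional"),
    ])
    def test_bin_edges(self, alpha, expected):
        assert classify_alpha(alpha) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_alpha(2.1)


class TestEstimateD:
    def test_plug_in_inversion_of_exact_curve(self):
        c = power_law_curve(1.0, 2 * 1500.0, 72.0)  # MSD = 2*D*tau + 2 sigma^2
        D, flagged = estimate_D(c, 72.0)
        assert D == pytest.approx(1.5e-3, rel=1e-9)
        assert not flagged

    def test_static_traces_flag_or_zero(self):
        rng = np.random.default_rng(4)
        small = []
        for _ in range(50):
            x = rng.normal(0, 72, 30)
            D, flagged = estimate_D(compute_msd(x, 5.0), 72.0)
            small.append(D)
        assert np.median(small) < 2e-4  # ~0 on the 1.5e-3 scale

    def test_optimal_lag_mode_close_to_short_mode(self):
        cfg = SimulationConfig(motion_model="diffusive", fixed_length=40, seed=9)
        tr = simulate_trace(cfg, seed=9)
        c = compute_msd(tr.observed, 5.0)
        d_short, _ = estimate_D(c, 72.0, mode="short")
        d_opt, _ = estimate_D(c, 72.0, mode="optimal")
        assert d_opt == pytest.approx(d_short, rel=1.0)  # same order of magnitude


class TestPopulationClassification:
    def test_majorities_match_generating_models(self):
        """512 directed traces are mostly unidirectional; 512 diffusive
        traces mostly free-diffusive (>= 14-frame retention)."""
        out = {}
        for model, seed in (("diffusive", 31), ("directed", 32)):
            cfg = SimulationConfig(motion_model=model, n_traces=512, seed=seed)
            classes = []
            for tr in simulate_traces(cfg):
                if tr.n_frames < 14:
                    continue
                fit = fit_alpha(compute_msd(tr.observed, 5.0), 72.0)
                classes.append("confined" if fit.degenerate else classify_alpha(fit.alpha))
            out[model] = classes
        diff = out["diffusive"]
        assert diff.count("free_diffusive") / len(diff) > 0.5
        dire = out["directed"]
        assert dire.count("unidirectional") / len(dire) > 0.5
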