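"""Simulation-based validation of the motion classifier.

Two studies mirror the pipeline's own error analysis: (1) the
anomalous-exponent error study, which simulates matched populations of
freely diffusive (alpha = 1) and constant-speed (alpha = 2) traces and
tabulates the spread of the fitted exponent as a function of the
minimum-trace-length retention threshold — fixing the threshold at
which sigma_alpha drops below 0.5, the value that keeps the alpha ~ 1
and alpha ~ 2 populations statistically separable; and (2) the motion
classification study, which reports the fraction of each simulated
population assigned to each motion class.  Small statistical helpers
used in population bar plots live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binomtest

from .msd import compute_msd, fit_alpha, classify_alpha
from .motion import drift_correct
from .synthetic import SimulationConfig, simulate_traces

__all__ = [
    "AlphaErrorTable",
    "run_alpha_error_study",
    "run_classification_study",
    "fit_alpha_population",
    "proportion_se",
    "two_proportion_binomial_test",
]

DEFAULT_DIFFUSIVE = SimulationConfig(motion_model="diffusive", D=1.5e-3, sigma_x=72.0,
                                     mean_lifetime=25.0, frame_interval=5.0, n_traces=512)
DEFAULT_DIRECTED = replace(DEFAULT_DIFFUSIVE, motion_model="directed", v=5.0)


@dataclass
class AlphaErrorTable:
    min_lengths: np.ndarray  # candidate retention thresholds, frames
    n_retained_diffusive: np.ndarray
    n_retained_directed: np.ndarray
    sigma_alpha_diffusive: np.ndarray
    sigma_alpha_directed: np.ndarray
    mean_alpha_diffusive: np.ndarray
    mean_alpha_directed: np.ndarray
    low_n_flag: np.ndarray  # rows with < 20 retained traces in either population
    qualifying_min_length: int | None  # smallest threshold with both sigma_alpha < 0.5

    def to_rows(self) -> list[dict]:
        return [
            dict(min_length=int(m), n_diffusive=int(nd), n_directed=int(nv),
                 sigma_alpha_diffusive=float(sd), sigma_alpha_directed=float(sv),
                 mean_alpha_diffusive=float(md), mean_alpha_directed=float(mv),
                 low_n=bool(f))
            for m, nd, nv, sd, sv, md, mv, f in zip(
                self.min_lengths, self.n_retained_diffusive, self.n_retained_directed,
                self.sigma_alpha_diffusive, self.sigma_alpha_directed,
                self.mean_alpha_diffusive, self.mean_alpha_directed, self.low_n_flag)
        ]


def fit_alpha_population(
    config: SimulationConfig, seed: int, tau_max_frac: float = 0.33
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a population and fit alpha per trace.

    Returns (trace lengths in frames, fitted alphas); traces too short
    for an MSD (or with a degenerate fit) get the fit's alpha = 0
    confined fallback, and 1-frame traces get NaN.
    """
    traces = simulate_traces(config, seed=seed)
    lengths = np.array([tr.n_frames for tr in traces])
    alphas = np.full(len(traces), np.nan)
    for i, tr in enumerate(traces):
        if tr.n_frames < 3:
            continue
        x = drift_correct(tr.observed, 0.0, config.frame_interval)
        curve = compute_msd(x, config.frame_interval)
        alphas[i] = fit_alpha(curve, config.sigma_x, tau_max_frac).alpha
    return lengths, alphas


def run_alpha_error_study(
    n_per_population: int = 512,
    D: float = 1.5e-3,
    v: float = 5.0,
    sigma_x: float = 72.0,
    mean_lifetime: float = 25.0,
    frame_interval: float = 5.0,
    seed: int = 0,
    min_lengths: np.ndarray | None = None,
    sigma_alpha_target: float = 0.5,
) -> AlphaErrorTable:
    """Tabulate sigma_alpha vs minimum-trace-length retention threshold.

    Simulates ``n_per_population`` diffusive and constant-speed traces
    with exponential (geometric) lifetimes and, for every candidate
    threshold, computes the SD of fitted alpha among traces at least
    that long.  The qualifying threshold is the smallest with
    sigma_alpha < ``sigma_alpha_target`` in both populations.
    """
    if min(n_per_population, D, v, sigma_x, mean_lifetime, frame_interval) <= 0:
        raise ValueError("all study parameters must be positive")
    if min_lengths is None:
        min_lengths = np.arange(5, 31)
    cfg_dif = SimulationConfig(motion_model="diffusive", D=D, sigma_x=sigma_x,
                               mean_lifetime=mean_lifetime, frame_interval=frame_interval,
                               n_traces=n_per_population)
    cfg_dir = replace(cfg_dif, motion_model="directed", v=v)
    len_dif, a_dif = fit_alpha_population(cfg_dif, seed)
    len_dir, a_dir = fit_alpha_population(cfg_dir, seed + 1)

    def sd_at(lengths, alphas, m):
        sel = (lengths >= m) & np.isfinite(alphas)
        n = int(sel.sum())
        if n < 2:
            return n, np.nan, np.nan
        return n, float(alphas[sel].std(ddof=1)), float(alphas[sel].mean())

    rows = [(*sd_at(len_dif, a_dif, m), *sd_at(len_dir, a_dir, m)) for m in min_lengths]
    nd, sd_d, mean_d, nv, sd_v, mean_v = (np.array(z) for z in zip(*rows))
    low_n = (nd < 20) | (nv < 20)
    qual = None
    for i, m in enumerate(min_lengths):
        if np.isfinite(sd_d[i]) and np.isfinite(sd_v[i]) and sd_d[i] < sigma_alpha_target and sd_v[i] < sigma_alpha_target:
            qual = int(m)
            break
    return AlphaErrorTable(
        min_lengths=np.asarray(min_lengths), n_retained_diffusive=nd, n_retained_directed=nv,
        sigma_alpha_diffusive=sd_d, sigma_alpha_directed=sd_v,
        mean_alpha_diffusive=mean_d, mean_alpha_directed=mean_v,
        low_n_flag=low_n, qualifying_min_length=qual,
    )


def run_classification_study(
    populations: dict[str, SimulationConfig] | None = None,
    seed: int = 0,
    min_frames: int = 14,
) -> dict[str, dict]:
    """Fractions of each motion class per simulated population.

    Traces shorter than ``min_frames`` are excluded (the pipeline's
    retention rule); fractions come with standard errors of proportion.
    """
    if populations is None:
        populations = {"diffusive": DEFAULT_DIFFUSIVE, "directed": DEFAULT_DIRECTED}
    out = {}
    for k, (name, cfg) in enumerate(populations.items()):
        lengths, alphas = fit_alpha_population(cfg, seed + k)
        sel = (lengths >= min_frames) & np.isfinite(alphas)
        classes = [classify_alpha(a) for a in alphas[sel]]
        n = len(classes)
        fractions = {}
        for cls in ("confined", "free_diffusive", "unidirectional"):
            p = classes.count(cls) / n if n else np.nan
            fractions[cls] = {"fraction": p, "se": proportion_se(p, n) if n else np.nan}
        out[name] = {"n": n, "fractions": fractions}
    return out


def proportion_se(p: float, n: int) -> float:
    """Standard error of a proportion: sqrt(p*(1-p)/n)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(np.sqrt(p * (1.0 - p) / n))


def two_proportion_binomial_test(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value for k successes of n at rate p0,
    summing all outcomes no more likely than the observed one."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)
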