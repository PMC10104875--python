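"""Pipeline constants derived from static fiducial (dCas9) traces.

A catalytically dead, sequence-targeted dCas9 bound at known bp
positions is static on the DNA, so its apparent motion measures the
instrument: the pixel-to-bp map comes from its known binding sites, the
residual drift mu_v and velocity noise sigma_v from the change-point
slopes of its traces, the localization error sigma_x from the scatter
of its positions about their per-trace means, and the single-fluorophore
bleaching step statistics (mu_dI, sigma_dI, dI_min) from its intensity
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changepoint import segment_constant, segment_means
from .motion import SegmentFit, drift_correct

__all__ = [
    "CalibrationSet",
    "build_px_to_bp_map",
    "estimate_drift_noise",
    "estimate_localization_error",
    "estimate_step_stats",
]


@dataclass
class CalibrationSet:
    """All fiducial-derived constants the pipeline consumes.

    Defaults are the experimentally calibrated values for the reference
    system (23.6 kbp DNA, 5 s frames): drift mu_v = 0.38 bp/s, velocity
    noise sigma_v = 0.40 bp/s (mobility cutoff 5*sigma_v = 2.0 bp/s),
    localization error sigma_x = 72 bp, force noise sigma_F = 0.1 pN.
    """

    px_to_bp_slope: float = 150.0  # bp per pixel (50 nm px / 0.333 nm/bp)
    px_to_bp_intercept: float = 0.0  # bp
    mu_v: float = 0.38  # bp/s
    sigma_v: float = 0.40  # bp/s
    sigma_x: float = 72.0  # bp
    mu_dI: float = 300.0  # ADU, per channel of interest
    sigma_dI: float = 30.0  # ADU
    crosstalk_ratio: float = 0.0  # mu_dI_red(crosstalk) / mu_dI_green
    sigma_F: float = 0.1  # pN
    cutoff_sigma: float = 5.0  # mobility cutoff in units of sigma_v
    residuals_bp: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def dI_min(self) -> float:
        """Minimum accepted bleaching step: mu_dI - 2*sigma_dI captures
        >= 95% of Gaussian step sizes."""
        return self.mu_dI - 2.0 * self.sigma_dI

    @property
    def mobility_cutoff(self) -> float:
        return self.cutoff_sigma * self.sigma_v

    def px_to_bp(self, x_px: np.ndarray | float) -> np.ndarray | float:
        return self.px_to_bp_slope * np.asarray(x_px, dtype=float) + self.px_to_bp_intercept

    def validate(self) -> None:
        if self.px_to_bp_slope == 0:
            raise ValueError("px_to_bp slope must be nonzero")
        if min(self.sigma_v, self.sigma_x, self.sigma_dI) < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.dI_min > self.mu_dI - 2.0 * self.sigma_dI + 1e-9:
            raise ValueError("dI_min must not exceed mu_dI - 2*sigma_dI")


def build_px_to_bp_map(
    fiducial_x_px: list[np.ndarray], known_positions_bp: np.ndarray,
    min_site_sep_px: float = 10.0,
) -> tuple[float, float, np.ndarray]:
    """Least-squares affine map px -> bp from fiducial traces.

    Each trace's mean pixel position is assigned to the nearest cluster
    of trace means (one cluster per known site, matched in sorted
    order); the map is fit through the per-site mean pixel positions.
    Returns (slope bp/px, intercept bp, per-site residuals bp).
    """
    known = np.sort(np.asarray(known_positions_bp, dtype=float))
    k = known.size
    if k < 2:
        raise ValueError("need at least 2 fiducial sites with known bp positions")
    means = np.array([np.mean(np.asarray(t, dtype=float)) for t in fiducial_x_px])
    if means.size < k:
        raise ValueError(f"need traces covering {k} sites, got {means.size} traces")
    # 1-D clustering: split the sorted trace means at the k-1 largest gaps
    order = np.argsort(means)
    sorted_means = means[order]
    gaps = np.diff(sorted_means)
    cut_idx = np.sort(np.argsort(gaps)[-(k - 1):]) + 1
    groups = np.split(sorted_means, cut_idx)
    site_px = np.array([g.mean() for g in groups])
    if np.any(np.diff(site_px) < min_site_sep_px):
        raise ValueError(f"fiducial sites closer than {min_site_sep_px} px cannot be resolved")
    slope, intercept = np.polyfit(site_px, known, 1)
    residuals = known - (slope * site_px + intercept)
    return float(slope), float(intercept), residuals


def estimate_drift_noise(fits: list[SegmentFit]) -> tuple[float, float]:
    """Drift mu_v and velocity noise sigma_v from fiducial CPA fits.

    Frame-weighted: every detection contributes its segment's slope, so
    the statistics describe the distribution of instantaneous v_CPA.
    """
    v = np.concatenate([f.v_cpa for f in fits if f.n_frames > 0]) if fits else np.empty(0)
    if v.size == 0:
        raise ValueError("no CPA segments to estimate drift from")
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


def estimate_localization_error(
    traces_bp: list[np.ndarray], mu_v: float = 0.0, frame_interval: float = 1.0
) -> float:
    """Localization error sigma_x: pooled SD of drift-corrected fiducial
    positions about their per-trace means.

    Invariant under per-trace offsets and under pure linear drift equal
    to ``mu_v``.  Uses the pooled unbiased variance (denominator
    sum(n_i - 1)).
    """
    ss = 0.0
    dof = 0
    usable = 0
    for x in traces_bp:
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            continue
        xc = drift_correct(x, mu_v, frame_interval)
        ss += float(np.sum((xc - xc.mean()) ** 2))
        dof += x.size - 1
        usable += 1
    if usable == 0:
        raise ValueError("need at least one fiducial trace of >= 2 frames")
    return float(np.sqrt(ss / dof))


def _single_step_size(series: np.ndarray) -> tuple[float, int] | None:
    """Best single-breakpoint fit of a one-fluorophore bleach series;
    returns (downward step size, frame) or None when no credible step."""
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 4:
        return None
    best = None
    for b in range(2, n - 1):  # min segment length 2 on both sides
        sse = np.sum((y[:b] - y[:b].mean()) ** 2) + np.sum((y[b:] - y[b:].mean()) ** 2)
        if best is None or sse < best[0]:
            best = (sse, b)
    b = best[1]
    step = y[:b].mean() - y[b:].mean()
    noise = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2.0)
    if step <= max(4.0 * noise, 0.0):
        return None
    return float(step), b


def estimate_step_stats(bleach_series: list[np.ndarray]) -> tuple[float, float, float]:
    """Bleaching step statistics from single-fluorophore fiducial series.

    Fits each series' single downward step; series with no detectable
    step are excluded.  Returns (mu_dI, sigma_dI, dI_min) with
    dI_min = mu_dI - 2*sigma_dI.
    """
    steps = []
    for s in bleach_series:
        res = _single_step_size(np.asarray(s, dtype=float))
        if res is not None:
            steps.append(res[0])
    if not steps:
        raise ValueError("no bleaching steps detected in any fiducial series")
    steps = np.asarray(steps)
    mu = float(steps.mean())
    sigma = float(steps.std(ddof=1)) if steps.size > 1 else 0.0
    return mu, sigma, mu - 2.0 * sigma
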