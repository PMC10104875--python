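"""Anomalous-diffusion analysis of drift-corrected traces.

The time-averaged mean squared displacement of a trace follows

    MSD(tau) = D_alpha * tau**alpha + 2 * sigma_x**2

where sigma_x is the static localization error.  The anomalous exponent
alpha is fit by least squares on

    log(MSD(tau) - 2*sigma_x**2) = log(D_alpha) + alpha * log(tau)

up to a maximum lag of 33% of the trace length (clamped to 5..50
frames), with alpha constrained to [0, 2]: alpha ~ 1 is free diffusion,
alpha ~ 2 ballistic (unidirectional) motion, alpha << 1 confinement.
Diffusion coefficients for freely diffusive traces come from refitting
with alpha fixed at 1 over a short-lag range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MsdCurve",
    "AlphaFit",
    "compute_msd",
    "fit_alpha",
    "classify_alpha",
    "estimate_D",
    "ALPHA_CONFINED_MAX",
    "ALPHA_FREE_MAX",
]

ALPHA_CONFINED_MAX = 0.5  # [0, 0.5): confined
ALPHA_FREE_MAX = 1.5  # [0.5, 1.5): free diffusion; [1.5, 2]: unidirectional


@dataclass
class MsdCurve:
    lags: np.ndarray  # frames, 1..n-1
    taus: np.ndarray  # seconds
    msd: np.ndarray  # bp^2
    n_pairs: np.ndarray  # displacement pairs averaged per lag
    frame_interval: float
    trace_length: int


@dataclass
class AlphaFit:
    alpha: float  # clipped to [0, 2]
    alpha_raw: float  # unconstrained least-squares estimate
    D_alpha: float  # bp^2 / s^alpha
    n_lags_used: int
    degenerate: bool = False  # < 2 usable lags; treated as confined


def compute_msd(
    positions: np.ndarray, frame_interval: float, overlapping: bool = True
) -> MsdCurve:
    """Time-averaged MSD over all (default: overlapping) frame pairs:
    MSD(k) = mean_i (x_{i+k} - x_i)^2 for k = 1..n-1."""
    x = np.asarray(positions, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 positions")
    lags = np.arange(1, n)
    msd = np.empty(n - 1)
    n_pairs = np.empty(n - 1, dtype=int)
    for k in lags:
        if overlapping:
            d = x[k:] - x[:-k]
        else:
            d = np.diff(x[::k])
        msd[k - 1] = np.mean(d * d)
        n_pairs[k - 1] = d.size
    return MsdCurve(lags=lags, taus=lags * float(frame_interval), msd=msd,
                    n_pairs=n_pairs, frame_interval=float(frame_interval), trace_length=n)


def max_lag(trace_length: int, frac: float = 0.33, lo: int = 5, hi: int = 50) -> int:
    """Maximum fit lag tau_M: ``frac`` of the trace length, rounded
    (half-even), clamped to [lo, hi] frames."""
    return int(np.clip(np.round(frac * trace_length), lo, hi))


def fit_alpha(
    curve: MsdCurve, sigma_x: float, tau_max_frac: float = 0.33
) -> AlphaFit:
    """Least-squares anomalous-exponent fit with measurement-error
    correction.

    Lags with MSD <= 2*sigma_x^2 carry no displacement signal above the
    localization noise floor and are excluded; with fewer than 2 usable
    lags the trace is flagged degenerate (alpha = 0, confined).
    """
    tm = min(max_lag(curve.trace_length, tau_max_frac), curve.lags.size)
    taus = curve.taus[:tm]
    msd = curve.msd[:tm]
    corrected = msd - 2.0 * sigma_x**2
    ok = corrected > 0
    if ok.sum() < 2:
        return AlphaFit(alpha=0.0, alpha_raw=np.nan, D_alpha=np.nan,
                        n_lags_used=int(ok.sum()), degenerate=True)
    slope, intercept = np.polyfit(np.log(taus[ok]), np.log(corrected[ok]), 1)
    return AlphaFit(
        alpha=float(np.clip(slope, 0.0, 2.0)), alpha_raw=float(slope),
        D_alpha=float(np.exp(intercept)), n_lags_used=int(ok.sum()),
    )


def classify_alpha(alpha: float) -> str:
    """Motion class from the anomalous exponent: [0,0.5) confined,
    [0.5,1.5) free_diffusive, [1.5,2] unidirectional."""
    if not (0.0 <= alpha <= 2.0):
        raise ValueError(f"alpha={alpha} outside [0, 2]; clip upstream")
    if alpha < ALPHA_CONFINED_MAX:
        return "confined"
    if alpha < ALPHA_FREE_MAX:
        return "free_diffusive"
    return "unidirectional"


def estimate_D(
    curve: MsdCurve, sigma_x: float, n_lags: int | None = None, mode: str = "short"
) -> tuple[float, bool]:
    """Diffusion coefficient by refitting MSD with alpha fixed to 1.

    Weighted least squares of MSD(tau) = 2*D*tau + 2*sigma_x^2 (weights
    = pairs per lag), i.e. a fit through the origin of the
    noise-floor-corrected MSD.  ``mode='short'`` uses the first
    max(2, round(n/10)) lags; ``mode='optimal'`` picks the lag count
    from the reduced localization error x = sigma_x^2/(D*dt) with the
    fixed-point rule p = 2 + 2.3*x^0.52.  Returns (D in kb^2/s,
    flagged); a negative fit is reported as 0 and flagged.
    """
    if n_lags is None:
        if mode == "short":
            n_lags = max(2, int(np.round(curve.trace_length / 10)))
        elif mode == "optimal":
            n_lags = 2
            for _ in range(3):  # fixed-point iteration on the D estimate
                D_bp, _ = _wls_D(curve, sigma_x, n_lags)
                if D_bp <= 0:
                    break
                x = sigma_x**2 / (D_bp * curve.frame_interval)
                n_lags = max(2, int(np.round(2.0 + 2.3 * x**0.52)))
                n_lags = min(n_lags, curve.lags.size)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    n_lags = min(max(2, int(n_lags)), curve.lags.size)
    D_bp, flagged = _wls_D(curve, sigma_x, n_lags)
    if D_bp < 0:
        return 0.0, True
    return D_bp / 1e6, flagged  # bp^2/s -> kb^2/s


def _wls_D(curve: MsdCurve, sigma_x: float, n_lags: int) -> tuple[float, bool]:
    taus = curve.taus[:n_lags]
    y = curve.msd[:n_lags] - 2.0 * sigma_x**2
    w = curve.n_pairs[:n_lags].astype(float)
    slope = float(np.sum(w * taus * y) / np.sum(w * taus * taus))
    return slope / 2.0, False
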