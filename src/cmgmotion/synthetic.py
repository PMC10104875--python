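"""Ground-truth generators for every stage of the trace-analysis pipeline.

These emulate the statistical structure of confocal scans of fluorescent
proteins on an optically trapped DNA: 1-D motion along the DNA axis
(static, freely diffusive, constant-velocity, or confined), Gaussian
localization noise, exponential fluorophore survival, linear stage
drift, stepwise photobleaching intensity series, force readouts with
optional jump artefacts, and rasterization of traces into photon-count
scan stacks with a Gaussian point-spread function and Poisson shot
noise.

Defaults follow the experimental regime the pipeline is calibrated for:
23.6 kbp DNA imaged at 5 s/frame on a 160x18 px field of 50 nm pixels,
diffusion constant D = 1.5e-3 kb^2/s, speed v = 5 bp/s, localization
error sigma_x = 72 bp (~24 nm at 0.333 nm/bp) and a mean fluorophore
lifetime of 25 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "TrueTrace",
    "ScanGeometry",
    "SyntheticScan",
    "simulate_trace",
    "simulate_traces",
    "simulate_bleach_series",
    "simulate_force",
    "render_scan",
]

MOTION_MODELS = ("static", "diffusive", "directed", "confined")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated single-fluorophore trace population.

    Units: D in kb^2/s, v and drift_v in bp/s, sigma_x in bp,
    mean_lifetime in frames, frame_interval in s, dna_length in bp.
    """

    motion_model: str = "diffusive"
    D: float = 1.5e-3
    v: float = 5.0
    sigma_x: float = 72.0
    mean_lifetime: float = 25.0
    frame_interval: float = 5.0
    n_traces: int = 1
    dna_length: float = 23600.0
    nm_per_bp: float = 0.333
    drift_v: float = 0.0
    seed: int = 0
    boundary: str = "reflecting"  # or "absorbing"
    corral_sd: float = 100.0  # bp; confined (Ornstein-Uhlenbeck) corral size
    fixed_length: int | None = None  # frames; overrides the lifetime draw

    def validate(self) -> None:
        if self.motion_model not in MOTION_MODELS:
            raise ValueError(f"unknown motion_model {self.motion_model!r}")
        if self.D < 0 or self.sigma_x < 0:
            raise ValueError("D and sigma_x must be non-negative")
        if self.mean_lifetime <= 0 or self.frame_interval <= 0 or self.dna_length <= 0:
            raise ValueError("mean_lifetime, frame_interval and dna_length must be positive")
        if self.boundary not in ("reflecting", "absorbing"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.fixed_length is not None and self.fixed_length < 1:
            raise ValueError("fixed_length must be >= 1")


@dataclass
class TrueTrace:
    """One simulated trace: noiseless ground truth plus what is observed."""

    positions: np.ndarray  # bp, ground truth
    observed: np.ndarray  # bp, positions + localization noise + drift
    motion_model: str
    start_bp: float

    @property
    def n_frames(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class ScanGeometry:
    """Confocal scan raster: field size, pixel pitch and optical response."""

    n_x: int = 160
    n_y: int = 18
    pixel_nm: float = 50.0
    psf_sigma_px: float = 2.0
    photons_per_fluor: float = 100.0
    background_rate: float = 0.1

    def validate(self) -> None:
        if min(self.n_x, self.n_y) <= 0 or self.pixel_nm <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.photons_per_fluor < 0 or self.background_rate < 0:
            raise ValueError("photon rates must be non-negative")


@dataclass
class SyntheticScan:
    """Rendered photon-count stack with its ground-truth sidecar."""

    frames: np.ndarray  # (n_frames, n_y, n_x) integer photon counts
    frame_interval: float
    pixel_nm: float
    truth: "object"  # pandas DataFrame: trace_id, frame, true_bp, observed_bp, x_px, y_px


def _draw_length(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    if cfg.fixed_length is not None:
        return int(cfg.fixed_length)
    # geometric on {1, 2, ...} with mean = mean_lifetime: discrete analog
    # of exponential photobleaching survival, floor at 1 frame for free
    return int(rng.geometric(1.0 / cfg.mean_lifetime))


def simulate_trace(config: SimulationConfig, seed: int | np.random.Generator) -> TrueTrace:
    """Simulate a single 1-D trace under ``config``.

    Ground-truth increments: diffusive steps are N(0, 2*D*dt); directed
    motion is x0 + v*t with a random sign for the direction; static is
    constant; confined is an Ornstein-Uhlenbeck corral of SD
    ``corral_sd`` about the start position.  The observation adds iid
    N(0, sigma_x^2) localization noise and drift_v * t.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = _draw_length(config, rng)
    dt = config.frame_interval
    L = config.dna_length
    D_bp2 = config.D * 1e6  # kb^2/s -> bp^2/s
    margin = min(0.1 * L, 2000.0)
    x0 = float(rng.uniform(margin, L - margin))
    t = np.arange(n) * dt

    if config.motion_model == "static":
        x = np.full(n, x0)
    elif config.motion_model == "directed":
        sign = 1.0 if rng.random() < 0.5 else -1.0
        x = x0 + sign * config.v * t
    elif config.motion_model == "diffusive":
        steps = rng.normal(0.0, np.sqrt(2.0 * D_bp2 * dt), size=n - 1) if n > 1 else np.empty(0)
        x = x0 + np.concatenate(([0.0], np.cumsum(steps)))
    else:  # confined: discretized OU about x0
        tau = 10.0 * dt  # relaxation time; corral_sd sets the stationary SD
        phi = np.exp(-dt / tau)
        innov_sd = config.corral_sd * np.sqrt(1.0 - phi**2)
        x = np.empty(n)
        x[0] = x0
        for k in range(1, n):
            x[k] = x0 + phi * (x[k - 1] - x0) + rng.normal(0.0, innov_sd)

    # boundary handling on the ground truth
    if config.boundary == "reflecting":
        x = _reflect(x, 0.0, L)
    else:
        inside = (x >= 0.0) & (x <= L)
        if not inside.all():
            n = max(int(np.argmin(inside)), 1)
            x, t = x[:n], t[:n]

    observed = x + rng.normal(0.0, config.sigma_x, size=x.size) + config.drift_v * t[: x.size]
    return TrueTrace(positions=x, observed=observed, motion_model=config.motion_model, start_bp=x0)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    return lo + np.where(y > width, 2.0 * width - y, y)


def simulate_traces(config: SimulationConfig, seed: int | None = None) -> list[TrueTrace]:
    """Simulate ``config.n_traces`` independent traces from one seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [simulate_trace(config, rng) for _ in range(config.n_traces)]


def simulate_bleach_series(
    n_fluors: int,
    mu_step: float = 300.0,
    sigma_step: float = 30.0,
    mean_lifetime: float = 25.0,
    noise_sd: float = 20.0,
    seed: int | np.random.Generator = 0,
    background: float = 0.0,
    n_frames: int | None = None,
    return_truth: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Stepwise photobleaching intensity series for a spot of ``n_fluors``.

    Each fluorophore contributes a Gaussian(mu_step, sigma_step^2) level
    until it bleaches at an exponential time of mean ``mean_lifetime``
    frames; the series decays to ``background`` plus Gaussian read noise.
    With ``return_truth`` the sorted true bleach frames are returned too
    (two bleach events closer than the step-fit resolution are not
    recoverable by any counter, so scoring needs the ground truth).
    """
    if n_fluors < 0:
        raise ValueError("n_fluors must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = rng.normal(mu_step, sigma_step, size=n_fluors)
    lifetimes = np.maximum(1, np.ceil(rng.exponential(mean_lifetime, size=n_fluors)).astype(int))
    if n_frames is None:
        n_frames = int(lifetimes.max() if n_fluors else mean_lifetime) + 5
    frames = np.arange(n_frames)
    series = np.full(n_frames, float(background))
    for size, life in zip(sizes, lifetimes):
        series += np.where(frames < life, size, 0.0)
    if noise_sd > 0:
        series += rng.normal(0.0, noise_sd, size=n_frames)
    if return_truth:
        return series, np.sort(lifetimes)
    return series


def simulate_force(
    n_frames: int,
    sigma_F: float = 0.1,
    jump_frame: int | None = None,
    jump_size: float = 0.0,
    seed: int | np.random.Generator = 0,
    baseline: float = 2.0,
) -> np.ndarray:
    """Force readout in pN: Gaussian noise about a 2 pN baseline with an
    optional step artefact of ``jump_size`` at ``jump_frame``."""
    if sigma_F < 0:
        raise ValueError("sigma_F must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.full(n_frames, float(baseline))
    if jump_frame is not None:
        f[int(jump_frame):] += jump_size
    if sigma_F > 0:
        f += rng.normal(0.0, sigma_F, size=n_frames)
    return f


def bp_to_px(bp: np.ndarray | float, config: SimulationConfig, geometry: ScanGeometry) -> np.ndarray | float:
    """Map a bp coordinate to a (0-based, pixel-centered) x coordinate,
    with the DNA centered in the scan field."""
    span_px = config.dna_length * config.nm_per_bp / geometry.pixel_nm
    x0 = (geometry.n_x - 1 - span_px) / 2.0
    return x0 + np.asarray(bp) * config.nm_per_bp / geometry.pixel_nm


def render_scan(
    traces: list[TrueTrace],
    geometry: ScanGeometry,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    n_frames: int | None = None,
    y_jitter_px: float = 0.0,
) -> SyntheticScan:
    """Rasterize traces into a photon-count scan stack.

    Every live fluorophore is rendered as a 2-D Gaussian of SD
    ``psf_sigma_px`` (integrated expected photons ``photons_per_fluor``)
    at its mapped pixel position, on a uniform Poisson background; pixel
    values are independent Poisson draws of the expected counts.
    """
    import pandas as pd

    geometry.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_frames is None:
        n_frames = max((tr.n_frames for tr in traces), default=1)
    ny, nx = geometry.n_y, geometry.n_x
    yc = (ny - 1) / 2.0
    expected = np.full((n_frames, ny, nx), float(geometry.background_rate))
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    sig2 = geometry.psf_sigma_px**2
    rows = []
    for tid, tr in enumerate(traces):
        x_px_all = np.asarray(bp_to_px(tr.observed, config, geometry), dtype=float)
        if np.any((x_px_all < 0) | (x_px_all > nx - 1)):
            raise ValueError(f"trace {tid} falls outside the scan field")
        for k in range(min(tr.n_frames, n_frames)):
            x_px = x_px_all[k]
            y_px = yc + (rng.normal(0.0, y_jitter_px) if y_jitter_px > 0 else 0.0)
            amp = geometry.photons_per_fluor / (2.0 * np.pi * sig2)
            expected[k] += amp * np.exp(-((xx - x_px) ** 2 + (yy - y_px) ** 2) / (2.0 * sig2))
            rows.append(
                dict(trace_id=tid, frame=k, true_bp=float(tr.positions[k]),
                     observed_bp=float(tr.observed[k]), x_px=float(x_px), y_px=float(y_px))
            )
    frames = rng.poisson(expected).astype(np.int32)
    truth = pd.DataFrame(rows, columns=["trace_id", "frame", "true_bp", "observed_bp", "x_px", "y_px"])
    return SyntheticScan(frames=frames, frame_interval=config.frame_interval,
                         pixel_nm=geometry.pixel_nm, truth=truth)
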