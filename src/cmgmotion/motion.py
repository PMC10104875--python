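"""Trace quality filtering, velocity segmentation and motion statistics.

The analysis chain per trace: truncate at force-jump artefacts, apply
the QC filter ledger, Kalman-smooth the bp positions, fit piecewise
linear segments by change-point analysis (each detection inherits its
segment's slope as the instantaneous velocity v_CPA), classify the
trace as static or mobile against the fiducial-derived velocity noise,
and derive velocity, direction-persistence, processivity and positional
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changepoint import segment_constant, segment_lines, segment_linear, segment_means
from .kalman import smooth_positions
from .photobleaching import prune_small_steps

__all__ = [
    "SegmentFit",
    "FilterReport",
    "fit_linear_segments",
    "kalman_smooth",
    "classify_static_mobile",
    "drift_correct",
    "truncate_on_force_jump",
    "force_jump_frame",
    "apply_filters",
    "direction_persistence",
    "velocity_and_processivity",
    "initial_position",
    "fold_to_center_distance",
]

# canonical histogram bin widths for the derived quantities
BIN_INITIAL_POSITION_BP = 700.0
BIN_INSTANT_VELOCITY = 2.5  # bp/s
BIN_MEAN_VELOCITY = 1.0  # bp/s
BIN_V_CPA = 1.0  # bp/s
BIN_PROCESSIVITY_KBP = 0.5
BIN_ALPHA = 0.25


@dataclass
class SegmentFit:
    """Piecewise-linear change-point fit of one position-vs-time trace."""

    breakpoints: np.ndarray  # interior breakpoints, frame indices
    slopes: np.ndarray  # bp/s per segment (the v_CPA values)
    intercepts: np.ndarray  # bp, at t of the trace's first frame
    v_cpa: np.ndarray  # bp/s per frame: each frame's segment slope
    n_frames: int
    degenerate: bool = False  # trace shorter than one minimal segment

    @property
    def n_segments(self) -> int:
        return self.slopes.size

    def segment_lengths(self) -> np.ndarray:
        edges = np.concatenate(([0], self.breakpoints, [self.n_frames]))
        return np.diff(edges)


def kalman_smooth(positions_bp: np.ndarray, frame_interval: float = 1.0) -> np.ndarray:
    """Denoise a bp position series with the EM-fitted Kalman smoother.

    Falls back to the raw series when the smoother cannot converge.
    """
    return smooth_positions(np.asarray(positions_bp, dtype=float), frame_interval).smoothed


def fit_linear_segments(
    positions_bp: np.ndarray,
    frame_interval: float,
    min_size: int = 3,
    penalty: float = 0.3,
) -> SegmentFit:
    """Change-point fit of piecewise-linear motion.

    The fit is computed on positions in kbp against time in seconds, so
    the per-breakpoint ``penalty`` (default 0.3) is in kbp² of residual
    sum of squares.  Slopes are returned in bp/s.
    """
    x = np.asarray(positions_bp, dtype=float)
    n = x.size
    if n < min_size:
        return SegmentFit(
            breakpoints=np.empty(0, dtype=int),
            slopes=np.zeros(1), intercepts=np.array([x.mean() if n else 0.0]),
            v_cpa=np.zeros(n), n_frames=n, degenerate=True,
        )
    t = np.arange(n, dtype=float) * frame_interval
    y_kbp = x / 1000.0
    bkps = segment_linear(y_kbp, penalty=penalty, min_size=min_size, t=t)
    starts, slopes_kbp, icepts_kbp = segment_lines(y_kbp, bkps, t=t)
    slopes = slopes_kbp * 1000.0
    v_cpa = np.empty(n)
    edges = np.concatenate((starts, [n]))
    for k in range(slopes.size):
        v_cpa[edges[k]:edges[k + 1]] = slopes[k]
    return SegmentFit(
        breakpoints=np.asarray(bkps, dtype=int), slopes=slopes,
        intercepts=icepts_kbp * 1000.0, v_cpa=v_cpa, n_frames=n,
    )


def classify_static_mobile(fit: SegmentFit, mu_v: float, cutoff: float) -> str:
    """'mobile' iff any segment slope deviates from the drift ``mu_v`` by
    more than ``cutoff`` (canonically 5·sigma_v); otherwise 'static'."""
    if np.any(np.abs(fit.slopes - mu_v) > cutoff):
        return "mobile"
    return "static"


def drift_correct(positions_bp: np.ndarray, mu_v: float, frame_interval: float = 1.0) -> np.ndarray:
    """x_corrected(t) = x(t) - t * mu_v, time measured from the trace's
    first frame."""
    x = np.asarray(positions_bp, dtype=float)
    t = np.arange(x.size, dtype=float) * frame_interval
    return x - t * mu_v


def force_jump_frame(force: np.ndarray, sigma_F: float = 0.1, min_size: int = 4) -> int | None:
    """Frame of the first force-level jump exceeding 2*sigma_F, found by
    a piecewise-constant change-point fit; None if the force is clean.

    ``min_size`` = 4 keeps two-sample noise flukes (whose level
    difference has SD ~ sigma_F) from masquerading as jumps.
    """
    f = np.asarray(force, dtype=float)
    if f.size < 2 * min_size or sigma_F < 0:
        return None
    thr = 2.0 * sigma_F
    penalty = max(thr**2, 1e-12)
    bkps = segment_constant(f, penalty=penalty, min_size=min_size)
    starts, means = segment_means(f, bkps)
    starts, means = prune_small_steps(starts, means, thr, f.size)
    if means.size <= 1:
        return None
    return int(starts[1])


def truncate_on_force_jump(
    positions: np.ndarray, force: np.ndarray, sigma_F: float = 0.1
) -> tuple[np.ndarray, int | None]:
    """Keep only the part of a trace before the first force jump larger
    than 2*sigma_F.  Returns (possibly truncated positions, jump frame)."""
    jf = force_jump_frame(force, sigma_F)
    x = np.asarray(positions, dtype=float)
    if jf is None or jf >= x.size:
        return x, None
    return x[:jf], jf


@dataclass
class FilterReport:
    """Disposition of every input trace under the QC filter ledger."""

    dispositions: dict = field(default_factory=dict)  # key -> "kept" | "truncated_force" | "dropped_<rule>"
    counts: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return sum(1 for v in self.dispositions.values() if v.startswith("kept"))

    @property
    def n_input(self) -> int:
        return len(self.dispositions)


def apply_filters(
    traces: dict[int, np.ndarray],
    frame_interval: float,
    dna_length_bp: float,
    n_fluors: dict[int, int] | None = None,
    forces: dict[int, np.ndarray] | None = None,
    start_frames: dict[int, int] | None = None,
    sigma_F: float = 0.1,
    max_fluors: int = 5,
    bead_margin_bp: float = 1000.0,
    max_start_frame: int = 3,
    min_frames: int = 14,
) -> tuple[dict[int, np.ndarray], FilterReport]:
    """Apply the QC rules, in order, to bp position traces.

    1. truncate at the first force jump > 2*sigma_F;
    2. drop spots with more than ``max_fluors`` fluorophores (aggregates);
    3. drop traces starting or ending within ``bead_margin_bp`` of a bead;
    4. drop traces starting after frame ``max_start_frame``;
    5. omit each trace's last frame (bleaching mid-frame distorts it);
    6. retain only traces of at least ``min_frames`` frames.

    ``traces`` maps trace id -> bp positions; optional side tables give
    per-trace fluorophore counts, force series and absolute start frames.
    Returns the kept traces and a report accounting for every input.
    """
    report = FilterReport()
    kept: dict[int, np.ndarray] = {}
    counts = {k: 0 for k in
              ("input", "truncated_force", "dropped_aggregate", "dropped_near_bead",
               "dropped_late_start", "dropped_short", "kept")}
    for tid, x in traces.items():
        counts["input"] += 1
        x = np.asarray(x, dtype=float)
        disposition = "kept"
        if forces is not None and tid in forces:
            x, jf = truncate_on_force_jump(x, forces[tid], sigma_F)
            if jf is not None:
                counts["truncated_force"] += 1
                disposition = "kept_truncated_force"
        if n_fluors is not None and n_fluors.get(tid, 1) > max_fluors:
            report.dispositions[tid] = "dropped_aggregate"
            counts["dropped_aggregate"] += 1
            continue
        if x.size and (
            min(x[0], x[-1]) < bead_margin_bp or max(x[0], x[-1]) > dna_length_bp - bead_margin_bp
        ):
            report.dispositions[tid] = "dropped_near_bead"
            counts["dropped_near_bead"] += 1
            continue
        if start_frames is not None and start_frames.get(tid, 0) > max_start_frame:
            report.dispositions[tid] = "dropped_late_start"
            counts["dropped_late_start"] += 1
            continue
        x = x[:-1]  # rule 5: last frame omitted
        if x.size < min_frames:
            report.dispositions[tid] = "dropped_short"
            counts["dropped_short"] += 1
            continue
        kept[tid] = x
        report.dispositions[tid] = disposition
        counts["kept"] += 1
    report.counts = counts
    return kept, report


def direction_persistence(fits: list[SegmentFit]) -> tuple[float | None, float | None, int]:
    """Probability that consecutive CPA segments move in the same
    direction, pooled over traces; 0.5 is the random-motion expectation.

    Exactly-zero slopes are skipped.  Returns (p, SE, n_pairs); p is
    None when no trace contributes a qualifying pair.
    """
    same = 0
    total = 0
    for fit in fits:
        signs = np.sign(fit.slopes)
        signs = signs[signs != 0]
        for a, b in zip(signs[:-1], signs[1:]):
            total += 1
            if a == b:
                same += 1
    if total == 0:
        return None, None, 0
    p = same / total
    return p, float(np.sqrt(p * (1.0 - p) / total)), total


def velocity_and_processivity(
    positions_bp: np.ndarray, fit: SegmentFit, frame_interval: float, mu_v: float = 0.0
) -> dict:
    """Velocity and run-length summary of one (drift-corrected) trace.

    instantaneous: per-frame |v_CPA - mu_v| (bp/s);
    mean_velocity: |net displacement| / duration (bp/s);
    path_velocity: per-segment path length / duration (bp/s), the
    alternative reading of a time-averaged velocity;
    processivity: |net displacement| (kbp).
    """
    x = np.asarray(positions_bp, dtype=float)
    duration = (x.size - 1) * frame_interval
    net = abs(x[-1] - x[0])
    seg_t = fit.segment_lengths() * frame_interval
    path = float(np.sum(np.abs(fit.slopes - mu_v) * seg_t))
    return {
        "instantaneous": np.abs(fit.v_cpa - mu_v),
        "mean_velocity": net / duration if duration > 0 else 0.0,
        "path_velocity": path / duration if duration > 0 else 0.0,
        "processivity_kbp": net / 1000.0,
    }


def initial_position(positions_bp: np.ndarray) -> float:
    """Average bp position of the first three frames (fewer if the trace
    is shorter)."""
    x = np.asarray(positions_bp, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    return float(x[: min(3, x.size)].mean())


def fold_to_center_distance(position_bp: float, dna_length_bp: float) -> float:
    """Distance from the DNA center, in kbp."""
    return abs(position_bp - dna_length_bp / 2.0) / 1000.0
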