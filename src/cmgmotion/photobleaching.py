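"""Fluorophore counting by photobleaching step analysis.

A spot's intensity-vs-time series is fit with a piecewise-constant
change-point model (L2 cost, minimum segment length 2, penalty
``dI_min**2``).  Steps smaller in magnitude than the calibrated minimum
bleaching step ``dI_min`` are pruned smallest-first: the two levels
flanking the pruned step are merged into their length-weighted mean
(equivalently, the exact mean of the merged segment) and the remaining
steps are re-evaluated until all survive the threshold.  The number of
fluorophores is the number of retained downward steps; retained upward
steps (blinking or re-binding) are reported but never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changepoint import segment_constant, segment_means

__all__ = ["BleachResult", "correct_crosstalk", "count_bleach_steps", "spots_per_dna", "prune_small_steps"]


@dataclass
class BleachResult:
    corrected_intensity: np.ndarray
    step_frames: np.ndarray  # frame index of each retained downward step
    step_sizes: np.ndarray  # downward steps, positive ADU
    n_fluorophores: int
    upward_step_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    upward_step_sizes: np.ndarray = field(default_factory=lambda: np.empty(0))
    level_starts: np.ndarray = field(default_factory=lambda: np.zeros(1, dtype=int))
    level_means: np.ndarray = field(default_factory=lambda: np.zeros(1))
    fallback: bool = False  # series too short for the change-point fit


def correct_crosstalk(i_red: np.ndarray, i_green: np.ndarray, crosstalk_ratio: float) -> np.ndarray:
    """Remove green-channel bleed-through from a red intensity series:
    I_corrected = I_r - I_g * ratio, floored at 0."""
    if crosstalk_ratio < 0:
        raise ValueError("crosstalk_ratio must be >= 0")
    i_red = np.asarray(i_red, dtype=float)
    i_green = np.asarray(i_green, dtype=float)
    if i_red.shape != i_green.shape:
        raise ValueError("red and green series must have the same length")
    return np.maximum(i_red - i_green * crosstalk_ratio, 0.0)


def prune_small_steps(
    starts: np.ndarray, means: np.ndarray, min_step: float, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Merge away level changes smaller than ``min_step``, smallest first.

    ``starts``/``means`` describe a piecewise-constant fit of a series of
    ``n_samples`` points (segment start indices and segment means).
    Merging replaces the two levels flanking the pruned step by their
    length-weighted mean — the exact mean of the merged segment — and all
    remaining steps are re-evaluated.  Returns the pruned (starts, means).
    """
    starts = list(np.asarray(starts, dtype=int))
    means = list(np.asarray(means, dtype=float))
    while len(means) > 1:
        steps = np.abs(np.diff(means))
        k = int(np.argmin(steps))
        if steps[k] >= min_step:
            break
        edges = [*starts, n_samples]
        w = [b - a for a, b in zip(edges[:-1], edges[1:])]
        means[k] = (w[k] * means[k] + w[k + 1] * means[k + 1]) / (w[k] + w[k + 1])
        del means[k + 1], starts[k + 1]
    return np.asarray(starts, dtype=int), np.asarray(means)


def count_bleach_steps(
    intensity: np.ndarray,
    dI_min: float,
    min_size: int = 2,
    penalty: float | None = None,
) -> BleachResult:
    """Count photobleaching steps in an intensity series.

    ``penalty`` defaults to ``dI_min**2``.  Series shorter than
    ``2 * min_size`` samples cannot support the change-point fit and
    fall back to a single-threshold count (flagged).
    """
    intensity = np.asarray(intensity, dtype=float)
    if dI_min <= 0:
        raise ValueError("dI_min must be positive")
    if penalty is None:
        penalty = dI_min**2
    if intensity.size < 2 * min_size:
        n = int(max(0.0, np.floor((intensity.max() - intensity.min()) / dI_min))) if intensity.size else 0
        return BleachResult(
            corrected_intensity=intensity,
            step_frames=np.empty(0, dtype=int), step_sizes=np.empty(0),
            n_fluorophores=n, fallback=True,
        )
    bkps = segment_constant(intensity, penalty=penalty, min_size=min_size)
    starts, means = segment_means(intensity, bkps)
    starts, means = prune_small_steps(starts, means, dI_min, intensity.size)
    deltas = np.diff(means)
    step_frames = starts[1:]
    down = deltas < 0
    return BleachResult(
        corrected_intensity=intensity,
        step_frames=step_frames[down],
        step_sizes=-deltas[down],
        n_fluorophores=int(down.sum()),
        upward_step_frames=step_frames[~down],
        upward_step_sizes=deltas[~down],
        level_starts=starts,
        level_means=means,
    )


def spots_per_dna(bleach_results: list[BleachResult]) -> tuple[int, list[int], int]:
    """Per-DNA summary: (number of spots, fluorophores per spot, total).

    Takes the bleach results of the (already filtered) spots found on a
    single DNA molecule.
    """
    per_spot = [r.n_fluorophores for r in bleach_results]
    return len(per_spot), per_spot, int(sum(per_spot))
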