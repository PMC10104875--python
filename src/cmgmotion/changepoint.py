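"""Exact change-point segmentation by penalized optimal partitioning.

Two cost models are provided, matching the two uses in the pipeline:

* piecewise-constant mean with an L2 cost — used to find photobleaching
  steps in intensity-vs-time series and level shifts in force signals;
* piecewise-linear fit with an L2 cost on the per-segment least-squares
  residuals — used to segment position-vs-time traces into runs of
  constant velocity.

Both minimize  sum_j C(segment_j) + beta * (number of breakpoints)
exactly, by O(n^2) dynamic programming over all admissible last-segment
start points.  Per-segment costs are evaluated in O(1) from prefix sums,
so the whole fit is quadratic in the series length — trajectories here
are tens to a few hundred frames, for which exactness is cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "segment_constant",
    "segment_linear",
    "segment_means",
    "segment_lines",
]


def _check_series(y: np.ndarray, min_size: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if y.size < min_size:
        raise ValueError(f"series of length {y.size} shorter than min_size={min_size}")
    return y


def _optimal_partition(cost: np.ndarray, n: int, penalty: float, min_size: int) -> list[int]:
    """DP over precomputed segment costs cost[i, j] for segment y[i:j].

    Returns sorted interior breakpoints (segment start indices, excluding 0).
    """
    # F[t] = best penalized cost of y[:t]; one penalty per breakpoint.
    F = np.full(n + 1, np.inf)
    F[0] = -penalty  # cancels the penalty charged for the first segment
    prev = np.zeros(n + 1, dtype=int)
    for t in range(min_size, n + 1):
        starts = np.arange(0, t - min_size + 1)
        totals = F[starts] + cost[starts, t] + penalty
        k = int(np.argmin(totals))  # ties -> smallest start index
        F[t] = totals[k]
        prev[t] = starts[k]
    bkps = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            bkps.append(s)
        t = s
    return sorted(bkps)


def segment_constant(y: np.ndarray, penalty: float, min_size: int = 2) -> list[int]:
    """Breakpoints of the best piecewise-constant fit to ``y``.

    Cost of a segment is its sum of squared deviations from the segment
    mean; each additional breakpoint costs ``penalty``.
    """
    y = _check_series(y, min_size)
    n = y.size
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    cnt = (j - i).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = (s2[None, :] - s2[:, None]) - (s1[None, :] - s1[:, None]) ** 2 / np.where(cnt > 0, cnt, 1.0)
    sse[cnt <= 0] = np.inf
    np.fill_diagonal(sse, 0.0)
    return _optimal_partition(sse, n, penalty, min_size)


def segment_linear(
    y: np.ndarray, penalty: float, min_size: int = 3, t: np.ndarray | None = None
) -> list[int]:
    """Breakpoints of the best piecewise-linear fit to ``y`` against ``t``.

    Cost of a segment is the residual sum of squares of its own
    least-squares line.  ``t`` defaults to the sample index.
    """
    y = _check_series(y, min_size)
    n = y.size
    if t is None:
        t = np.arange(n, dtype=float)
    else:
        t = np.asarray(t, dtype=float)
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")

    def cum(v):
        return np.concatenate(([0.0], np.cumsum(v)))

    St, Sy = cum(t), cum(y)
    Stt, Syy, Sty = cum(t * t), cum(y * y), cum(t * y)
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    cnt = (j - i).astype(float)
    d = lambda S: S[None, :] - S[:, None]  # noqa: E731
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(cnt > 0, cnt, 1.0)
        ctt = d(Stt) - d(St) ** 2 / m
        cyy = d(Syy) - d(Sy) ** 2 / m
        cty = d(Sty) - d(St) * d(Sy) / m
        sse = cyy - np.where(ctt > 0, cty**2 / np.where(ctt > 0, ctt, 1.0), 0.0)
    sse = np.maximum(sse, 0.0)  # guard tiny negative round-off
    sse[cnt <= 0] = np.inf
    np.fill_diagonal(sse, 0.0)
    return _optimal_partition(sse, n, penalty, min_size)


def segment_means(y: np.ndarray, bkps: list[int]) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment (start_index, mean) for breakpoints from segment_constant."""
    y = np.asarray(y, dtype=float)
    edges = [0, *bkps, y.size]
    starts = np.array(edges[:-1], dtype=int)
    means = np.array([y[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return starts, means


def segment_lines(
    y: np.ndarray, bkps: list[int], t: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment (start_index, slope, intercept) from segment_linear output."""
    y = np.asarray(y, dtype=float)
    if t is None:
        t = np.arange(y.size, dtype=float)
    edges = [0, *bkps, y.size]
    starts, slopes, intercepts = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        ts, ys = t[a:b], y[a:b]
        if b - a == 1:
            sl, ic = 0.0, float(ys[0])
        else:
            sl, ic = np.polyfit(ts, ys, 1)
        starts.append(a)
        slopes.append(float(sl))
        intercepts.append(float(ic))
    return np.array(starts, dtype=int), np.array(slopes), np.array(intercepts)
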