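"""Spot detection, subpixel localization, LAP track linking and
two-channel colocalization for confocal scan stacks.

Detection uses a Laplacian-of-Gaussian blob detector at a single scale
``sigma = radius_px / sqrt(2)`` (so a spot of the detection radius
maximizes the scale-normalized response), refined by 1-D Gaussian fits
to the x- and y-intensity projections of a window around each blob.
Frame-to-frame linking solves the linear assignment problem with
squared-distance costs and birth/death alternatives, followed by a
gap-closing pass over track ends and starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, linear_sum_assignment
from skimage.feature import blob_log

__all__ = [
    "Detection",
    "Trace",
    "detect_spots",
    "localize_subpixel",
    "link_traces",
    "colocalize",
    "ColocalizationResult",
]


@dataclass
class Detection:
    frame: int
    x_px: float
    y_px: float
    intensity: float
    channel: str = "green"
    centroid_fallback: bool = False


@dataclass
class Trace:
    """Time-ordered detections of one diffraction-limited spot."""

    trace_id: int
    detections: list[Detection] = field(default_factory=list)
    positions_bp: np.ndarray | None = None  # set after px->bp calibration
    scan_id: str = ""

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def x_px(self) -> np.ndarray:
        return np.array([d.x_px for d in self.detections])

    @property
    def y_px(self) -> np.ndarray:
        return np.array([d.y_px for d in self.detections])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([d.intensity for d in self.detections])

    @property
    def n_frames(self) -> int:
        return len(self.detections)

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame


def _gauss(x, amp, mu, sigma, offset):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + offset


def localize_subpixel(
    frame: np.ndarray, x0: float, y0: float, radius_px: float = 5.0
) -> tuple[float, float, bool]:
    """Refine a coarse detection by Gaussian fits to the window's x- and
    y-projections.  Returns (x, y, centroid_fallback)."""
    ny, nx = frame.shape
    r = int(np.ceil(radius_px))
    xlo, xhi = max(0, int(round(x0)) - r), min(nx, int(round(x0)) + r + 1)
    ylo, yhi = max(0, int(round(y0)) - r), min(ny, int(round(y0)) + r + 1)
    win = frame[ylo:yhi, xlo:xhi].astype(float)
    fallback = False
    out = []
    for proj, lo in ((win.sum(axis=0), xlo), (win.sum(axis=1), ylo)):
        coords = lo + np.arange(proj.size, dtype=float)
        total = proj.sum()
        if total <= 0 or np.ptp(proj) == 0:
            out.append(coords.mean())
            fallback = True
            continue
        centroid = float(np.sum(coords * proj) / total)
        try:
            amp0 = float(np.ptp(proj))
            popt, _ = curve_fit(
                _gauss, coords, proj,
                p0=(amp0, centroid, max(radius_px / 2.0, 1.0), float(proj.min())),
                maxfev=2000,
            )
            mu = float(popt[1])
            if not (coords[0] - 1 <= mu <= coords[-1] + 1):
                raise RuntimeError("fit outside window")
            out.append(mu)
        except (RuntimeError, ValueError):
            out.append(centroid)
            fallback = True
    return out[0], out[1], fallback


def detect_spots(
    frame: np.ndarray,
    radius_px: float = 5.0,
    threshold: float = 0.5,
    frame_index: int = 0,
    channel: str = "green",
    merge_dist_px: float = 1.0,
) -> list[Detection]:
    """LoG blob detection on one frame, with subpixel refinement.

    ``threshold`` applies to the scale-normalized LoG response (ADU).
    Duplicate blobs closer than ``merge_dist_px`` are merged, keeping
    the brighter one.  An all-zero frame yields an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not np.any(frame > 0):
        return []
    sigma = radius_px / np.sqrt(2.0)
    blobs = blob_log(frame, min_sigma=sigma, max_sigma=sigma, num_sigma=1, threshold=threshold)
    dets: list[Detection] = []
    ny, nx = frame.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    for by, bx, _ in blobs:
        x, y, fb = localize_subpixel(frame, bx, by, radius_px)
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= radius_px**2
        inten = float(frame[mask].sum())
        dets.append(Detection(frame=frame_index, x_px=x, y_px=y, intensity=inten,
                              channel=channel, centroid_fallback=fb))
    # merge near-duplicates, keep the brighter
    dets.sort(key=lambda d: -d.intensity)
    kept: list[Detection] = []
    for d in dets:
        if all((d.x_px - k.x_px) ** 2 + (d.y_px - k.y_px) ** 2 >= merge_dist_px**2 for k in kept):
            kept.append(d)
    kept.sort(key=lambda d: (d.x_px, d.y_px))
    return kept


def _lap_pairs(
    prev: list[Detection], curr: list[Detection], max_dist_px: float
) -> list[tuple[int, int]]:
    """Minimal-cost assignment between two detection sets with
    birth/death alternatives priced at max_dist^2; returns linked index
    pairs (i_prev, j_curr)."""
    n, m = len(prev), len(curr)
    if n == 0 or m == 0:
        return []
    big = 1e12
    b = max_dist_px**2
    cost = np.full((n + m, m + n), big)
    for i, p in enumerate(prev):
        for j, c in enumerate(curr):
            d2 = (p.x_px - c.x_px) ** 2 + (p.y_px - c.y_px) ** 2
            if d2 <= max_dist_px**2:
                cost[i, j] = d2
    cost[np.arange(n), m + np.arange(n)] = b  # deaths
    cost[n + np.arange(m), np.arange(m)] = b  # births
    cost[n:, m:] = 0.0  # dummy-dummy
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if i < n and j < m and cost[i, j] < big]


def link_traces(
    detections_by_frame: dict[int, list[Detection]] | list[list[Detection]],
    max_dist_px: float = 6.0,
    max_gap_frames: int = 3,
) -> list[Trace]:
    """Link per-frame detections into traces.

    Two passes: (1) frame-to-frame LAP linking with squared-distance
    costs, links beyond ``max_dist_px`` forbidden; (2) gap closing that
    joins a track end to a later track start when the frame gap is at
    most ``max_gap_frames`` missing frames and the distance is within
    ``max_dist_px``.  Every detection belongs to exactly one trace.
    """
    if isinstance(detections_by_frame, dict):
        by_frame = dict(detections_by_frame)
    else:
        by_frame = {f: list(ds) for f, ds in enumerate(detections_by_frame)}
    frames = sorted(by_frame)
    # sort detections deterministically so linking is input-order invariant
    for f in frames:
        by_frame[f] = sorted(by_frame[f], key=lambda d: (d.x_px, d.y_px, -d.intensity))

    tracks: list[list[Detection]] = []
    open_by_det: dict[int, int] = {}  # id(detection) -> track index
    prev_frame = None
    for f in frames:
        curr = by_frame[f]
        if prev_frame is not None and f == prev_frame + 1:
            prev = by_frame[prev_frame]
            pairs = _lap_pairs(prev, curr, max_dist_px)
            linked_curr = set()
            for i, j in pairs:
                ti = open_by_det.get(id(prev[i]))
                if ti is not None:
                    tracks[ti].append(curr[j])
                    open_by_det[id(curr[j])] = ti
                    linked_curr.add(j)
            for j, d in enumerate(curr):
                if j not in linked_curr:
                    tracks.append([d])
                    open_by_det[id(d)] = len(tracks) - 1
        else:
            for d in curr:
                tracks.append([d])
                open_by_det[id(d)] = len(tracks) - 1
        prev_frame = f

    tracks = _close_gaps(tracks, max_dist_px, max_gap_frames)
    tracks.sort(key=lambda tr: (tr[0].frame, tr[0].x_px, tr[0].y_px))
    return [Trace(trace_id=i, detections=tr) for i, tr in enumerate(tracks)]


def _close_gaps(
    tracks: list[list[Detection]], max_dist_px: float, max_gap_frames: int
) -> list[list[Detection]]:
    changed = True
    while changed:
        changed = False
        ends = [(ti, tr[-1]) for ti, tr in enumerate(tracks) if tr]
        starts = [(ti, tr[0]) for ti, tr in enumerate(tracks) if tr]
        cand = []
        for ei, (ti, e) in enumerate(ends):
            for si, (tj, s) in enumerate(starts):
                if ti == tj:
                    continue
                gap = s.frame - e.frame - 1  # missing frames between them
                if 1 <= gap <= max_gap_frames:
                    d2 = (e.x_px - s.x_px) ** 2 + (e.y_px - s.y_px) ** 2
                    if d2 <= max_dist_px**2:
                        cand.append((d2, e.frame, s.x_px, ti, tj))
        if not cand:
            break
        # greedy by cost; ties by smaller frame index, then smaller x
        cand.sort()
        used_ends, used_starts = set(), set()
        merges = []
        for d2, _, _, ti, tj in cand:
            if ti in used_ends or tj in used_starts:
                continue
            merges.append((ti, tj))
            used_ends.add(ti)
            used_starts.add(tj)
        if merges:
            changed = True
            # apply merges; chains are resolved over while-loop iterations
            for ti, tj in merges:
                if tracks[ti] and tracks[tj] and tracks[tj][0].frame > tracks[ti][-1].frame:
                    tracks[ti].extend(tracks[tj])
                    tracks[tj] = []
            tracks = [tr for tr in tracks if tr]
    return [tr for tr in tracks if tr]


@dataclass
class ColocalizationResult:
    fraction: float | None  # None when there are no reference spots
    n_colocalized: int
    n_reference: int
    se: float | None
    per_frame: dict[int, float]
    pairs: list[tuple[int, int]]  # (trace_id_A, trace_id_B)


def colocalize(
    traces_a: list[Trace], traces_b: list[Trace], max_sep_px: float = 2.0,
    min_overlap_frac: float = 0.5,
) -> ColocalizationResult:
    """Fraction of A-spots with a colocalized B-spot.

    A frame-level colocalization is a Euclidean separation strictly
    below ``max_sep_px``; an A trace counts as colocalized when at
    least ``min_overlap_frac`` of its frames have a B spot that close.
    An empty A set yields ``fraction=None`` (undefined, distinct from 0).
    """
    b_by_frame: dict[int, list[tuple[int, float, float]]] = {}
    for tb in traces_b:
        for d in tb.detections:
            b_by_frame.setdefault(d.frame, []).append((tb.trace_id, d.x_px, d.y_px))

    per_frame_hits: dict[int, list[int]] = {}
    pairs = set()
    n_coloc = 0
    for ta in traces_a:
        hit_frames = 0
        for d in ta.detections:
            best = None
            for tid, bx, by in b_by_frame.get(d.frame, []):
                sep = np.hypot(d.x_px - bx, d.y_px - by)
                if sep < max_sep_px and (best is None or sep < best[0]):
                    best = (sep, tid)
            per_frame_hits.setdefault(d.frame, []).append(1 if best else 0)
            if best:
                hit_frames += 1
                pairs.add((ta.trace_id, best[1]))
        if ta.n_frames and hit_frames / ta.n_frames >= min_overlap_frac:
            n_coloc += 1
    n_ref = len(traces_a)
    if n_ref == 0:
        return ColocalizationResult(None, 0, 0, None, {}, [])
    frac = n_coloc / n_ref
    se = float(np.sqrt(frac * (1.0 - frac) / n_ref))
    per_frame = {f: float(np.mean(v)) for f, v in sorted(per_frame_hits.items())}
    return ColocalizationResult(frac, n_coloc, n_ref, se, per_frame, sorted(pairs))
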