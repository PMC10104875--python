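"""Spot detection, localization, LAP linking and colocalization."""

import itertools

import numpy as np
import pytest

from cmgmotion.detection import (
    Detection,
    Trace,
    _lap_pairs,
    colocalize,
    detect_spots,
    link_traces,
    localize_subpixel,
)
from cmgmotion.synthetic import ScanGeometry, SimulationConfig, render_scan, simulate_traces


def det(frame, x, y=9.0, inten=100.0):
    return Detection(frame=frame, x_px=x, y_px=y, intensity=inten)


class TestDetect:
    def test_zero_frame_no_detections(self):
        assert detect_spots(np.zeros((18, 60))) == []

    def test_single_spot_found_and_localized(self, gaussian_frame):
        frame = gaussian_frame([(80.3, 8.7)])
        dets = detect_spots(frame)
        assert len(dets) == 1
        assert dets[0].x_px == pytest.approx(80.3, abs=0.05)
        assert dets[0].y_px == pytest.approx(8.7, abs=0.05)

    def test_two_spots_ten_px_apart(self, gaussian_frame):
        dets = detect_spots(gaussian_frame([(70.0, 9.0), (80.0, 9.0)]))
        assert len(dets) == 2

    def test_intensity_is_photon_sum_in_radius(self, gaussian_frame):
        frame = gaussian_frame([(80.0, 9.0)], amp_photons=100.0)
        d = detect_spots(frame)[0]
        # ~95% of a sigma=2 Gaussian falls within r=5 px
        assert 85.0 < d.intensity < 101.0

    def test_recall_and_false_positives_on_rendered_scans(self):
        cfg = SimulationConfig(motion_model="static", sigma_x=0.0, n_traces=1, fixed_length=100)
        geom = ScanGeometry(photons_per_fluor=100.0, background_rate=0.1)
        scan = render_scan(simulate_traces(cfg, seed=5), geom, cfg, seed=9)
        truth = scan.truth
        hits = fps = 0
        for f in range(100):
            row = truth[truth.frame == f].iloc[0]
            dets = detect_spots(scan.frames[f], frame_index=f)
            if any(np.hypot(d.x_px - row.x_px, d.y_px - row.y_px) <= 1.0 for d in dets):
                hits += 1
            fps += sum(1 for d in dets if np.hypot(d.x_px - row.x_px, d.y_px - row.y_px) > 2.0)
        assert hits >= 99
        assert fps <= 1


class TestLocalize:
    def test_symmetric_spot_at_integer_center(self, gaussian_frame):
        frame = gaussian_frame([(80.0, 9.0)])
        x, y, fb = localize_subpixel(frame, 80, 9)
        assert (x, y) == (pytest.approx(80.0, abs=1e-6), pytest.approx(9.0, abs=1e-6))
        assert not fb

    def test_flat_window_falls_back_to_centroid(self):
        x, y, fb = localize_subpixel(np.ones((18, 160)), 80, 9)
        assert fb
        assert x == pytest.approx(80.0, abs=0.5)


class TestLinking:
    def test_single_moving_spot_one_trace(self):
        frames = {f: [det(f, 10.0 + f)] for f in range(20)}
        traces = link_traces(frames)
        assert len(traces) == 1
        assert traces[0].n_frames == 20

    def test_parallel_spots_never_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            frames = {}
            for f in range(15):
                xa = 20.0 + f + rng.normal(0, 0.5)
                xb = 40.0 + f + rng.normal(0, 0.5)
                frames[f] = [det(f, xa, inten=100), det(f, xb, inten=200)]
            traces = link_traces(frames)
            assert len(traces) == 2
            for tr in traces:
                assert np.all(np.abs(np.diff(tr.x_px)) < 6)
                assert np.ptp(tr.x_px) < 20  # stayed on its own lane

    def test_gap_closing_rules(self):
        # absent 2 frames, returns within 6 px -> one trace
        frames = {0: [det(0, 50.0)], 1: [det(1, 51.0)], 4: [det(4, 53.0)], 5: [det(5, 54.0)]}
        assert len(link_traces(frames, max_gap_frames=3)) == 1
        # absent 4 frames -> two traces
        frames = {0: [det(0, 50.0)], 1: [det(1, 51.0)], 6: [det(6, 53.0)], 7: [det(7, 54.0)]}
        assert len(link_traces(frames, max_gap_frames=3)) == 2

    def test_no_link_beyond_max_distance(self):
        frames = {0: [det(0, 10.0)], 1: [det(1, 20.0)]}
        assert len(link_traces(frames, max_dist_px=6.0)) == 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        frames = {f: [det(f, 10.0 + f + rng.normal(0, 0.3)),
                      det(f, 30.0 - f + rng.normal(0, 0.3)),
                      det(f, 60.0 + rng.normal(0, 0.3))] for f in range(10)}
        ref = [(tr.start_frame, tuple(np.round(tr.x_px, 6))) for tr in link_traces(frames)]
        shuffled = {f: list(reversed(ds)) for f, ds in frames.items()}
        got = [(tr.start_frame, tuple(np.round(tr.x_px, 6))) for tr in link_traces(shuffled)]
        assert sorted(ref) == sorted(got)

    @pytest.mark.parametrize("seed", range(10))
    def test_lap_matches_bruteforce_assignment(self, seed):
        """Frame-pair linking equals the exhaustive minimal-cost matching."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 7), rng.integers(1, 7)
        prev = [det(0, x, y) for x, y in zip(rng.uniform(0, 40, n), rng.uniform(0, 15, n))]
        curr = [det(1, x, y) for x, y in zip(rng.uniform(0, 40, m), rng.uniform(0, 15, m))]
        max_dist = 6.0
        b = max_dist**2

        def cost_of(pairs):
            c = 0.0
            for i, j in pairs:
                d2 = (prev[i].x_px - curr[j].x_px) ** 2 + (prev[i].y_px - curr[j].y_px) ** 2
                if d2 > max_dist**2:
                    return np.inf
                c += d2
            return c + b * (len(prev) - len(pairs)) + b * (len(curr) - len(pairs))

        best = np.inf
        for k in range(0, min(n, m) + 1):
            for subset in itertools.combinations(range(n), k):
                for perm in itertools.permutations(range(m), k):
                    best = min(best, cost_of(list(zip(subset, perm))))
        got = cost_of(_lap_pairs(prev, curr, max_dist))
        assert got == pytest.approx(best, abs=1e-9)


class TestColocalize:
    def _traces(self, coords, start_id=0):
        return [Trace(trace_id=start_id + i, detections=[det(f, x, y) for f, (x, y) in enumerate(cs)])
                for i, cs in enumerate(coords)]

    def test_identical_coordinates_fraction_one(self):
        a = self._traces([[(10, 9)] * 5])
        b = self._traces([[(10, 9)] * 5], start_id=100)
        res = colocalize(a, b)
        assert res.fraction == 1.0

    def test_distant_spots_fraction_zero(self):
        a = self._traces([[(10, 9)] * 5])
        b = self._traces([[(15, 9)] * 5], start_id=100)
        assert colocalize(a, b).fraction == 0.0

    def test_empty_reference_is_undefined_not_zero(self):
        b = self._traces([[(10, 9)] * 5])
        res = colocalize([], b)
        assert res.fraction is None

    def test_fraction_and_se_on_constructed_population(self):
        # 13 of 65 reference spots get a partner within 1 px -> p = 0.2, SE = 0.0496
        a = self._traces([[(float(5 + 4 * i), 9.0)] * 3 for i in range(65)])
        b = self._traces([[(float(5 + 4 * i) + 0.5, 9.0)] * 3 for i in range(13)], start_id=100)
        res = colocalize(a, b)
        assert res.fraction == pytest.approx(0.2)
        assert res.se == pytest.approx(0.0496, abs=5e-4)
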