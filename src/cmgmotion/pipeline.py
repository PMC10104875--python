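"""End-to-end orchestration of the trace-analysis stages.

A run is driven by a flat ``RunConfig`` (every threshold pre-filled
with its calibrated default) and proceeds, as toggled:

    simulate -> [render -> detect -> track] -> calibrate ->
    count bleaching steps -> filter -> motion -> msd

All randomness derives from the single config seed through named
per-stage substreams, so any stage rerun is reproducible; every run
emits a manifest with per-stage row counts and the config snapshot.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationSet, estimate_drift_noise, estimate_localization_error
from .detection import detect_spots, link_traces
from .io import write_calibration, write_keyvalues, read_keyvalues, write_scan
from .motion import (
    apply_filters, classify_static_mobile, drift_correct, fit_linear_segments,
    fold_to_center_distance, initial_position, kalman_smooth, velocity_and_processivity,
)
from .msd import classify_alpha, compute_msd, estimate_D, fit_alpha
from .photobleaching import count_bleach_steps
from .synthetic import (
    ScanGeometry, SimulationConfig, render_scan, simulate_bleach_series,
    simulate_force, simulate_traces,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "analyze_positions"]


@dataclass
class RunConfig:
    """Flat, serializable configuration of a full pipeline run."""

    # stage toggles
    simulate: bool = True
    render: bool = False
    validate: bool = False
    # simulation
    motion_model: str = "diffusive"
    n_traces: int = 64
    n_fiducial_traces: int = 50
    D: float = 1.5e-3  # kb^2/s
    v: float = 5.0  # bp/s
    sigma_x: float = 72.0  # bp
    mean_lifetime: float = 25.0  # frames
    frame_interval: float = 5.0  # s
    dna_length: float = 23600.0  # bp
    drift_v: float = 0.0  # bp/s
    # thresholds (calibrated defaults)
    radius_px: float = 5.0
    log_threshold: float = 0.5
    max_link_px: float = 6.0
    max_gap: int = 3
    min_frames: int = 14
    cutoff_sigma: float = 5.0
    penalty: float = 0.3
    tau_max_frac: float = 0.33
    sigma_F: float = 0.1
    max_fluors: int = 5
    # bleaching simulation
    mu_step: float = 300.0
    sigma_step: float = 30.0
    noise_sd: float = 20.0
    # bookkeeping
    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_file(self, path: str | Path) -> None:
        write_keyvalues(path, dataclasses.asdict(self))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = read_keyvalues(path)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.type == "bool":
                kwargs[f.name] = v in ("True", "true", "1")
            elif f.type == "int":
                kwargs[f.name] = int(v)
            elif f.type == "float":
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the run seed.

    Uses CRC32 of the stage name (stable across processes, unlike
    ``hash``), mixed into a SeedSequence with the run seed.
    """
    name_key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return int(np.random.SeedSequence([base_seed, name_key]).generate_state(1)[0] % (2**31))


def analyze_positions(
    positions_bp: np.ndarray,
    frame_interval: float,
    cal: CalibrationSet,
    penalty: float = 0.3,
    tau_max_frac: float = 0.33,
) -> dict:
    """Full per-trace motion analysis of one filtered bp trace.

    Kalman-smooth, CPA-segment, classify static/mobile against the
    mobility cutoff, and (for mobile traces) fit the anomalous exponent
    and diffusion coefficient on the drift-corrected positions.
    """
    x = np.asarray(positions_bp, dtype=float)
    xc = drift_correct(x, cal.mu_v, frame_interval)
    sm = kalman_smooth(xc, frame_interval)
    fit = fit_linear_segments(sm, frame_interval, penalty=penalty)
    label = classify_static_mobile(fit, 0.0, cal.mobility_cutoff)
    out = {
        "segments": fit,
        "label": label,
        "initial_bp": initial_position(x),
        "n_frames": x.size,
    }
    vp = velocity_and_processivity(xc, fit, frame_interval, mu_v=0.0)
    out.update({k: vp[k] for k in ("mean_velocity", "path_velocity", "processivity_kbp")})
    out["v_cpa"] = fit.v_cpa
    if label == "mobile" and x.size >= 3:
        curve = compute_msd(xc, frame_interval)
        af = fit_alpha(curve, cal.sigma_x, tau_max_frac)
        out["alpha"] = af.alpha
        out["motion_class"] = "confined" if af.degenerate else classify_alpha(af.alpha)
        if out["motion_class"] == "free_diffusive":
            D, flagged = estimate_D(curve, cal.sigma_x)
            out["D_kb2_per_s"] = D
            out["D_flagged"] = flagged
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if not config.simulate:
        raise FileNotFoundError(
            "no input scans were given and simulation is disabled; enable "
            "`simulate` or run the detect/track stages on your own scan stack"
        )

    sim_cfg = SimulationConfig(
        motion_model=config.motion_model, D=config.D, v=config.v, sigma_x=config.sigma_x,
        mean_lifetime=config.mean_lifetime, frame_interval=config.frame_interval,
        n_traces=config.n_traces, dna_length=config.dna_length, drift_v=config.drift_v,
    )
    traces = simulate_traces(sim_cfg, seed=stage_seed(config.seed, "simulate"))
    manifest["stages"]["simulate"] = {"n_traces": len(traces)}

    if config.render:
        geom = ScanGeometry()
        renderable = [tr for tr in traces[: min(len(traces), 8)]]
        scan = render_scan(renderable, geom, sim_cfg, seed=stage_seed(config.seed, "render"))
        write_scan(out_dir / "scan.tiff", scan, out_dir / "scan_truth.tsv")
        dets = {f: detect_spots(scan.frames[f], config.radius_px, config.log_threshold, frame_index=f)
                for f in range(scan.frames.shape[0])}
        linked = link_traces(dets, config.max_link_px, config.max_gap)
        manifest["stages"]["detect_track"] = {
            "n_frames": int(scan.frames.shape[0]),
            "n_detections": int(sum(len(v) for v in dets.values())),
            "n_traces": len(linked),
        }

    # calibration from simulated static fiducials
    rng_cal = stage_seed(config.seed, "calibrate")
    fid_cfg = replace(sim_cfg, motion_model="static", n_traces=config.n_fiducial_traces,
                      fixed_length=25, drift_v=config.drift_v)
    fiducials = simulate_traces(fid_cfg, seed=rng_cal)
    fid_fits = [fit_linear_segments(kalman_smooth(tr.observed, config.frame_interval),
                                    config.frame_interval, penalty=config.penalty)
                for tr in fiducials]
    mu_v, sigma_v = estimate_drift_noise(fid_fits)
    sigma_x_est = estimate_localization_error([tr.observed for tr in fiducials],
                                              mu_v, config.frame_interval)
    cal = CalibrationSet(mu_v=mu_v, sigma_v=sigma_v, sigma_x=sigma_x_est,
                         mu_dI=config.mu_step, sigma_dI=config.sigma_step,
                         sigma_F=config.sigma_F, cutoff_sigma=config.cutoff_sigma)
    write_calibration(out_dir / "calibration.txt", cal)
    manifest["stages"]["calibrate"] = {
        "n_fiducials": len(fiducials), "mu_v": mu_v, "sigma_v": sigma_v,
        "sigma_x": sigma_x_est, "cutoff": cal.mobility_cutoff,
    }

    # bleaching-step counting on per-trace intensity series
    rng_bleach = np.random.default_rng(stage_seed(config.seed, "bleach"))
    n_fluors_true = {i: int(rng_bleach.integers(1, 4)) for i in range(len(traces))}
    n_fluors = {}
    bleach_rows = []
    for i, tr in enumerate(traces):
        series = simulate_bleach_series(
            n_fluors_true[i], config.mu_step, config.sigma_step,
            config.mean_lifetime, config.noise_sd, seed=rng_bleach,
            n_frames=max(tr.n_frames, 4),
        )
        res = count_bleach_steps(series, cal.dI_min)
        n_fluors[i] = res.n_fluorophores
        bleach_rows.append(dict(trace_id=i, n_true=n_fluors_true[i],
                                n_fluorophores=res.n_fluorophores,
                                step_frames=",".join(map(str, res.step_frames)),
                                step_sizes=",".join(f"{s:.1f}" for s in res.step_sizes)))
    pd.DataFrame(bleach_rows).to_csv(out_dir / "bleach_counts.tsv", sep="\t", index=False)
    manifest["stages"]["bleach"] = {"n_series": len(bleach_rows)}

    # QC filters
    rng_force = np.random.default_rng(stage_seed(config.seed, "force"))
    forces = {i: simulate_force(tr.n_frames, config.sigma_F, seed=rng_force)
              for i, tr in enumerate(traces)}
    pos = {i: tr.observed for i, tr in enumerate(traces)}
    kept, report = apply_filters(
        pos, config.frame_interval, config.dna_length, n_fluors=n_fluors,
        forces=forces, sigma_F=config.sigma_F, max_fluors=config.max_fluors,
        min_frames=config.min_frames,
    )
    manifest["stages"]["filter"] = dict(report.counts)

    # motion + anomalous diffusion analysis
    rows = []
    for tid, x in kept.items():
        res = analyze_positions(x, config.frame_interval, cal,
                                penalty=config.penalty, tau_max_frac=config.tau_max_frac)
        rows.append(dict(
            trace_id=tid, n_frames=res["n_frames"], label=res["label"],
            true_model=traces[tid].motion_model,
            n_segments=res["segments"].n_segments,
            mean_velocity=res["mean_velocity"],
            processivity_kbp=res["processivity_kbp"],
            initial_bp=res["initial_bp"],
            center_distance_kbp=fold_to_center_distance(res["initial_bp"], config.dna_length),
            alpha=res.get("alpha", np.nan),
            motion_class=res.get("motion_class", ""),
            D_kb2_per_s=res.get("D_kb2_per_s", np.nan),
        ))
    motion_table = pd.DataFrame(rows)
    motion_table.to_csv(out_dir / "motion_summary.tsv", sep="\t", index=False)
    manifest["stages"]["motion"] = {
        "n_analyzed": len(rows),
        "n_mobile": int((motion_table["label"] == "mobile").sum()) if len(rows) else 0,
    }

    if config.validate:
        from .validation import run_alpha_error_study

        tab = run_alpha_error_study(seed=stage_seed(config.seed, "validate"))
        pd.DataFrame(tab.to_rows()).to_csv(out_dir / "alpha_error_table.tsv", sep="\t", index=False)
        manifest["stages"]["validate"] = {"qualifying_min_length": tab.qualifying_min_length}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    config.to_file(out_dir / "run_config.txt")
    return manifest
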