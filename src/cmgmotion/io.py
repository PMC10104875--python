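"""Table and scan I/O.

Tables are plain TSV with a header; trace tables follow the
spot-tracking layout (scan_id, trace_id, frame, x_px, y_px, intensity,
channel) and round-trip losslessly, preserving unknown columns.
Calibration sets and run configurations serialize as flat key=value
text files.  Scan stacks are multi-page TIFFs with a ground-truth TSV
sidecar when synthetic.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationSet

TRACE_COLUMNS = ["scan_id", "trace_id", "frame", "x_px", "y_px", "intensity", "channel"]

__all__ = [
    "read_traces",
    "write_traces",
    "traces_to_table",
    "table_to_traces",
    "write_calibration",
    "read_calibration",
    "write_scan",
    "read_scan",
    "write_keyvalues",
    "read_keyvalues",
]


def write_traces(path: str | Path, table: pd.DataFrame) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trace table missing required column(s): {', '.join(missing)}")
    table.to_csv(path, sep="\t", index=False)


def read_traces(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in TRACE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path.name}: missing required column(s): {', '.join(missing)}")
        n_cols = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_cols:
                raise ValueError(f"{path.name}: malformed row at line {lineno}")
    table = pd.read_csv(path, sep="\t")
    for col, kind in (("frame", int), ("x_px", float), ("y_px", float), ("intensity", float)):
        try:
            table[col] = table[col].astype(kind)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path.name}: column {col!r} is not numeric") from exc
    return table


def traces_to_table(traces, scan_id: str = "") -> pd.DataFrame:
    rows = []
    for tr in traces:
        for d in tr.detections:
            rows.append(dict(scan_id=scan_id or tr.scan_id, trace_id=tr.trace_id,
                             frame=d.frame, x_px=d.x_px, y_px=d.y_px,
                             intensity=d.intensity, channel=d.channel))
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def table_to_traces(table: pd.DataFrame):
    from .detection import Detection, Trace

    traces = []
    for (scan_id, tid), grp in table.groupby(["scan_id", "trace_id"], sort=True):
        grp = grp.sort_values("frame")
        dets = [Detection(frame=int(r.frame), x_px=float(r.x_px), y_px=float(r.y_px),
                          intensity=float(r.intensity), channel=str(r.channel))
                for r in grp.itertuples()]
        traces.append(Trace(trace_id=int(tid), detections=dets, scan_id=str(scan_id)))
    return traces


def write_keyvalues(path: str | Path, values: dict) -> None:
    with open(path, "w") as fh:
        for k, v in values.items():
            fh.write(f"{k}={v}\n")


def read_keyvalues(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out


_CAL_FIELDS = [f.name for f in dataclasses.fields(CalibrationSet) if f.name != "residuals_bp"]


def write_calibration(path: str | Path, cal: CalibrationSet) -> None:
    write_keyvalues(path, {k: repr(getattr(cal, k)) for k in _CAL_FIELDS})


def read_calibration(path: str | Path) -> CalibrationSet:
    raw = read_keyvalues(path)
    kwargs = {k: float(raw[k]) for k in _CAL_FIELDS if k in raw}
    cal = CalibrationSet(**kwargs)
    cal.validate()
    return cal


def write_scan(path: str | Path, scan, truth_path: str | Path | None = None) -> None:
    """Write a scan stack as a multi-page TIFF (+ ground-truth TSV)."""
    tifffile.imwrite(str(path), np.asarray(scan.frames, dtype=np.int32),
                     metadata={"frame_interval_s": scan.frame_interval,
                               "pixel_nm": scan.pixel_nm})
    if truth_path is not None and getattr(scan, "truth", None) is not None:
        scan.truth.to_csv(truth_path, sep="\t", index=False)


def read_scan(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))
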