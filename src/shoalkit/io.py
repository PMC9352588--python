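"""File I/O for the pipeline's fixed formats.

Units are fixed per format and validated at load: tracks are CSV in
dish-centred mm and seconds (columns ``t_s,x_mm,y_mm[,heading_rad]``),
trace matrices are delimited CSV (rows = ROIs) with the sampling rate
in a JSON sidecar, cell points are CSV in µm, and volumes are
multi-page TIFF with a JSON sidecar carrying the voxel spacing in µm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import Track
from .tuning import TraceSet

__all__ = [
    "read_track", "write_track",
    "read_traces", "write_traces",
    "read_volume", "write_volume",
    "read_schedule", "write_schedule",
]


def read_track(path) -> Track:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t_s", "x_mm", "y_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: track file missing columns {sorted(missing)}")
    heading = df["heading_rad"].to_numpy() if "heading_rad" in df.columns else None
    return Track(df["t_s"].to_numpy(), df["x_mm"].to_numpy(),
                 df["y_mm"].to_numpy(), heading)


def write_track(track: Track, path) -> None:
    track.to_csv(path)


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def read_traces(path) -> TraceSet:
    """Delimited ROI x time matrix; sampling rate from the JSON sidecar."""
    mat = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(_sidecar(path).read_text())
    coords = np.asarray(meta["coords_um"]) if "coords_um" in meta else None
    return TraceSet(mat, float(meta["rate_hz"]), coords)


def write_traces(traces: TraceSet, path) -> None:
    np.savetxt(path, traces.traces, delimiter=",", fmt="%.6g")
    meta = {"rate_hz": traces.rate_hz}
    if traces.coords_um is not None:
        meta["coords_um"] = np.asarray(traces.coords_um).tolist()
    _sidecar(path).write_text(json.dumps(meta))


def read_volume(path) -> tuple[np.ndarray, float]:
    """Multi-page TIFF volume plus voxel spacing (µm) from the JSON sidecar."""
    vol = tifffile.imread(path)
    side = _sidecar(path)
    spacing = float(json.loads(side.read_text())["spacing_um"]) if side.exists() else 1.0
    return np.asarray(vol), spacing


def write_volume(volume: np.ndarray, spacing_um: float, path) -> None:
    tifffile.imwrite(path, np.asarray(volume, dtype=np.float32),
                     photometric="minisblack")
    _sidecar(path).write_text(json.dumps({"spacing_um": spacing_um}))


def read_schedule(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"onset_s", "duration_s", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: schedule missing columns {sorted(missing)}")
    return df


def write_schedule(schedule: pd.DataFrame, path) -> None:
    schedule.to_csv(path, index=False)
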