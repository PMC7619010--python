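"""Readers and writers for the pipeline's file formats.

Linescans: multi-page TIFF (one page per line block) or HDF5 (dataset
"linescan" with attrs ``dt``, ``dx``); ground truth as a JSON sidecar.
Trajectories: CSV with columns time_s, x_mm, y_mm, heading_rad, trial_id,
contrast_pct (plus fish_id and drift_sign).  Quantal/event series: CSV with
time_s, amplitude, quanta.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .behavior import TrajectoryRecording
from .quantal import LinescanRecording, QuantalSeries

__all__ = [
    "write_linescan_h5",
    "read_linescan_h5",
    "write_linescan_tiff",
    "read_linescan_tiff",
    "write_ground_truth",
    "read_ground_truth",
    "write_trajectories",
    "read_trajectories",
    "write_quantal_series",
    "read_quantal_series",
]


def write_linescan_h5(path, recording: LinescanRecording) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("linescan", data=recording.values)
        ds.attrs["dt"] = recording.dt
        ds.attrs["dx"] = recording.dx
        for k, v in recording.metadata.items():
            if isinstance(v, (int, float, str, np.integer, np.floating)):
                ds.attrs[f"meta_{k}"] = v


def read_linescan_h5(path) -> LinescanRecording:
    with h5py.File(path, "r") as f:
        ds = f["linescan"]
        meta = {
            k[5:]: (v.item() if hasattr(v, "item") else v)
            for k, v in ds.attrs.items()
            if k.startswith("meta_")
        }
        return LinescanRecording(
            values=ds[()], dt=float(ds.attrs["dt"]), dx=float(ds.attrs["dx"]),
            metadata=meta,
        )


def write_linescan_tiff(path, recording: LinescanRecording) -> None:
    tifffile.imwrite(
        path,
        recording.values.astype(np.float32),
        metadata={"dt": recording.dt, "dx": recording.dx, **{
            k: v for k, v in recording.metadata.items()
            if isinstance(v, (int, float, str))
        }},
    )


def read_linescan_tiff(path) -> LinescanRecording:
    with tifffile.TiffFile(path) as tf:
        values = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    dt = float(meta.pop("dt"))
    dx = float(meta.pop("dx"))
    meta.pop("shape", None)
    return LinescanRecording(values=np.asarray(values, float), dt=dt, dx=dx,
                             metadata=dict(meta))


def write_ground_truth(path, train) -> None:
    payload = {
        "event_times": np.asarray(train.event_times).tolist(),
        "event_quanta": np.asarray(train.event_quanta).tolist(),
        "duration": float(train.duration),
        "regime_id": train.regime_id,
        "seed": train.seed,
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path):
    from .synth import GroundTruthTrain

    d = json.loads(Path(path).read_text())
    return GroundTruthTrain(
        event_times=np.asarray(d["event_times"], float),
        event_quanta=np.asarray(d["event_quanta"], int),
        duration=d["duration"],
        regime_id=d.get("regime_id", ""),
        seed=d.get("seed"),
    )


def write_trajectories(path, recordings: list[TrajectoryRecording]) -> None:
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": rec.time,
                    "x_mm": rec.x,
                    "y_mm": rec.y,
                    "heading_rad": rec.heading,
                    "trial_id": rec.metadata.get("trial_id", 0),
                    "contrast_pct": rec.metadata.get("contrast", np.nan),
                    "fish_id": rec.metadata.get("fish_id", -1),
                    "drift_sign": rec.metadata.get("drift_sign", 1.0),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[TrajectoryRecording]:
    df = pd.read_csv(path)
    out = []
    for (fish, trial), g in df.groupby(["fish_id", "trial_id"], sort=True):
        out.append(
            TrajectoryRecording(
                time=g["time_s"].to_numpy(),
                x=g["x_mm"].to_numpy(),
                y=g["y_mm"].to_numpy(),
                heading=g["heading_rad"].to_numpy(),
                metadata={
                    "fish_id": int(fish),
                    "trial_id": int(trial),
                    "contrast": float(g["contrast_pct"].iloc[0]),
                    "drift_sign": float(g["drift_sign"].iloc[0]),
                },
            )
        )
    return out


def write_quantal_series(path, series: QuantalSeries) -> None:
    pd.DataFrame(
        {"time_s": series.times, "quanta": series.quanta}
    ).to_csv(path, index=False)


def read_quantal_series(path, quantal_size: float = 1.0) -> QuantalSeries:
    df = pd.read_csv(path)
    return QuantalSeries(
        times=df["time_s"].to_numpy(),
        quanta=df["quanta"].to_numpy(),
        quantal_size=quantal_size,
    )
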