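"""Readers and writers for the tool's delimited-text formats.

All tabular data are plain CSV with mandatory headers; trial metadata and
calibration state are YAML sidecars.  Timestamps are seconds as floats and
sample indexing is 0-based throughout.

Formats
-------
trial.csv       ``sensor_id,segment,side,t,gx,gy,gz,ax,ay,az`` (raw counts)
trial.meta.yaml ``fs, calibration_window, turn_index, seed, ...``
calib.yaml      per sensor: gyro offset (deg/s) and accel norm (counts)
segments.csv    ``t,segment,side,theta_deg``
joints.csv      ``t,side,hip_deg,knee_deg,ankle_deg,hip_vel,knee_vel,ankle_vel``
report.yaml     metric name -> value
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationState
from .kinematics import JointAngleSeries
from .synthetic import SENSOR_LAYOUT, RawImuTrial

log = logging.getLogger("imugait")

__all__ = [
    "read_trial",
    "write_trial",
    "read_calibration",
    "write_calibration",
    "write_segments",
    "read_segments",
    "write_joints",
    "read_joints",
    "write_report",
    "read_sus_responses",
]

_TRIAL_COLUMNS = ["sensor_id", "segment", "side", "t",
                  "gx", "gy", "gz", "ax", "ay", "az"]


def _meta_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_trial(trial: RawImuTrial, path) -> Path:
    """Write a trial as CSV plus a ``<name>.meta.yaml`` sidecar."""
    path = Path(path)
    frames = []
    keys = [k for k in SENSOR_LAYOUT if k in trial.sensors]
    keys += sorted(k for k in trial.sensors if k not in keys)
    for sensor_id, key in enumerate(keys):
        segment, side = key
        ch = trial.sensors[key]
        frames.append(pd.DataFrame({
            "sensor_id": sensor_id, "segment": segment, "side": side,
            "t": trial.t,
            "gx": ch["gyro"][:, 0], "gy": ch["gyro"][:, 1], "gz": ch["gyro"][:, 2],
            "ax": ch["acc"][:, 0], "ay": ch["acc"][:, 1], "az": ch["acc"][:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.6f")
    meta = {k: v for k, v in trial.meta.items() if k != "truth_joints"}
    meta.update(fs=float(trial.fs),
                calibration_window=float(trial.calibration_window),
                turn_index=(None if trial.turn_index is None
                            else int(trial.turn_index)))
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_trial(path, expected_layout=SENSOR_LAYOUT) -> RawImuTrial:
    """Read and validate a trial CSV (+ sidecar metadata if present).

    Rejects malformed rows and non-monotone timestamps; missing sensors from
    ``expected_layout`` only raise a warning (downstream joint computations
    will refuse on their own if a needed segment is absent).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing_cols = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    bad = df[_TRIAL_COLUMNS[3:]].isna().any(axis=1)
    if bad.any():
        # +2: header line and 1-based file lines
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 2}")

    meta_path = _meta_path(path)
    meta = (yaml.safe_load(meta_path.read_text()) or {}) if meta_path.exists() else {}
    sensors, t_ref = {}, None
    for (segment, side), g in df.groupby(["segment", "side"], sort=True):
        g = g.sort_index()
        t = g["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: non-monotone timestamps for sensor "
                             f"({segment}, {side})")
        if t_ref is None:
            t_ref = t
        elif len(t) != len(t_ref) or not np.allclose(t, t_ref, atol=1e-9):
            raise ValueError(f"{path}: sensors disagree on the time base")
        sensors[(segment, side)] = {
            "gyro": g[["gx", "gy", "gz"]].to_numpy(dtype=float).astype(np.int32),
            "acc": g[["ax", "ay", "az"]].to_numpy(dtype=float).astype(np.int32),
        }
    if t_ref is None:
        raise ValueError(f"{path}: no samples")
    for key in expected_layout:
        if key not in sensors:
            log.warning("%s: sensor %s missing from trial", path, key)

    fs = float(meta.get("fs", round(1.0 / np.median(np.diff(t_ref)))))
    trial = RawImuTrial(
        t=t_ref, sensors=sensors, fs=fs,
        calibration_window=float(meta.get("calibration_window", 10.0)),
        turn_index=meta.get("turn_index"),
        meta={k: v for k, v in meta.items()
              if k not in ("fs", "calibration_window", "turn_index")},
    )
    trial.validate()
    return trial


def write_calibration(states: Mapping, path) -> Path:
    """Serialize per-sensor calibration states as key: value text."""
    path = Path(path)
    doc = {}
    for (segment, side), st in sorted(states.items()):
        doc[f"{segment}_{side}"] = {
            "gyro_offset": [float(v) for v in st.gyro_offset],
            "acc_norm": float(st.acc_norm),
            "gyro_scale": float(st.gyro_scale),
            "acc_scale": float(st.acc_scale),
            "window": float(st.window),
        }
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def read_calibration(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    states = {}
    for name, d in doc.items():
        segment, side = name.rsplit("_", 1)
        states[(segment, side)] = CalibrationState(
            gyro_offset=np.asarray(d["gyro_offset"], dtype=float),
            acc_norm=float(d["acc_norm"]),
            gyro_scale=float(d["gyro_scale"]),
            acc_scale=float(d["acc_scale"]),
            window=float(d["window"]),
        )
    return states


def write_segments(angles: Mapping, t, path) -> Path:
    """Write (segment, side) -> theta series as long CSV."""
    path = Path(path)
    frames = [pd.DataFrame({"t": t, "segment": seg, "side": side,
                            "theta_deg": theta})
              for (seg, side), theta in sorted(angles.items())]
    pd.concat(frames, ignore_index=True)[
        ["t", "segment", "side", "theta_deg"]].to_csv(
        path, index=False, float_format="%.6f")
    return path


def read_segments(path) -> tuple[dict, np.ndarray]:
    df = pd.read_csv(path)
    out, t = {}, None
    for (seg, side), g in df.groupby(["segment", "side"], sort=True):
        out[(seg, side)] = g["theta_deg"].to_numpy(dtype=float)
        t = g["t"].to_numpy(dtype=float)
    return out, t


def write_joints(joints: Mapping[str, JointAngleSeries], path) -> Path:
    """Write per-side joint series (angles + angular velocities)."""
    path = Path(path)
    frames = []
    for side in sorted(joints):
        j = joints[side]
        frames.append(pd.DataFrame({
            "t": j.t, "side": side,
            "hip_deg": j.hip, "knee_deg": j.knee, "ankle_deg": j.ankle,
            "hip_vel": j.angular_velocity("hip"),
            "knee_vel": j.angular_velocity("knee"),
            "ankle_vel": j.angular_velocity("ankle"),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.6f")
    return path


def read_joints(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for side, g in df.groupby("side", sort=True):
        fs = round(1.0 / float(np.median(np.diff(g["t"].to_numpy()))))
        out[side] = JointAngleSeries(
            hip=g["hip_deg"].to_numpy(dtype=float),
            knee=g["knee_deg"].to_numpy(dtype=float),
            ankle=g["ankle_deg"].to_numpy(dtype=float),
            fs=fs, side=side,
            velocity={j: g[f"{j}_vel"].to_numpy(dtype=float)
                      for j in ("hip", "knee", "ankle")},
        )
    return out


def write_report(report: Mapping, path) -> Path:
    """Serialize a (possibly nested) metric report as key: value text."""
    def clean(v):
        if isinstance(v, Mapping):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.floating, float)):
            return round(float(v), 9)
        if isinstance(v, np.integer):
            return int(v)
        return v

    path = Path(path)
    path.write_text(yaml.safe_dump(clean(dict(report)), sort_keys=True))
    return path


def read_sus_responses(path) -> list:
    """One row per user, 10 integer columns (header optional)."""
    df = pd.read_csv(path)
    if df.shape[1] < 10:
        raise ValueError("SUS responses need 10 item columns")
    return [tuple(int(v) for v in row[:10]) for row in df.to_numpy()]
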