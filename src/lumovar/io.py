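"""Tabular I/O for trials, cohorts and configuration.

Two CSV dialects are read and written (header row mandatory, SI units):

* markers CSV — columns ``time`` then ``<marker>_{x,y,z}`` for the six
  markers ``thorax_1..3`` / ``pelvis_1..3``, coordinates in meters;
* angles CSV — columns ``time, flexion_extension, lateral_bending,
  axial_rotation`` in degrees, uniformly sampled.

C3D containers are not supported by this build; export capture data to the
markers CSV dialect instead.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import AngleSeries, MarkerTrial, THORAX_MARKERS, PELVIS_MARKERS, KinematicsError

__all__ = [
    "read_markers_csv",
    "write_markers_csv",
    "read_angles_csv",
    "write_angles_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_yaml",
    "dump_yaml",
]

_ANGLE_COLUMNS = ("flexion_extension", "lateral_bending", "axial_rotation")


def read_markers_csv(path) -> MarkerTrial:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message path
        raise KinematicsError(f"cannot parse marker file {path}: {exc}") from exc
    if "time" not in df.columns:
        raise KinematicsError(f"{path}: missing mandatory 'time' column")
    positions = {}
    for marker in (*THORAX_MARKERS, *PELVIS_MARKERS):
        cols = [f"{marker}_{ax}" for ax in "xyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise KinematicsError(f"{path}: missing columns {missing}")
        positions[marker] = df[cols].to_numpy(dtype=float)
    return MarkerTrial(timestamps=df["time"].to_numpy(dtype=float), positions=positions)


def write_markers_csv(trial: MarkerTrial, path) -> None:
    data = {"time": trial.timestamps}
    for marker, pos in trial.positions.items():
        for j, ax in enumerate("xyz"):
            data[f"{marker}_{ax}"] = pos[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_angles_csv(path) -> AngleSeries:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise KinematicsError(f"cannot parse angle file {path}: {exc}") from exc
    missing = [c for c in ("time", *_ANGLE_COLUMNS) if c not in df.columns]
    if missing:
        raise KinematicsError(f"{path}: missing columns {missing}")
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], atol=1e-6):
        raise KinematicsError(f"{path}: angle series must be uniformly sampled")
    return AngleSeries(
        angles=df[list(_ANGLE_COLUMNS)].to_numpy(dtype=float),
        sample_rate=1.0 / dt[0],
    )


def write_angles_csv(series: AngleSeries, path) -> None:
    df = pd.DataFrame({"time": series.time})
    for j, col in enumerate(_ANGLE_COLUMNS):
        df[col] = series.angles[:, j]
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
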