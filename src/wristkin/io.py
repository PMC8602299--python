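"""Plain-text file round-tripping: IMU/wrist CSVs, calibration and report JSON.

All formats are simple headered CSVs in SI units (see the column lists below);
writes use full float precision so write -> read round trips are lossless to
1e-12 or better.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import WristTrajectory
from .errors import FormatError
from .imu import ImuStream, MagCalibration

IMU_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]
WRIST_COLUMNS = ["t", "px", "py", "pz"]

_FLOAT_FMT = "%.17g"


def load_imu_csv(path: str | Path, sample_rate: float | None = None) -> ImuStream:
    """Read an IMU CSV with columns t,gx,gy,gz,ax,ay,az,mx,my,mz.

    Units: seconds, rad/s, m/s² (specific force), magnetometer in any
    consistent units.  ``sample_rate`` defaults to the median timestamp rate.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"IMU CSV {path} missing column(s): {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if sample_rate is None:
        if len(t) < 2:
            raise FormatError(f"IMU CSV {path} has fewer than 2 samples")
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return ImuStream(
        t=t,
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        mag=df[["mx", "my", "mz"]].to_numpy(dtype=float),
        sample_rate=sample_rate,
    )


def write_imu_csv(stream: ImuStream, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.gyro, stream.accel, stream.mag]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_wrist_csv(path: str | Path) -> WristTrajectory:
    """Read a wrist trajectory CSV with columns t,px,py,pz (s, cm)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WRIST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"wrist CSV {path} missing column(s): {', '.join(missing)}")
    return WristTrajectory(
        t=df["t"].to_numpy(dtype=float),
        p=df[["px", "py", "pz"]].to_numpy(dtype=float),
    )


def write_wrist_csv(traj: WristTrajectory, path: str | Path) -> None:
    df = pd.DataFrame(np.column_stack([traj.t, traj.p]), columns=WRIST_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_mag_calibration(path: str | Path) -> MagCalibration:
    """Read a calibration JSON {hard_iron: [3], soft_iron: [[3]x3]}."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return MagCalibration(
            hard_iron=np.asarray(data["hard_iron"], dtype=float),
            soft_iron=np.asarray(data["soft_iron"], dtype=float),
        )
    except KeyError as exc:
        raise FormatError(f"calibration JSON {path} missing key {exc}") from exc


def write_mag_calibration(cal: MagCalibration, path: str | Path, **extra) -> None:
    data = {
        "hard_iron": cal.hard_iron.tolist(),
        "soft_iron": cal.soft_iron.tolist(),
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def load_annotations(path: str | Path) -> list[tuple[str, float, float]]:
    """Read an annotation CSV of (label, t_start, t_end) rows."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("label", "t_start", "t_end") if c not in df.columns]
    if missing:
        raise FormatError(f"annotation CSV {path} missing column(s): {', '.join(missing)}")
    return [
        (str(r.label), float(r.t_start), float(r.t_end))
        for r in df.itertuples(index=False)
    ]


def write_annotations(rows: list[tuple[str, float, float]], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["label", "t_start", "t_end"]).to_csv(path, index=False)


def write_json(data: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, default=default)
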