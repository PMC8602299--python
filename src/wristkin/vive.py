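"""6-DoF tracker pose ingestion: frame conversion, dropout repair, resampling.

Consumer VR trackers report position + orientation in the base-station
("lighthouse") frame, conventionally Y-up.  This module converts such streams
to the package's Z-up world frame, fills brief occlusion dropouts by spherical
interpolation, and resamples two trackers onto a common timeline so the
kinematic chain can consume synchronized orientations.  Positions are carried
through for completeness but the chain uses orientations only: wrist position
is a function of the arm and forearm orientations alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import rotations as rot
from .errors import FormatError, InvalidInputError, NoValidDataError
from .imu import OrientationTrajectory

__all__ = [
    "PoseStream",
    "load_pose_stream",
    "write_pose_stream",
    "to_world",
    "repair_dropouts",
    "resample_orientation",
    "common_timeline",
]

POSE_COLUMNS = ["t", "x", "y", "z", "qw", "qx", "qy", "qz"]

# Y-up native -> Z-up world change of basis: X<-x, Y<- -z, Z<-y
# (a +90 degree rotation about X, determinant +1).
_C_Y_UP = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
_Q_Y_UP = rot.from_matrix(_C_Y_UP)


@dataclass
class PoseStream:
    """Timestamped 6-DoF tracker poses in a named frame.

    ``valid`` flags samples the tracking system actually resolved; occluded
    samples are kept in place (flagged, not dropped) so gaps stay explicit.
    """

    t: np.ndarray
    position: np.ndarray
    q: np.ndarray
    valid: np.ndarray
    native_frame: str = "y_up"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if self.position.shape != (n, 3) or self.q.shape != (n, 4) or self.valid.shape != (n,):
            raise InvalidInputError("pose stream channel shapes do not match t")
        if not np.all(np.diff(self.t) > 0):
            raise FormatError("pose timestamps must be strictly increasing")
        if self.native_frame not in ("y_up", "z_up"):
            raise InvalidInputError(f"unknown native frame {self.native_frame!r}")
        norms = np.linalg.norm(self.q[self.valid], axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
            self.q = self.q.copy()
            self.q[self.valid] /= norms[:, None]

    def __len__(self) -> int:
        return len(self.t)


def load_pose_stream(path: str | Path, native_frame: str = "y_up") -> PoseStream:
    """Read a pose CSV with columns t,x,y,z,qw,qx,qy,qz[,valid].

    Rows flagged ``valid=0`` are kept but marked invalid.  Missing columns or
    non-monotone timestamps raise :class:`FormatError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pose CSV {path} missing column(s): {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise FormatError(f"pose CSV {path} has non-monotone timestamps")
    valid = (
        df["valid"].to_numpy(dtype=float) > 0.5
        if "valid" in df.columns
        else np.ones(len(df), dtype=bool)
    )
    return PoseStream(
        t=t,
        position=df[["x", "y", "z"]].to_numpy(dtype=float),
        q=df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float),
        valid=valid,
        native_frame=native_frame,
    )


def write_pose_stream(stream: PoseStream, path: str | Path) -> None:
    """Write a pose stream as CSV (full float precision round trips)."""
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.position, stream.q, stream.valid.astype(int)]),
        columns=POSE_COLUMNS + ["valid"],
    )
    df.to_csv(path, index=False, float_format="%.17g")


def to_world(stream: PoseStream) -> PoseStream:
    """Convert a native-frame pose stream to the Z-up world frame.

    Y-up input is mapped by the fixed right-handed change of basis
    X<-x, Y<- -z, Z<-y; orientations are composed with the same frame rotation.
    Z-up input passes through unchanged.
    """
    if stream.native_frame == "z_up":
        return stream
    pos = stream.position @ _C_Y_UP.T
    q = rot.compose(_Q_Y_UP, stream.q)
    return replace(stream, position=pos, q=q, native_frame="z_up")


def repair_dropouts(stream: PoseStream, max_gap: float = 0.2) -> OrientationTrajectory:
    """Fill brief invalid runs by slerp between flanking valid orientations.

    Gaps no longer than ``max_gap`` seconds are interpolated; longer gaps are
    left as explicit masked intervals (``valid=False``, nearest-neighbour
    orientation as a placeholder).  The output carries only time and
    orientation — tracker positions are not used downstream.
    """
    if not stream.valid.any():
        raise NoValidDataError("pose stream contains no valid samples")
    t = stream.t
    q = stream.q.copy()
    valid = stream.valid.copy()
    n = len(t)
    idx_valid = np.flatnonzero(stream.valid)

    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and not valid[j + 1]:
            j += 1
        # flanking valid samples
        left = idx_valid[idx_valid < i]
        right = idx_valid[idx_valid > j]
        if len(left) and len(right):
            a, b = int(left[-1]), int(right[0])
            if t[b] - t[a] <= max_gap:
                frac = (t[i : j + 1] - t[a]) / (t[b] - t[a])
                q[i : j + 1] = rot.slerp(q[a], q[b], frac)
                valid[i : j + 1] = True
            else:
                q[i : j + 1] = q[a]  # placeholder; stays masked
        elif len(left):
            q[i : j + 1] = q[int(left[-1])]
        else:
            q[i : j + 1] = q[int(right[0])]
        i = j + 1

    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    return OrientationTrajectory(t=t.copy(), q=q, valid=valid if not valid.all() else None)


def resample_orientation(traj: OrientationTrajectory, t_new: np.ndarray) -> OrientationTrajectory:
    """Slerp an orientation trajectory onto a new timeline.

    ``t_new`` must lie within the original time span.  Validity is carried
    over: a new sample is valid only if both bracketing source samples are.
    """
    t_new = np.asarray(t_new, dtype=float)
    t = traj.t
    if t_new[0] < t[0] - 1e-9 or t_new[-1] > t[-1] + 1e-9:
        raise InvalidInputError("resample timeline extends beyond the recording")
    hi = np.clip(np.searchsorted(t, t_new, side="right"), 1, len(t) - 1)
    lo = hi - 1
    span = t[hi] - t[lo]
    frac = np.clip((t_new - t[lo]) / span, 0.0, 1.0)
    q_new = np.empty((len(t_new), 4))
    for k in range(len(t_new)):  # pairwise slerp keeps sign continuity local
        q_new[k] = rot.slerp(traj.q[lo[k]], traj.q[hi[k]], float(frac[k]))
    mask = traj.valid_mask
    valid_new = mask[lo] & mask[hi]
    return OrientationTrajectory(
        t=t_new.copy(), q=q_new, valid=None if valid_new.all() else valid_new
    )


def common_timeline(
    a: OrientationTrajectory, b: OrientationTrajectory, rate: float = 100.0
) -> tuple[OrientationTrajectory, OrientationTrajectory]:
    """Resample two trajectories onto a shared uniform timeline at ``rate`` Hz."""
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if t1 <= t0:
        raise InvalidInputError("trajectories do not overlap in time")
    n = int(np.floor((t1 - t0) * rate)) + 1
    t_new = t0 + np.arange(n) / rate
    return resample_orientation(a, t_new), resample_orientation(b, t_new)
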