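"""End-to-end tracking pipelines: sensor streams in, wrist trajectory out.

These wrappers chain the per-module stages in the documented order and return
a structured run log recording every automatic decision (windows, gains, bias
and heading corrections) so a run is auditable and reproducible.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

import numpy as np

from . import rotations as rot
from .chain import (
    BaselineCalibration,
    FECalibration,
    LimbModel,
    WristTrajectory,
    calibrate_fe,
    remove_baseline,
    wrist_position,
)
from .imu import (
    FilterConfig,
    ImuStream,
    MagCalibration,
    OrientationTrajectory,
    apply_mag_calibration,
    estimate_gyro_bias,
    fuse_orientation,
    prepend_rest,
)
from .vive import PoseStream, common_timeline, repair_dropouts, to_world

__all__ = ["track_imu", "track_pose", "baseline_and_fe"]


def _fuse_one(
    stream: ImuStream,
    config: FilterConfig,
    rest_window: tuple[float, float],
    mag_cal: MagCalibration | None,
    log: dict[str, Any],
    tag: str,
) -> OrientationTrajectory:
    if mag_cal is not None:
        stream = apply_mag_calibration(stream, mag_cal)
    bias = estimate_gyro_bias(stream, rest_window)
    stream = replace(stream, gyro=stream.gyro - bias)
    sl = stream.window(*rest_window)
    q0 = rot.orientation_from_accel_mag(
        stream.accel[sl].mean(axis=0), stream.mag[sl].mean(axis=0)
    )
    padded, offset = prepend_rest(stream, rest_window, config)
    log[f"gyro_bias_{tag}"] = bias.tolist()
    log[f"prepend_samples_{tag}"] = int(offset)
    return fuse_orientation(padded, config, q0, prepend_offset=offset)


def baseline_and_fe(
    arm: OrientationTrajectory,
    fa: OrientationTrajectory,
    limb: LimbModel,
    rest_window: tuple[float, float],
    fe_window: tuple[float, float] | None,
    log: dict[str, Any],
) -> tuple[BaselineCalibration, FECalibration | None]:
    """Shared calibration tail of both pipelines."""
    _, q0_arm, u_arm = remove_baseline(arm, rest_window, limb.nominal_axis_arm)
    _, q0_fa, u_fa = remove_baseline(fa, rest_window, limb.nominal_axis_fa)
    base = BaselineCalibration(q0_arm=q0_arm, q0_fa=q0_fa, u_arm=u_arm, u_fa=u_fa)
    fe: FECalibration | None = None
    if fe_window is not None:
        fe = calibrate_fe(arm, fa, fe_window)
        yaw = rot.to_rotvec(fe.heading_correction)[2]
        log["fe_window"] = list(fe_window)
        log["heading_correction_deg"] = float(np.rad2deg(yaw))
        log["hinge_alignment_deg"] = fe.alignment_deg
    else:
        log["heading_correction_deg"] = 0.0
    log["u_arm"] = u_arm.tolist()
    log["u_fa"] = u_fa.tolist()
    return base, fe


def track_imu(
    arm_stream: ImuStream,
    fa_stream: ImuStream,
    limb: LimbModel,
    *,
    config: FilterConfig | None = None,
    rest_window: tuple[float, float] | None = None,
    fe_window: tuple[float, float] | None = None,
    mag_cal_arm: MagCalibration | None = None,
    mag_cal_fa: MagCalibration | None = None,
) -> tuple[WristTrajectory, dict[str, Any]]:
    """Full IMU method: calibrate, fuse, remove baseline, run the chain.

    ``rest_window`` defaults to the first ``config.rest_duration`` seconds.
    Returns the wrist trajectory (cm, world frame) and a run log.
    """
    config = config or FilterConfig()
    if rest_window is None:
        rest_window = (float(arm_stream.t[0]), float(arm_stream.t[0]) + config.rest_duration)
    log: dict[str, Any] = {
        "mode": "imu",
        "rest_window": list(rest_window),
        "run_gain": config.run_gain,
        "init_gain": config.init_gain,
        "prepend_total": config.prepend_total,
        "mag_yaw_only": config.mag_yaw_only,
    }
    arm = _fuse_one(arm_stream, config, rest_window, mag_cal_arm, log, "arm")
    fa = _fuse_one(fa_stream, config, rest_window, mag_cal_fa, log, "fa")
    base, fe = baseline_and_fe(arm, fa, limb, rest_window, fe_window, log)
    traj = wrist_position(arm, fa, limb, base, fe)
    return traj, log


def track_pose(
    arm_stream: PoseStream,
    fa_stream: PoseStream,
    limb: LimbModel,
    *,
    rest_window: tuple[float, float],
    fe_window: tuple[float, float] | None = None,
    max_gap: float = 0.2,
    rate: float = 100.0,
) -> tuple[WristTrajectory, dict[str, Any]]:
    """Full tracker method: world frame, dropout repair, resample, chain."""
    log: dict[str, Any] = {
        "mode": "pose",
        "rest_window": list(rest_window),
        "max_gap": max_gap,
        "resample_rate": rate,
    }
    arm = repair_dropouts(to_world(arm_stream), max_gap=max_gap)
    fa = repair_dropouts(to_world(fa_stream), max_gap=max_gap)
    log["masked_intervals_arm"] = arm.masked_intervals()
    log["masked_intervals_fa"] = fa.masked_intervals()
    arm, fa = common_timeline(arm, fa, rate=rate)
    base, fe = baseline_and_fe(arm, fa, limb, rest_window, fe_window, log)
    traj = wrist_position(arm, fa, limb, base, fe)
    return traj, log
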