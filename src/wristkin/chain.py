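"""Two-segment upper-limb kinematic chain.

Wrist position relative to the shoulder is the sum of the rotated segment
vectors::

    p(t) = L_arm * R(q_arm(t)) u_arm  +  L_fa * R(q_hc) R(q_fa(t)) u_fa

where ``u_arm``/``u_fa`` are the limb long-axis directions *in each sensor's
frame* and ``q_hc`` is an optional one-time heading correction aligning the
two sensors' world frames.  The shoulder is treated as a fixed point, so
compensatory trunk movements are factored out by construction.

Two calibration steps make exact sensor mounting irrelevant:

* **baseline orientation removal** (:func:`remove_baseline`): with the limb
  hanging vertically at rest, the limb axis in the sensor frame is *derived*
  as ``u = R(q0)^T (0,0,-1)`` from the mean rest orientation ``q0``; any
  mounting rotation about the limb's long axis is absorbed into ``u``.
* **passive flexion-extension (FE) calibration** (:func:`calibrate_fe`): the
  elbow hinge axis observed by each sensor during passive elbow FE determines
  a yaw offset between the two sensors' world frames; for IMUs sharing
  magnetic north (or trackers sharing a lighthouse frame) the correction is a
  refinement and defaults to identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import rotations as rot
from .errors import (
    InsufficientExcursionError,
    InvalidInputError,
    SynchronizationError,
    UnstableBaselineError,
)
from .imu import OrientationTrajectory

__all__ = [
    "LimbModel",
    "BaselineCalibration",
    "FECalibration",
    "WristTrajectory",
    "remove_baseline",
    "calibrate_fe",
    "wrist_position",
    "elbow_position",
    "elbow_angle",
    "angular_velocity_world",
]

DOWN = np.array([0.0, 0.0, -1.0])


@dataclass
class LimbModel:
    """Measured segment lengths and nominal sensor mounting axes.

    ``L_arm``: acromion to antecubital fossa, cm.  ``L_fa``: antecubital fossa
    to the ventral wrist centre, cm.  The nominal axes (sensor frame, proximal
    to distal) are used only to sanity-check the baseline-derived limb axes.
    """

    L_arm: float
    L_fa: float
    nominal_axis_arm: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    nominal_axis_fa: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self) -> None:
        if self.L_arm <= 0 or self.L_fa <= 0:
            raise InvalidInputError("limb lengths must be positive")
        for name in ("nominal_axis_arm", "nominal_axis_fa"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            n = np.linalg.norm(v)
            if n == 0:
                raise InvalidInputError(f"{name} must be a nonzero vector")
            setattr(self, name, v / n)

    @property
    def reach(self) -> float:
        """Full-extension radius L_arm + L_fa, cm."""
        return self.L_arm + self.L_fa


@dataclass
class BaselineCalibration:
    """Rest-pose orientations and the limb axes they define (sensor frames)."""

    q0_arm: np.ndarray
    q0_fa: np.ndarray
    u_arm: np.ndarray
    u_fa: np.ndarray


@dataclass
class FECalibration:
    """Elbow hinge axes (sensor frames) and the world-yaw heading correction
    applied to the forearm sensor's world frame."""

    hinge_axis_arm: np.ndarray
    hinge_axis_fa: np.ndarray
    heading_correction: np.ndarray
    alignment_deg: float = 0.0

    @classmethod
    def identity(cls) -> "FECalibration":
        y = np.array([0.0, 1.0, 0.0])
        return cls(y.copy(), y.copy(), rot.IDENTITY.copy(), 0.0)


@dataclass
class WristTrajectory:
    """Wrist position relative to the shoulder, cm, Z-up world frame."""

    t: np.ndarray
    p: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.t), 3):
            raise InvalidInputError("p must be (N, 3) matching t")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.ones(len(self.t), dtype=bool) if self.valid is None else self.valid


def remove_baseline(
    traj: OrientationTrajectory,
    rest_window: tuple[float, float],
    nominal_axis: np.ndarray,
    *,
    max_rms_deg_per_sample: float = 1.0,
    warn_axis_deg: float = 20.0,
) -> tuple[OrientationTrajectory, np.ndarray, np.ndarray]:
    """Capture the baseline orientation and derive the limb axis.

    With the limb hanging vertically and still during ``rest_window``, the
    baseline ``q0`` is the mean orientation over the window and the limb axis
    in the sensor frame is ``u = R(q0)^T (0, 0, -1)``.  The trajectory is
    returned unchanged, paired with ``(q0, u)``.

    Raises :class:`UnstableBaselineError` when consecutive orientations in the
    window move by more than ``max_rms_deg_per_sample`` RMS.  Warns when ``u``
    deviates from the configured nominal mounting axis by more than
    ``warn_axis_deg``.
    """
    sl = traj.window(*rest_window)
    qs = traj.q[sl]
    if len(qs) < 2:
        raise InvalidInputError("rest window must contain at least 2 samples")
    steps = rot.angle_between(qs[:-1], qs[1:])
    rms = float(np.sqrt(np.mean(np.rad2deg(steps) ** 2)))
    if rms > max_rms_deg_per_sample:
        raise UnstableBaselineError(
            f"baseline window moves ({rms:.2f} deg/sample RMS); cannot define the limb axis"
        )
    q0 = rot.mean_orientation(qs)
    u = rot.rotate_vector(rot.conjugate(q0), DOWN)
    nominal = np.asarray(nominal_axis, dtype=float)
    nominal = nominal / np.linalg.norm(nominal)
    dev = np.rad2deg(np.arccos(np.clip(np.dot(u, nominal), -1.0, 1.0)))
    if dev > warn_axis_deg:
        warnings.warn(
            f"baseline limb axis deviates {dev:.1f} deg from the nominal mounting axis; "
            "check sensor placement",
            stacklevel=2,
        )
    return traj, q0, u


def angular_velocity_world(traj: OrientationTrajectory) -> np.ndarray:
    """World-frame angular velocity (rad/s) by central quaternion differencing."""
    t = traj.t
    q = traj.q
    n = len(t)
    if n < 2:
        raise InvalidInputError("need at least 2 samples for angular velocity")
    w = np.zeros((n, 3))
    # left-difference: q_{k+1} = Exp(w dt) (x) q_k  =>  w in the world frame
    rel = rot.compose(q[1:], rot.conjugate(q[:-1]))
    rv = rot.to_rotvec(rel) / np.diff(t)[:, None]
    w[1:-1] = 0.5 * (rv[:-1] + rv[1:])
    w[0] = rv[0]
    w[-1] = rv[-1]
    return w


def _principal_axis(w: np.ndarray) -> np.ndarray:
    """Dominant direction of a cloud of angular-velocity vectors (unit)."""
    _, _, Vt = np.linalg.svd(w, full_matrices=False)
    return Vt[0]


def calibrate_fe(
    arm: OrientationTrajectory,
    fa: OrientationTrajectory,
    fe_window: tuple[float, float],
    *,
    min_excursion_deg: float = 20.0,
    min_arm_excursion_deg: float = 2.0,
    alignment_warn_deg: float = 2.0,
) -> FECalibration:
    """Estimate the elbow flexion-extension hinge axis and the heading offset
    between the two sensors' world frames from a passive FE movement.

    The hinge axis is taken per sensor as the principal direction of that
    sensor's world-frame angular velocity over ``fe_window`` (signs are
    matched by correlating the angular-velocity projections).  The heading
    correction is the rotation about world Z aligning the forearm-frame axis
    with the arm-frame axis.  When the upper arm barely moves (excursion below
    ``min_arm_excursion_deg``) its hinge axis is unobservable and the heading
    correction falls back to identity — for sensors sharing a world reference
    (magnetic north, or a common lighthouse frame) no correction is needed.

    Raises :class:`InsufficientExcursionError` when the relative arm/forearm
    rotation spans less than ``min_excursion_deg`` over the window.
    """
    sl_a = arm.window(*fe_window)
    sl_f = fa.window(*fe_window)
    q_rel = rot.compose(rot.conjugate(arm.q[sl_a]), fa.q[sl_f])
    ang = rot.angle_between(q_rel[0], q_rel)
    excursion = np.rad2deg(float(ang.max() - ang.min()))
    if excursion < min_excursion_deg:
        raise InsufficientExcursionError(
            f"relative elbow rotation of {excursion:.1f} deg is below the "
            f"{min_excursion_deg:.0f} deg minimum for FE calibration"
        )

    sub_a = OrientationTrajectory(t=arm.t[sl_a], q=arm.q[sl_a])
    sub_f = OrientationTrajectory(t=fa.t[sl_f], q=fa.q[sl_f])
    w_a = angular_velocity_world(sub_a)
    w_f = angular_velocity_world(sub_f)
    axis_f = _principal_axis(w_f)
    # sign: make the dominant forearm rotation positive about the axis
    s_f = w_f @ axis_f
    if s_f[np.argmax(np.abs(s_f))] < 0:
        axis_f = -axis_f
        s_f = -s_f

    arm_ang = rot.angle_between(sub_a.q[0], sub_a.q)
    arm_excursion = np.rad2deg(float(arm_ang.max() - arm_ang.min()))
    if arm_excursion < min_arm_excursion_deg:
        heading = rot.IDENTITY.copy()
        axis_a_world = axis_f
        alignment = 0.0
    else:
        axis_a_world = _principal_axis(w_a)
        s_a = w_a @ axis_a_world
        if float(np.dot(s_a, s_f)) < 0:
            axis_a_world = -axis_a_world
        ha = np.hypot(axis_a_world[0], axis_a_world[1])
        hf = np.hypot(axis_f[0], axis_f[1])
        if ha < 0.17 or hf < 0.17:  # hinge axis within ~10 deg of vertical
            warnings.warn(
                "hinge axis nearly vertical; heading offset unobservable, using identity",
                stacklevel=2,
            )
            heading = rot.IDENTITY.copy()
            alignment = 0.0
        else:
            yaw = np.arctan2(axis_a_world[1], axis_a_world[0]) - np.arctan2(
                axis_f[1], axis_f[0]
            )
            yaw = np.arctan2(np.sin(yaw), np.cos(yaw))
            heading = rot.from_axis_angle(rot.UP, yaw)
            corrected = rot.rotate_vector(heading, axis_f)
            alignment = float(
                np.rad2deg(np.arccos(np.clip(np.dot(corrected, axis_a_world), -1, 1)))
            )
            if alignment > alignment_warn_deg:
                warnings.warn(
                    f"world-frame hinge axes agree only to {alignment:.2f} deg after "
                    "heading correction; FE movement may not have been a clean hinge",
                    stacklevel=2,
                )

    # axes mapped into each sensor's frame (mean over the window)
    def to_sensor(traj_q: np.ndarray, axis_world: np.ndarray) -> np.ndarray:
        v = rot.rotate_vector(rot.conjugate(traj_q), axis_world)
        v = v.mean(axis=0)
        return v / np.linalg.norm(v)

    return FECalibration(
        hinge_axis_arm=to_sensor(sub_a.q, axis_a_world),
        hinge_axis_fa=to_sensor(sub_f.q, axis_f),
        heading_correction=heading,
        alignment_deg=alignment,
    )


def _check_sync(arm: OrientationTrajectory, fa: OrientationTrajectory) -> None:
    if len(arm) != len(fa) or not np.allclose(arm.t, fa.t, atol=1e-9):
        raise SynchronizationError(
            "arm and forearm trajectories are not on the same timeline; resample first"
        )


def _segment_directions(
    arm: OrientationTrajectory,
    fa: OrientationTrajectory,
    base: BaselineCalibration,
    fe: FECalibration | None,
) -> tuple[np.ndarray, np.ndarray]:
    _check_sync(arm, fa)
    d_arm = rot.rotate_vector(arm.q, base.u_arm)
    q_fa = fa.q
    if fe is not None and not np.allclose(fe.heading_correction, rot.IDENTITY):
        q_fa = rot.compose(fe.heading_correction, q_fa)
    d_fa = rot.rotate_vector(q_fa, base.u_fa)
    return d_arm, d_fa


def wrist_position(
    arm: OrientationTrajectory,
    fa: OrientationTrajectory,
    model: LimbModel,
    base: BaselineCalibration,
    fe: FECalibration | None = None,
) -> WristTrajectory:
    """Wrist position relative to the shoulder (cm, Z-up world frame).

    Requires synchronized trajectories; validity masks from either input are
    intersected into the output.
    """
    d_arm, d_fa = _segment_directions(arm, fa, base, fe)
    p = model.L_arm * d_arm + model.L_fa * d_fa
    mask = arm.valid_mask & fa.valid_mask
    return WristTrajectory(t=arm.t.copy(), p=p, valid=None if mask.all() else mask)


def elbow_position(
    arm: OrientationTrajectory, model: LimbModel, base: BaselineCalibration
) -> np.ndarray:
    """Elbow position relative to the shoulder, cm (exposed for completeness)."""
    return model.L_arm * rot.rotate_vector(arm.q, base.u_arm)


def elbow_angle(
    arm: OrientationTrajectory,
    fa: OrientationTrajectory,
    base: BaselineCalibration,
    fe: FECalibration | None = None,
) -> np.ndarray:
    """Elbow angle in degrees per sample; full extension (collinear segments)
    maps to 180 degrees."""
    d_arm, d_fa = _segment_directions(arm, fa, base, fe)
    cosang = np.clip(np.sum(d_arm * d_fa, axis=-1), -1.0, 1.0)
    return 180.0 - np.rad2deg(np.arccos(cosang))
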