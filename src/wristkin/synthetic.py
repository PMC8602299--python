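"""Ground-truth arm motion and forward sensor models.

Because the methods are validated against known motion rather than deposited
human recordings, this module generates the study's movement scenarios from
first principles and forward-models what each sensor would have measured:

* :func:`simulate_reach` — multiplanar reach-hold-return sequences with
  minimum-jerk wrist paths and an elbow-in-vertical-plane inverse-kinematics
  convention (the reaching task used for accuracy validation);
* :func:`simulate_sweep` — shoulder abduction followed by a horizontal sweep
  at constant elbow angle; with no extension deficit the wrist traces a
  semicircle of radius L_arm + L_fa in the horizontal plane;
* :func:`simulate_static` and :func:`simulate_fe` — rest and passive elbow
  flexion-extension calibration movements;
* :func:`imu_forward_model` / :func:`pose_forward_model` — invert the
  estimation problem: 9-axis IMU streams (gyro from quaternion differencing,
  accelerometer from double-differentiated sensor positions plus gravity,
  magnetometer through hard/soft-iron distortion) and 6-DoF tracker pose
  streams (orientation noise, occlusion dropouts) from the ground truth.

All randomness flows from ``SensorNoiseModel.seed``; identical configurations
reproduce bit-identically.  Ground-truth sensor frames mount the sensor x-axis
along the limb (proximal to distal), so at the hanging baseline each segment
orientation maps sensor +x to world down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import rotations as rot
from .chain import LimbModel
from .errors import InvalidInputError, ReachabilityError
from .imu import ImuStream
from .vive import PoseStream, _Q_Y_UP, _C_Y_UP

__all__ = [
    "MotionGroundTruth",
    "SensorNoiseModel",
    "ReachTiming",
    "SweepTiming",
    "simulate_reach",
    "simulate_sweep",
    "simulate_static",
    "simulate_fe",
    "imu_forward_model",
    "pose_forward_model",
    "simulate_mag_calibration",
    "apply_mount_twist",
    "min_jerk",
    "MAG_FIELD_WORLD",
]

DOWN = np.array([0.0, 0.0, -1.0])
X_SENSOR = np.array([1.0, 0.0, 0.0])

# world magnetic field: magnitude 50 (arbitrary units), 60 degree downward dip;
# the horizontal component defines world X by convention.
MAG_FIELD_WORLD = 50.0 * np.array(
    [np.cos(np.deg2rad(60.0)), 0.0, -np.sin(np.deg2rad(60.0))]
)

# sensor mounting: world <- sensor at the hanging baseline maps +x to down
_Q_MOUNT = rot.shortest_arc(X_SENSOR, DOWN)

# a reachable six-target board (cm, shoulder origin) spanning azimuths and
# heights, used by the CLI and the validation scripts for L = 30 + 25 cm
DEFAULT_TARGETS = [
    np.array([35.0, 10.0, -20.0]),
    np.array([40.0, 0.0, -10.0]),
    np.array([38.0, -12.0, 0.0]),
    np.array([30.0, 20.0, 10.0]),
    np.array([45.0, 5.0, -5.0]),
    np.array([25.0, -18.0, 15.0]),
]


def min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1]: 10t^3 - 15t^4 + 6t^5."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


@dataclass
class SensorNoiseModel:
    """Error sources of the forward models, commodity-sensor magnitudes.

    Units: gyro rad/s, accel m/s², mag in field units (field magnitude is 50),
    pose noise rad.  ``dropout_rate`` is occlusion events per second, each
    lasting ``dropout_duration`` seconds.  All magnitudes >= 0; ``seed`` feeds
    every random draw.
    """

    gyro_noise_rms: float = 0.005
    gyro_bias: float = 0.002
    accel_noise_rms: float = 0.05
    mag_noise_rms: float = 0.5
    hard_iron: np.ndarray = field(default_factory=lambda: np.array([10.0, -5.0, 3.0]))
    soft_iron: np.ndarray | None = None
    pose_angle_noise: float = np.deg2rad(0.3)
    dropout_rate: float = 0.0
    dropout_duration: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gyro_noise_rms",
            "gyro_bias",
            "accel_noise_rms",
            "mag_noise_rms",
            "pose_angle_noise",
            "dropout_rate",
            "dropout_duration",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        self.hard_iron = np.asarray(self.hard_iron, dtype=float).reshape(3)
        if self.soft_iron is None:
            S = np.array(
                [
                    [1.05, 0.02, 0.00],
                    [0.02, 0.97, 0.01],
                    [0.00, 0.01, 0.99],
                ]
            )
            self.soft_iron = S / np.linalg.det(S) ** (1.0 / 3.0)
        else:
            self.soft_iron = np.asarray(self.soft_iron, dtype=float).reshape(3, 3)

    @classmethod
    def zero(cls, seed: int = 0) -> "SensorNoiseModel":
        """Noiseless, undistorted model (identity soft iron, zero hard iron)."""
        return cls(
            gyro_noise_rms=0.0,
            gyro_bias=0.0,
            accel_noise_rms=0.0,
            mag_noise_rms=0.0,
            hard_iron=np.zeros(3),
            soft_iron=np.eye(3),
            pose_angle_noise=0.0,
            dropout_rate=0.0,
            seed=seed,
        )


@dataclass
class MotionGroundTruth:
    """Ground-truth segment orientations, directions and wrist position.

    ``p_true`` always equals ``L_arm * d_arm + L_fa * d_fa`` (the chain formula
    applied to the generating orientations) by construction.  ``schedule``
    carries scenario-specific intervals: rest window, labelled holds, rest
    intervals between reaches, sweep interval, FE window, per-target truth.
    """

    t: np.ndarray
    q_arm: np.ndarray
    q_fa: np.ndarray
    d_arm: np.ndarray
    d_fa: np.ndarray
    p_true: np.ndarray
    limb: LimbModel
    scenario: str
    schedule: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ReachTiming:
    """Phase durations (s) of one rest-reach-hold-return cycle."""

    initial_rest: float = 5.0
    move: float = 1.2
    hold: float = 3.0
    inter_rest: float = 1.5


@dataclass
class SweepTiming:
    """Phase durations (s) of the abduction + horizontal sweep task."""

    initial_rest: float = 5.0
    abduction: float = 2.5
    sweep: float = 6.0
    lower: float = 2.5
    final_rest: float = 1.0


def _orientations_from_directions(d: np.ndarray) -> np.ndarray:
    """world <- sensor quaternions whose sensor x-axis points along d.

    Shortest-arc from the hanging direction keeps the series twist-free and
    continuous for any motion that avoids pointing straight up.
    """
    return rot.compose(rot.shortest_arc(DOWN, d), _Q_MOUNT)


def _finish(
    t: np.ndarray,
    d_arm: np.ndarray,
    d_fa: np.ndarray,
    limb: LimbModel,
    scenario: str,
    schedule: dict[str, Any],
) -> MotionGroundTruth:
    d_arm = d_arm / np.linalg.norm(d_arm, axis=1, keepdims=True)
    d_fa = d_fa / np.linalg.norm(d_fa, axis=1, keepdims=True)
    return MotionGroundTruth(
        t=t,
        q_arm=_orientations_from_directions(d_arm),
        q_fa=_orientations_from_directions(d_fa),
        d_arm=d_arm,
        d_fa=d_fa,
        p_true=limb.L_arm * d_arm + limb.L_fa * d_fa,
        limb=limb,
        scenario=scenario,
        schedule=schedule,
    )


def _ik_two_segment(p: np.ndarray, limb: LimbModel, plane_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elbow-below-the-line inverse kinematics for wrist positions ``p`` (cm).

    The elbow is offset from the shoulder-wrist line toward world down
    (anatomically, the elbow hangs below a forward reach).  Where the line is
    itself vertical the offset direction degenerates and falls back to
    ``plane_dir``; the reach paths used here start at full extension (zero
    offset) when vertical, so the fallback never produces a visible jump.
    """
    d = np.linalg.norm(p, axis=1)
    if np.any(d > limb.reach + 1e-9):
        raise ReachabilityError("wrist path leaves the reachable workspace")
    if np.any(d < abs(limb.L_arm - limb.L_fa) - 1e-9):
        raise ReachabilityError("wrist path closer than |L_arm - L_fa| to the shoulder")
    d = np.clip(d, abs(limb.L_arm - limb.L_fa), limb.reach)
    phat = p / d[:, None]
    cosb = (limb.L_arm**2 + d**2 - limb.L_fa**2) / (2.0 * limb.L_arm * d)
    cosb = np.clip(cosb, -1.0, 1.0)
    sinb = np.sqrt(np.maximum(0.0, 1.0 - cosb**2))
    e2 = DOWN - np.sum(DOWN * phat, axis=1, keepdims=True) * phat
    n2 = np.linalg.norm(e2, axis=1, keepdims=True)
    fb = plane_dir - np.sum(plane_dir * phat, axis=1, keepdims=True) * phat
    nfb = np.linalg.norm(fb, axis=1, keepdims=True)
    e2 = np.where(n2 > 1e-9, e2 / np.where(n2 == 0, 1.0, n2), fb / np.where(nfb == 0, 1.0, nfb))
    elbow = limb.L_arm * (cosb[:, None] * phat + sinb[:, None] * e2)
    d_arm = elbow / limb.L_arm
    d_fa = (p - elbow) / limb.L_fa
    return d_arm, d_fa


def simulate_reach(
    targets: list[np.ndarray],
    limb: LimbModel,
    timing: ReachTiming | None = None,
    *,
    reaches_per_target: int = 1,
    rate: float = 100.0,
) -> MotionGroundTruth:
    """Reach-hold-return sequences to each target in order.

    From the hanging rest posture the segments rotate to the target's
    inverse-kinematics configuration (elbow offset below the shoulder-wrist
    line) along a minimum-jerk time profile, hold, and return; the wrist
    therefore follows a smooth, gently curved path with a bell-shaped speed
    profile.  Joint-space interpolation is used because a straight wrist line
    out of the fully extended rest posture would require unbounded elbow
    angular acceleration (a square-root kinematic singularity at full
    extension).  Targets must be reachable and are labelled T1, T2, ... in
    the given order; every hold and rest interval is recorded in ``schedule``.
    """
    timing = timing or ReachTiming()
    targets = [np.asarray(tt, dtype=float).reshape(3) for tt in targets]
    for k, tgt in enumerate(targets):
        if np.linalg.norm(tgt) > limb.reach + 1e-9:
            raise ReachabilityError(
                f"target {k + 1} at {np.linalg.norm(tgt):.1f} cm exceeds reach {limb.reach:.1f} cm"
            )
    dt = 1.0 / rate

    seg_a: list[np.ndarray] = []
    seg_f: list[np.ndarray] = []
    holds: list[tuple[tuple[float, float], str]] = []
    rests: list[tuple[float, float]] = []

    def n_samples(dur: float) -> int:
        return max(2, int(round(dur * rate)))

    def plane_of(tgt: np.ndarray) -> np.ndarray:
        h = np.array([tgt[0], tgt[1], 0.0])
        nh = np.linalg.norm(h)
        return h / nh if nh > 1e-9 else np.array([1.0, 0.0, 0.0])

    def still(n: int) -> tuple[np.ndarray, np.ndarray]:
        return np.tile(DOWN, (n, 1)), np.tile(DOWN, (n, 1))

    def swing(rv_arm: np.ndarray, rv_fa: np.ndarray, s: np.ndarray, reverse: bool):
        """Rotate both segments from rest to the target configuration (or
        back) along the minimum-jerk fraction ``s``."""
        frac = (1.0 - s) if reverse else s
        da = rot.rotate_vector(rot.from_rotvec(frac[:, None] * rv_arm), DOWN)
        df = rot.rotate_vector(rot.from_rotvec(frac[:, None] * rv_fa), DOWN)
        return da, df

    t_cursor = 0.0
    n0 = n_samples(timing.initial_rest)
    a, f = still(n0)
    seg_a.append(a)
    seg_f.append(f)
    rests.append((0.0, timing.initial_rest))
    t_cursor += n0 * dt

    for ti, tgt in enumerate(targets):
        label = f"T{ti + 1}"
        da_t, df_t = _ik_two_segment(tgt[None, :], limb, plane_of(tgt)[None, :])
        rv_arm = rot.to_rotvec(rot.shortest_arc(DOWN, da_t[0]))
        rv_fa = rot.to_rotvec(rot.shortest_arc(DOWN, df_t[0]))
        for _ in range(reaches_per_target):
            nm = n_samples(timing.move)
            s = min_jerk(np.linspace(0.0, 1.0, nm))
            a, f = swing(rv_arm, rv_fa, s, reverse=False)
            seg_a.append(a)
            seg_f.append(f)
            t_cursor += nm * dt

            nh = n_samples(timing.hold)
            seg_a.append(np.tile(da_t[0], (nh, 1)))
            seg_f.append(np.tile(df_t[0], (nh, 1)))
            holds.append(((t_cursor, t_cursor + (nh - 1) * dt), label))
            t_cursor += nh * dt

            nm = n_samples(timing.move)
            s = min_jerk(np.linspace(0.0, 1.0, nm))
            a, f = swing(rv_arm, rv_fa, s, reverse=True)
            seg_a.append(a)
            seg_f.append(f)
            t_cursor += nm * dt

            nr = n_samples(timing.inter_rest)
            a, f = still(nr)
            seg_a.append(a)
            seg_f.append(f)
            rests.append((t_cursor, t_cursor + (nr - 1) * dt))
            t_cursor += nr * dt

    d_arm = np.concatenate(seg_a)
    d_fa = np.concatenate(seg_f)
    n = len(d_arm)
    t = np.arange(n) * dt
    schedule = {
        "rest_window": (0.0, timing.initial_rest),
        "holds": holds,
        "rests": rests,
        "targets": {f"T{k + 1}": tgt for k, tgt in enumerate(targets)},
        "target_epd": {f"T{k + 1}": float(np.linalg.norm(tgt)) for k, tgt in enumerate(targets)},
        "rest_epd": float(limb.reach),
    }
    return _finish(t, d_arm, d_fa, limb, "reach", schedule)


def simulate_sweep(
    limb: LimbModel,
    extension_deficit: float = 0.0,
    timing: SweepTiming | None = None,
    *,
    sub_movements: int = 1,
    pause: float = 0.5,
    rate: float = 100.0,
) -> MotionGroundTruth:
    """Shoulder abduction to horizontal followed by a 180-degree horizontal sweep.

    ``extension_deficit`` (degrees, in [0, 120]) is how far the elbow falls
    short of full extension; the sweep holds the elbow at 180 - deficit
    degrees.  With zero deficit the wrist traces a horizontal semicircle of
    radius ``L_arm + L_fa``; larger deficits shrink the swept workspace.

    ``sub_movements`` splits the sweep into that many separate strokes with a
    ``pause``-second stop between them, emulating the segmented, stop-and-go
    movement typical of impaired reaching: the true movement smoothness
    (peak over mean speed) grows with the number of sub-movements, while a
    single-stroke sweep is a clean minimum-jerk bell.  Deterministic:
    repeated calls produce identical motion.
    """
    if not 0.0 <= extension_deficit <= 120.0:
        raise InvalidInputError("extension deficit must be in [0, 120] degrees")
    if sub_movements < 1:
        raise InvalidInputError("sub_movements must be >= 1")
    timing = timing or SweepTiming()
    dt = 1.0 / rate
    psi = np.deg2rad(extension_deficit)

    def n_samples(dur: float) -> int:
        return max(2, int(round(dur * rate)))

    def dirs(alpha: np.ndarray, theta: np.ndarray, bend: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Arm at elevation alpha (0 = down, pi/2 = horizontal) and azimuth
        theta; forearm bent by ``bend`` about world Z relative to the arm."""
        a = np.stack(
            [
                np.sin(alpha) * np.cos(theta),
                np.sin(alpha) * np.sin(theta),
                -np.cos(alpha),
            ],
            axis=1,
        )
        cz, sz = np.cos(bend), np.sin(bend)
        f = np.stack(
            [
                cz * a[:, 0] - sz * a[:, 1],
                sz * a[:, 0] + cz * a[:, 1],
                a[:, 2],
            ],
            axis=1,
        )
        nf = np.linalg.norm(f, axis=1, keepdims=True)
        return a, f / nf

    segs_a: list[np.ndarray] = []
    segs_f: list[np.ndarray] = []

    # initial rest: hanging straight down
    n0 = n_samples(timing.initial_rest)
    zeros = np.zeros(n0)
    a, f = dirs(zeros, zeros - np.pi / 2.0, zeros)
    segs_a.append(a)
    segs_f.append(f)

    # abduction in the Y-Z plane (azimuth -90 deg) while the elbow bends to the deficit
    n1 = n_samples(timing.abduction)
    s = min_jerk(np.linspace(0.0, 1.0, n1))
    a, f = dirs(s * np.pi / 2.0, np.full(n1, -np.pi / 2.0), s * psi)
    segs_a.append(a)
    segs_f.append(f)

    # horizontal sweep: azimuth -90 -> +90 deg at constant elevation and bend,
    # in one or more min-jerk strokes separated by brief stops
    stroke_dur = timing.sweep / sub_movements
    az0 = -np.pi / 2.0
    n2 = 0
    for j in range(sub_movements):
        nj = n_samples(stroke_dur)
        s = min_jerk(np.linspace(0.0, 1.0, nj))
        az = az0 + (s + j) * (np.pi / sub_movements)
        a, f = dirs(np.full(nj, np.pi / 2.0), az, np.full(nj, psi))
        segs_a.append(a)
        segs_f.append(f)
        n2 += nj
        if j < sub_movements - 1 and pause > 0:
            np_pause = n_samples(pause)
            a, f = dirs(
                np.full(np_pause, np.pi / 2.0),
                np.full(np_pause, az0 + (j + 1) * np.pi / sub_movements),
                np.full(np_pause, psi),
            )
            segs_a.append(a)
            segs_f.append(f)
            n2 += np_pause

    # lower back down on the contralateral side, elbow re-extending
    n3 = n_samples(timing.lower)
    s = min_jerk(np.linspace(0.0, 1.0, n3))
    a, f = dirs((1.0 - s) * np.pi / 2.0, np.full(n3, np.pi / 2.0), (1.0 - s) * psi)
    segs_a.append(a)
    segs_f.append(f)

    n4 = n_samples(timing.final_rest)
    zeros = np.zeros(n4)
    a, f = dirs(zeros, zeros + np.pi / 2.0, zeros)
    segs_a.append(a)
    segs_f.append(f)

    d_arm = np.concatenate(segs_a)
    d_fa = np.concatenate(segs_f)
    n = len(d_arm)
    t = np.arange(n) * dt
    t_ab = n0 * dt
    t_sweep_end = (n0 + n1 + n2) * dt
    schedule = {
        "rest_window": (0.0, timing.initial_rest),
        "sweep_interval": (t_ab, t_sweep_end),
        "abduction_interval": (t_ab, t_ab + timing.abduction),
        "extension_deficit_deg": float(extension_deficit),
        "sub_movements": int(sub_movements),
    }
    return _finish(t, d_arm, d_fa, limb, "sweep", schedule)


def simulate_static(
    limb: LimbModel, duration: float = 10.0, *, rate: float = 100.0
) -> MotionGroundTruth:
    """Motionless hanging posture (both segments pointing straight down)."""
    n = max(2, int(round(duration * rate)))
    t = np.arange(n) / rate
    d = np.tile(DOWN, (n, 1))
    return _finish(
        t, d.copy(), d.copy(), limb, "static", {"rest_window": (0.0, duration)}
    )


def simulate_fe(
    limb: LimbModel,
    *,
    rest_duration: float = 5.0,
    fe_duration: float = 10.0,
    rock_amplitude_deg: float = 6.0,
    flexion_max_deg: float = 70.0,
    rate: float = 100.0,
) -> MotionGroundTruth:
    """Passive elbow flexion-extension about the world Y axis.

    The forearm flexes to ``flexion_max_deg`` and back (twice over the
    window) while the whole limb rocks gently by ``rock_amplitude_deg`` about
    the same hinge axis — passive manipulation never isolates the forearm
    perfectly, and the rock is what lets the arm sensor observe the hinge
    axis.  Starts from the hanging rest posture.
    """
    n0 = max(2, int(round(rest_duration * rate)))
    n1 = max(2, int(round(fe_duration * rate)))
    t = np.arange(n0 + n1) / rate
    tau = (t[n0:] - t[n0]) / fe_duration

    rock = np.deg2rad(rock_amplitude_deg) * np.sin(2.0 * np.pi * 1.6 * tau) ** 2
    flex = np.deg2rad(flexion_max_deg) * 0.5 * (1.0 - np.cos(2.0 * np.pi * 2.0 * tau))

    beta_arm = np.concatenate([np.zeros(n0), rock])
    beta_fa = np.concatenate([np.zeros(n0), rock + flex])

    def ry_down(beta: np.ndarray) -> np.ndarray:
        # rotate DOWN about world +Y by beta: (-sin b, 0, -cos b)
        return np.stack([-np.sin(beta), np.zeros_like(beta), -np.cos(beta)], axis=1)

    d_arm = ry_down(beta_arm)
    d_fa = ry_down(beta_fa)
    schedule = {
        "rest_window": (0.0, rest_duration),
        "fe_window": (rest_duration, rest_duration + fe_duration),
        "hinge_axis_world": np.array([0.0, 1.0, 0.0]),
    }
    return _finish(t, d_arm, d_fa, limb, "fe_calibration", schedule)


def apply_mount_twist(q: np.ndarray, angle_deg: float) -> np.ndarray:
    """Re-mount the sensor rotated about the limb long axis by ``angle_deg``.

    The limb axis is sensor +x by the generator's convention, so the twist is
    a constant right-side rotation about (1, 0, 0).
    """
    twist = rot.from_axis_angle(X_SENSOR, np.deg2rad(angle_deg))
    return rot.compose(q, twist)


# --------------------------------------------------------------------------
# forward sensor models


def _body_angular_velocity(t: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Sensor-frame angular velocity by central quaternion differencing."""
    n = len(t)
    w = np.zeros((n, 3))
    rel = rot.compose(rot.conjugate(q[:-1]), q[1:])
    rv = rot.to_rotvec(rel) / np.diff(t)[:, None]
    w[1:-1] = 0.5 * (rv[:-1] + rv[1:])
    w[0] = rv[0]
    w[-1] = rv[-1]
    return w


def _sensor_positions_m(truth: MotionGroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """World positions (m) of the arm and forearm sensors.

    Sensors sit distally on each segment ("proximal to the elbow and wrist"):
    75% along the arm, elbow + 60% of the forearm.
    """
    limb = truth.limb
    arm_pos = 0.75 * limb.L_arm * truth.d_arm / 100.0
    fa_pos = (limb.L_arm * truth.d_arm + 0.6 * limb.L_fa * truth.d_fa) / 100.0
    return arm_pos, fa_pos


def _imu_stream_for(
    t: np.ndarray,
    q: np.ndarray,
    pos_m: np.ndarray,
    noise: SensorNoiseModel,
    rng: np.random.Generator,
    rate: float,
) -> ImuStream:
    n = len(t)
    gyro = _body_angular_velocity(t, q)
    if noise.gyro_bias > 0:
        bias_dir = rng.normal(size=3)
        bias_dir /= np.linalg.norm(bias_dir)
        gyro = gyro + noise.gyro_bias * bias_dir
    if noise.gyro_noise_rms > 0:
        gyro = gyro + rng.normal(scale=noise.gyro_noise_rms / np.sqrt(3.0), size=(n, 3))

    vel = np.gradient(pos_m, t, axis=0)
    acc_world = np.gradient(vel, t, axis=0)
    f_world = acc_world + np.array([0.0, 0.0, rot.GRAVITY])
    accel = rot.rotate_vector(rot.conjugate(q), f_world)
    if noise.accel_noise_rms > 0:
        accel = accel + rng.normal(scale=noise.accel_noise_rms / np.sqrt(3.0), size=(n, 3))

    m_clean = rot.rotate_vector(rot.conjugate(q), MAG_FIELD_WORLD)
    mag = m_clean @ noise.soft_iron.T + noise.hard_iron
    if noise.mag_noise_rms > 0:
        mag = mag + rng.normal(scale=noise.mag_noise_rms / np.sqrt(3.0), size=(n, 3))

    return ImuStream(t=t.copy(), gyro=gyro, accel=accel, mag=mag, sample_rate=rate)


def imu_forward_model(
    truth: MotionGroundTruth, noise: SensorNoiseModel | None = None
) -> tuple[ImuStream, ImuStream]:
    """Forward-model the two 9-axis IMU streams for a ground-truth motion.

    Gyro = sensor-frame angular velocity + bias + noise; accelerometer =
    sensor-frame specific force from double-differentiated sensor positions
    plus gravity; magnetometer = soft-iron-distorted, hard-iron-offset
    sensor-frame field + noise.  Returns (arm stream, forearm stream).
    """
    noise = noise or SensorNoiseModel()
    t = truth.t
    rate = 1.0 / float(np.median(np.diff(t)))
    w_max = max(
        float(np.max(np.linalg.norm(_body_angular_velocity(t, truth.q_arm), axis=1))),
        float(np.max(np.linalg.norm(_body_angular_velocity(t, truth.q_fa), axis=1))),
    )
    if rate < 4.0 * w_max / (2.0 * np.pi):
        warnings.warn(
            f"sample rate {rate:.0f} Hz below twice the motion bandwidth; aliasing likely",
            stacklevel=2,
        )
    rng = np.random.default_rng(noise.seed)
    arm_pos, fa_pos = _sensor_positions_m(truth)
    arm = _imu_stream_for(t, truth.q_arm, arm_pos, noise, rng, rate)
    fa = _imu_stream_for(t, truth.q_fa, fa_pos, noise, rng, rate)
    return arm, fa


def _pose_stream_for(
    t: np.ndarray,
    q: np.ndarray,
    pos_m: np.ndarray,
    noise: SensorNoiseModel,
    rng: np.random.Generator,
    native_frame: str,
) -> PoseStream:
    n = len(t)
    if noise.pose_angle_noise > 0:
        perturb = rot.from_rotvec(
            rng.normal(scale=noise.pose_angle_noise / np.sqrt(3.0), size=(n, 3))
        )
        q = rot.compose(q, perturb)
    valid = np.ones(n, dtype=bool)
    if noise.dropout_rate > 0:
        duration = t[-1] - t[0]
        n_events = rng.poisson(noise.dropout_rate * duration)
        starts = rng.uniform(t[0], t[-1], size=n_events)
        for s in starts:
            valid[(t >= s) & (t <= s + noise.dropout_duration)] = False
    if native_frame == "y_up":
        q = rot.compose(rot.conjugate(_Q_Y_UP), q)
        pos = pos_m @ _C_Y_UP  # C^T rows: world -> native
    else:
        pos = pos_m
    return PoseStream(t=t.copy(), position=pos, q=q, valid=valid, native_frame=native_frame)


def pose_forward_model(
    truth: MotionGroundTruth,
    noise: SensorNoiseModel | None = None,
    *,
    native_frame: str = "y_up",
) -> tuple[PoseStream, PoseStream]:
    """Forward-model the two 6-DoF tracker pose streams for a ground truth.

    Orientations are perturbed by small random rotations of RMS
    ``pose_angle_noise`` and occlusion dropouts are inserted as invalid runs;
    positions are emitted for completeness (the chain never uses them).
    """
    noise = noise or SensorNoiseModel()
    rng = np.random.default_rng(noise.seed)
    arm_pos, fa_pos = _sensor_positions_m(truth)
    arm = _pose_stream_for(truth.t, truth.q_arm, arm_pos, noise, rng, native_frame)
    fa = _pose_stream_for(truth.t, truth.q_fa, fa_pos, noise, rng, native_frame)
    return arm, fa


def simulate_mag_calibration(
    noise: SensorNoiseModel | None = None, n_samples: int = 400
) -> np.ndarray:
    """Magnetometer readings from waving the sensor through random orientations.

    The true field direction is uniform on the sphere (constant magnitude);
    readings pass through the same hard/soft-iron distortion as
    :func:`imu_forward_model`, so the fitted calibration transfers to the
    recording.
    """
    noise = noise or SensorNoiseModel()
    rng = np.random.default_rng(noise.seed + 104729)  # independent sub-stream
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    field = v * np.linalg.norm(MAG_FIELD_WORLD)
    samples = field @ noise.soft_iron.T + noise.hard_iron
    if noise.mag_noise_rms > 0:
        samples = samples + rng.normal(
            scale=noise.mag_noise_rms / np.sqrt(3.0), size=samples.shape
        )
    return samples
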