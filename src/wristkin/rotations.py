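"""Quaternion algebra, world-frame conventions, and the static orientation solver.

Conventions (used everywhere in wristkin, documented once here):

* Quaternions are scalar-first ``(w, x, y, z)`` numpy arrays using the Hamilton
  product convention.  A quaternion ``q`` represents the rotation
  *world <- sensor*: ``rotate(q, v_sensor) = v_world``.
* The world frame is right-handed and Z-up.  Gravity is ``(0, 0, -9.81)`` m/s²,
  so a static accelerometer (which measures specific force) reads ``+9.81`` on
  the world up axis.  World X is the horizontal projection of the magnetic
  field ("magnetic north"); Y = Z x X.  The magnetic dip angle is arbitrary:
  only the horizontal field component defines heading.

All functions broadcast over leading axes, so a trajectory of N quaternions is
an ``(N, 4)`` array and ``compose(A, B)`` composes element-wise.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError, InvalidInputError, NonStaticError

GRAVITY = 9.81
"""Magnitude of gravitational acceleration, m/s² (world-frame definition)."""

UP = np.array([0.0, 0.0, 1.0])
"""World up axis (gravity is -9.81 * UP)."""

NORTH = np.array([1.0, 0.0, 0.0])
"""World X: horizontal projection of the magnetic field."""

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _require_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise InvalidInputError("non-finite components in rotation input")


def normalize(q: np.ndarray) -> np.ndarray:
    """Return ``q`` scaled to unit norm (broadcasts over leading axes)."""
    q = np.asarray(q, dtype=float)
    _require_finite(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise InvalidInputError("zero-norm quaternion")
    return q / n


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Flip sign so w >= 0; q and -q are the same rotation."""
    q = np.asarray(q, dtype=float)
    return np.where(q[..., :1] < 0, -q, q)


def compose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a (x) b``: apply rotation ``b`` first, then ``a``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _require_finite(a, b)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def conjugate(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate (inverse for unit quaternions)."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate 3-vector(s) ``v`` by unit quaternion(s) ``q`` (sensor -> world).

    Uses the expansion ``v + w*t + qv x t`` with ``t = 2 qv x v``, which costs
    two cross products instead of two quaternion products.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    _require_finite(q, v)
    qv = q[..., 1:]
    t = 2.0 * np.cross(qv, v)
    return v + q[..., :1] * t + np.cross(qv, t)


def from_axis_angle(axis: np.ndarray, angle: float | np.ndarray) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle`` radians about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    angle = np.asarray(angle, dtype=float)
    half = 0.5 * angle
    return np.concatenate(
        [np.cos(half)[..., None], np.sin(half)[..., None] * axis], axis=-1
    )


def from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (axis * angle, rad) -> unit quaternion."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sinc form is well conditioned at angle -> 0
    k = np.where(angle > 1e-12, np.sin(half) / np.where(angle == 0, 1.0, angle), 0.5)
    return np.concatenate([np.cos(half), k * rv], axis=-1)


def to_rotvec(q: np.ndarray) -> np.ndarray:
    """Logarithmic map: unit quaternion -> rotation vector (rad)."""
    q = canonicalize(np.asarray(q, dtype=float))
    vec = q[..., 1:]
    s = np.linalg.norm(vec, axis=-1, keepdims=True)
    angle = 2.0 * np.arctan2(s, q[..., :1])
    k = np.where(s > 1e-12, angle / np.where(s == 0, 1.0, s), 2.0)
    return k * vec


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix equivalent to ``q`` (world <- sensor), shape (..., 3, 3)."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = (q[..., i] for i in range(4))
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
        ],
        axis=-2,
    )


def from_matrix(R: np.ndarray) -> np.ndarray:
    """Unit quaternion from a proper rotation matrix (Shepperd's branching)."""
    R = np.asarray(R, dtype=float)
    _require_finite(R)
    if R.shape != (3, 3):
        raise InvalidInputError("from_matrix expects a single 3x3 matrix")
    tr = np.trace(R)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(R[i, i] - R[j, j] - R[k, k] + 1.0, 0.0)) * 2.0
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    return normalize(canonicalize(q))


def angle_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Geodesic angle (rad) between two rotations; robust near 0 and pi."""
    rel = compose(conjugate(a), b)
    s = np.linalg.norm(rel[..., 1:], axis=-1)
    return 2.0 * np.arctan2(s, np.abs(rel[..., 0]))


def shortest_arc(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying unit vector ``u`` onto unit vector ``v``."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    dot = np.sum(u * v, axis=-1)
    if np.any(dot < -1.0 + 1e-12):
        # antiparallel: 180 deg about any axis orthogonal to u
        axis = np.cross(u, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, np.array([0.0, 1.0, 0.0]))
        return from_axis_angle(axis, np.pi)
    q = np.concatenate([(1.0 + dot)[..., None], np.cross(u, v)], axis=-1)
    return normalize(q)


def slerp(a: np.ndarray, b: np.ndarray, frac: float | np.ndarray) -> np.ndarray:
    """Spherical linear interpolation from ``a`` (frac=0) to ``b`` (frac=1)."""
    a = normalize(a)
    b = normalize(b)
    if float(np.sum(a * b)) < 0:  # take the short way around
        b = -b
    rel = compose(conjugate(a), b)
    rv = to_rotvec(rel)
    frac = np.asarray(frac, dtype=float)
    return compose(a, from_rotvec(frac[..., None] * rv))


def mean_orientation(qs: np.ndarray) -> np.ndarray:
    """Average rotation of an (N, 4) quaternion series.

    Principal eigenvector of the accumulated outer-product matrix; invariant
    to per-sample sign flips, exact for a constant series.
    """
    qs = np.asarray(qs, dtype=float)
    if qs.ndim != 2 or qs.shape[0] == 0:
        raise InvalidInputError("mean_orientation expects a non-empty (N, 4) array")
    M = qs.T @ qs
    _, vecs = np.linalg.eigh(M)
    return normalize(canonicalize(vecs[:, -1]))


def orientation_from_accel_mag(
    accel_mean: np.ndarray,
    mag_mean: np.ndarray,
    *,
    on_nonstatic: str = "raise",
) -> np.ndarray:
    """Solve a static sensor's world orientation from mean accelerometer and
    magnetometer readings (two-vector TRIAD construction).

    Parameters
    ----------
    accel_mean : (3,) array
        Mean specific force over a static window, m/s².  Must be within 20% of
        9.81 in magnitude (otherwise the window was not static).
    mag_mean : (3,) array
        Mean magnetic field over the window, any consistent units.
    on_nonstatic : {"raise", "warn"}
        What to do when the accelerometer norm check fails.

    Returns
    -------
    q : (4,) array
        world <- sensor quaternion with ``rotate_vector(q, accel_mean)`` along
        +Z (up) and the horizontal part of ``rotate_vector(q, mag_mean)``
        along +X.

    Raises
    ------
    DegenerateGeometryError
        If the field is within 5 degrees of gravity (heading undefined).
    """
    a = np.asarray(accel_mean, dtype=float)
    m = np.asarray(mag_mean, dtype=float)
    _require_finite(a, m)
    an = np.linalg.norm(a)
    mn = np.linalg.norm(m)
    if an == 0 or mn == 0:
        raise InvalidInputError("zero accelerometer or magnetometer vector")
    if abs(an - GRAVITY) > 0.2 * GRAVITY:
        msg = f"accelerometer norm {an:.2f} m/s² not within 20% of gravity; window not static?"
        if on_nonstatic == "warn":
            import warnings

            warnings.warn(msg, stacklevel=2)
        else:
            raise NonStaticError(msg)
    z_s = a / an  # world up, in sensor coordinates
    cosang = abs(float(np.dot(z_s, m / mn)))
    if cosang > np.cos(np.deg2rad(5.0)):
        raise DegenerateGeometryError(
            "magnetic field within 5 degrees of gravity; heading is undefined"
        )
    mh = m - np.dot(m, z_s) * z_s  # horizontal field component
    x_s = mh / np.linalg.norm(mh)  # world north, in sensor coordinates
    y_s = np.cross(z_s, x_s)
    # rows of R are the world basis vectors expressed in the sensor frame,
    # so R maps sensor coordinates to world coordinates.
    return from_matrix(np.stack([x_s, y_s, z_s]))
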