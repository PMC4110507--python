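"""Rigid-body kinematics for chains of body-worn orientation sensors.

A MIMU (magnetic and inertial measurement unit) emits a fused orientation
estimate for the segment it is strapped to.  Finite 3-D rotations are not
vectors, so angular velocity cannot be obtained by differentiating attitude
angles directly; instead the angular-velocity (Poisson) matrix of the rotating
frame is formed,

    Omega = dR/dt . R^-1,

which is skew-symmetric for an exactly orthonormal R, and the velocity vector
is read off its off-diagonal entries.  This module houses that extraction plus
the small set of derived series the rest of the package needs: Euler-angle
decomposition, joint angular velocity by proximal/distal subtraction, angular
displacement and acceleration, resampling, and the inverse operation
(integration of an angular-velocity series into an orientation stream) used by
the synthetic-trial generator and by round-trip tests.

Conventions
-----------
* Rotation matrices map body coordinates into the global frame.
* ``Frame.GLOBAL`` velocities come from ``dR/dt R^T``; ``Frame.BODY`` from
  ``R^T dR/dt``.
* All angles are radians, all rates rad/s, timestamps seconds.
* Derivatives are second-order central differences (one-sided at endpoints),
  adequate at 100 Hz for signal content up to the 12 Hz tremor ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .errors import UnsupportedOperation, ValidationError

__all__ = [
    "Frame",
    "GimbalLockWarning",
    "OrientationTrace",
    "AngularVelocityTrace",
    "poisson_angular_velocity",
    "euler_decompose",
    "joint_angular_velocity",
    "angular_displacement",
    "angular_acceleration",
    "resample",
    "resample_angular_velocity",
    "integrate_angular_velocity",
    "orthonormalize_rotations",
]

#: tolerance on ||R^T R - I||_inf after load-time orthonormalization
ORTHONORMALITY_TOL = 1e-6
#: maximum timestamp jitter as a fraction of the nominal sampling period
JITTER_TOL = 0.01


class Frame(str, Enum):
    """Reference frame of an angular-velocity series."""

    GLOBAL = "global"
    BODY = "body"


class GimbalLockWarning(UserWarning):
    """Euler decomposition requested near a gimbal-locked attitude."""


def _check_uniform_timestamps(timestamps: np.ndarray) -> tuple[np.ndarray, float]:
    """Validate strictly increasing, uniformly spaced timestamps.

    Returns the array as float64 together with the nominal period.
    """
    t = np.asarray(timestamps, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValidationError("timestamps must be a 1-D array with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("timestamps must be strictly increasing")
    nominal = (t[-1] - t[0]) / (t.size - 1)
    if np.max(np.abs(dt - nominal)) > JITTER_TOL * nominal:
        raise ValidationError(
            f"non-uniform sampling: jitter exceeds {JITTER_TOL:.0%} of the "
            f"nominal period {nominal:.6g} s"
        )
    return t, nominal


def orthonormalize_rotations(rotations: np.ndarray) -> np.ndarray:
    """Project near-rotation matrices onto SO(3) via SVD (polar projection)."""
    U, _, Vt = np.linalg.svd(rotations)
    R = U @ Vt
    # enforce det +1 by flipping the smallest singular direction where needed
    det = np.linalg.det(R)
    bad = det < 0
    if np.any(bad):
        U = U.copy()
        U[bad, :, -1] *= -1.0
        R = U @ Vt
    return R


@dataclass
class OrientationTrace:
    """A single sensor's time series of rigid-body orientations.

    Parameters
    ----------
    timestamps : (n,) array of seconds, strictly increasing and uniform.
    rotations : (n, 3, 3) array of proper orthonormal matrices (body->global).
    """

    timestamps: np.ndarray
    rotations: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps, self._dt = _check_uniform_timestamps(self.timestamps)
        R = np.asarray(self.rotations, dtype=float)
        if R.shape != (self.timestamps.size, 3, 3):
            raise ValidationError(
                f"rotations must have shape (n, 3, 3) matching {self.timestamps.size} "
                f"timestamps; got {R.shape}"
            )
        if self.timestamps.size < 3:
            raise ValidationError("an orientation trace needs at least 3 samples")
        eye = np.eye(3)
        err = np.max(np.abs(R.transpose(0, 2, 1) @ R - eye))
        if err > ORTHONORMALITY_TOL:
            raise ValidationError(
                f"rotations deviate from orthonormality by {err:.3g} "
                f"(> {ORTHONORMALITY_TOL:.0e}); orthonormalize first"
            )
        if np.any(np.linalg.det(R) <= 0):
            raise ValidationError("rotations must be proper (det +1)")
        self.rotations = R

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def dt(self) -> float:
        return self._dt

    @property
    def sample_rate(self) -> float:
        return 1.0 / self._dt

    @classmethod
    def from_quaternions(
        cls,
        timestamps: np.ndarray,
        quaternions_wxyz: np.ndarray,
        *,
        norm_tol: float = 1e-3,
    ) -> "OrientationTrace":
        """Build a trace from scalar-first unit quaternions.

        Quaternions whose norm deviates from 1 by more than ``norm_tol`` are
        rejected; smaller deviations are silently renormalized.
        """
        q = np.asarray(quaternions_wxyz, dtype=float)
        if q.ndim != 2 or q.shape[1] != 4:
            raise ValidationError("quaternions must have shape (n, 4), scalar first")
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > norm_tol):
            worst = np.max(np.abs(norms - 1.0))
            raise ValidationError(
                f"quaternion norm deviates from 1 by {worst:.3g} (> {norm_tol:g})"
            )
        q = q / norms[:, None]
        # scipy uses scalar-last storage
        R = Rotation.from_quat(np.roll(q, -1, axis=1)).as_matrix()
        return cls(timestamps, R)

    def as_quaternions(self) -> np.ndarray:
        """Return scalar-first unit quaternions with temporal sign continuity."""
        q = np.roll(Rotation.from_matrix(self.rotations).as_quat(), 1, axis=1)
        if q[0, 0] < 0:
            q[0] = -q[0]
        # fix antipodal sign flips so the series is differentiable
        flips = np.cumsum(np.sum(q[1:] * q[:-1], axis=1) < 0) % 2
        q[1:][flips == 1] *= -1.0
        return q


@dataclass
class AngularVelocityTrace:
    """Timestamped 3-vector angular velocity series (rad/s) with a frame tag."""

    timestamps: np.ndarray
    omega: np.ndarray
    frame: Frame = Frame.GLOBAL

    def __post_init__(self) -> None:
        self.timestamps, self._dt = _check_uniform_timestamps(self.timestamps)
        w = np.asarray(self.omega, dtype=float)
        if w.shape != (self.timestamps.size, 3):
            raise ValidationError(
                f"omega must have shape (n, 3) matching {self.timestamps.size} "
                f"timestamps; got {w.shape}"
            )
        self.omega = w
        self.frame = Frame(self.frame)

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def dt(self) -> float:
        return self._dt

    @property
    def sample_rate(self) -> float:
        return 1.0 / self._dt

    def norm(self) -> np.ndarray:
        """Euclidean norm of the velocity vector at each sample."""
        return np.linalg.norm(self.omega, axis=1)


def poisson_angular_velocity(
    trace: OrientationTrace, frame: Frame = Frame.GLOBAL
) -> AngularVelocityTrace:
    """Extract angular velocity from an orientation series.

    The rate-of-change matrix dR/dt is estimated by central differences
    (one-sided at the endpoints) and combined with the attitude into the
    angular-velocity matrix ``Omega = dR/dt R^T`` (global frame; ``R^T dR/dt``
    for the body frame).  Omega is skew-symmetrized as ``(Omega - Omega^T)/2``
    before the components are read off, which suppresses the symmetric part
    introduced by finite differencing.
    """
    if len(trace) < 3:
        raise ValidationError("angular-velocity extraction needs at least 3 samples")
    R = trace.rotations
    Rdot = np.gradient(R, trace.dt, axis=0)
    if Frame(frame) is Frame.GLOBAL:
        Om = Rdot @ R.transpose(0, 2, 1)
    else:
        Om = R.transpose(0, 2, 1) @ Rdot
    Om = 0.5 * (Om - Om.transpose(0, 2, 1))
    omega = np.stack([Om[:, 2, 1], Om[:, 0, 2], Om[:, 1, 0]], axis=1)
    return AngularVelocityTrace(trace.timestamps.copy(), omega, Frame(frame))


def euler_decompose(
    trace: OrientationTrace,
    convention: str = "ZYX",
    *,
    unwrap: bool = True,
    gimbal_tol: float = 1e-3,
) -> np.ndarray:
    """Per-sample Euler angles (rad) in the given axis order.

    Angles are unwrapped along time so consecutive samples never jump by 2*pi.
    Attitudes within ``gimbal_tol`` rad of gimbal lock trigger a
    :class:`GimbalLockWarning` but the decomposition is still returned.
    """
    angles = Rotation.from_matrix(trace.rotations).as_euler(convention)
    # middle angle saturates at +-pi/2 (asymmetric) or 0/pi (symmetric order)
    mid = angles[:, 1]
    symmetric = convention[0].upper() == convention[2].upper()
    lock = np.pi if symmetric else np.pi / 2
    dist = np.min(np.abs(np.abs(mid)[:, None] - np.array([0.0, lock])), axis=1) if symmetric \
        else np.abs(np.abs(mid) - lock)
    if np.any(dist < gimbal_tol):
        warnings.warn(
            f"{int(np.sum(dist < gimbal_tol))} samples within {gimbal_tol:g} rad of "
            f"gimbal lock for convention {convention}",
            GimbalLockWarning,
            stacklevel=2,
        )
    if unwrap:
        angles = np.unwrap(angles, axis=0)
    return angles


def joint_angular_velocity(
    distal: AngularVelocityTrace, proximal: AngularVelocityTrace
) -> AngularVelocityTrace:
    """Joint angular velocity as distal-sensor minus proximal-sensor velocity."""
    if distal.frame is not proximal.frame:
        raise ValidationError("distal and proximal series must share a frame")
    if len(distal) != len(proximal) or not np.allclose(
        distal.timestamps, proximal.timestamps, atol=1e-9, rtol=0.0
    ):
        raise ValidationError("distal and proximal series must share timestamps")
    return AngularVelocityTrace(
        distal.timestamps.copy(), distal.omega - proximal.omega, distal.frame
    )


def angular_displacement(av: AngularVelocityTrace) -> np.ndarray:
    """Per-axis cumulative angular displacement (rad), zero at the first sample."""
    return cumulative_trapezoid(av.omega, av.timestamps, axis=0, initial=0.0)


def angular_acceleration(av: AngularVelocityTrace) -> np.ndarray:
    """Per-axis angular acceleration (rad/s^2) by central differences."""
    if len(av) < 3:
        raise ValidationError("angular acceleration needs at least 3 samples")
    return np.gradient(av.omega, av.dt, axis=0)


def resample(
    timestamps: np.ndarray, values: np.ndarray, target_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a uniformly sampled series onto a faster grid.

    The new grid starts at the first timestamp, steps by ``1/target_rate`` and
    spans the same interval.  Downsampling is refused: the package never needs
    it and silent aliasing would corrupt the tremor band.
    """
    t, nominal = _check_uniform_timestamps(timestamps)
    src_rate = 1.0 / nominal
    if target_rate < src_rate * (1.0 - 1e-9):
        raise UnsupportedOperation(
            f"resample only upsamples (source {src_rate:g} Hz, requested "
            f"{target_rate:g} Hz)"
        )
    v = np.asarray(values, dtype=float)
    if v.shape[0] != t.size:
        raise ValidationError("values must have one row per timestamp")
    n_new = int(np.floor((t[-1] - t[0]) * target_rate + 0.5)) + 1
    t_new = t[0] + np.arange(n_new) / target_rate
    t_new = np.minimum(t_new, t[-1])  # guard fp overshoot at the last point
    if v.ndim == 1:
        v_new = np.interp(t_new, t, v)
    else:
        v_new = np.stack([np.interp(t_new, t, v[:, j]) for j in range(v.shape[1])], axis=1)
    return t_new, v_new


def resample_angular_velocity(
    av: AngularVelocityTrace, target_rate: float
) -> AngularVelocityTrace:
    """Upsample an angular-velocity trace (see :func:`resample`)."""
    t_new, w_new = resample(av.timestamps, av.omega, target_rate)
    return AngularVelocityTrace(t_new, w_new, av.frame)


def integrate_angular_velocity(
    timestamps: np.ndarray,
    omega: np.ndarray,
    R0: np.ndarray | None = None,
    frame: Frame = Frame.GLOBAL,
) -> OrientationTrace:
    """Integrate an angular-velocity series into an orientation stream.

    Uses exact per-step axis-angle increments with the midpoint velocity
    (not a small-angle approximation), so Poisson extraction of the result is
    a genuine round-trip test rather than a shared linearization.
    """
    t, dt = _check_uniform_timestamps(timestamps)
    w = np.asarray(omega, dtype=float)
    if w.shape != (t.size, 3):
        raise ValidationError("omega must have shape (n, 3)")
    R = np.empty((t.size, 3, 3))
    R[0] = np.eye(3) if R0 is None else np.asarray(R0, dtype=float)
    rotvecs = 0.5 * (w[:-1] + w[1:]) * dt
    increments = Rotation.from_rotvec(rotvecs).as_matrix()
    if Frame(frame) is Frame.GLOBAL:
        for k in range(t.size - 1):
            R[k + 1] = increments[k] @ R[k]
    else:
        for k in range(t.size - 1):
            R[k + 1] = R[k] @ increments[k]
    return OrientationTrace(t, orthonormalize_rotations(R))
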