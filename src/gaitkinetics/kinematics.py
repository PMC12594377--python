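"""Augmented joint kinematics: velocity and acceleration from 2-D joint centers.

Video gives only joint-center positions; the additional velocity and
acceleration modalities are produced by backward finite differencing with
fixed edge-handling rules:

* velocity: ``v[0] = 0``, ``v[t] = p[t] - p[t-1]``;
* acceleration: ``a[t] = v[t] - v[t-1]`` for interior frames, with
  ``a[0] = a[1] = a[T-1] = 0``.

By default the raw first differences are returned (units of position per
frame); ``scale_by_rate=True`` multiplies by the sampling rate to obtain
physical units.  The downstream encoders batch-normalize every channel, so
the two conventions differ only by a fixed scale.  No smoothing or low-pass
filtering is applied before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "JointTrajectory",
    "AugmentedKinematics",
    "derive_velocity",
    "derive_acceleration",
    "augment",
]


@dataclass
class JointTrajectory:
    """Height-normalized 2-D joint-center positions, ``[T, channels]``.

    The canonical channel layout is joint-major: for each of the 11 joints,
    (camera-1 x, camera-1 y, camera-2 x, camera-2 y), giving 44 channels.
    """

    positions: np.ndarray
    sampling_rate: float = 100.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2:
            raise InvalidInputError("positions must be a [T, channels] array")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidInputError("positions contain non-finite values")


@dataclass
class AugmentedKinematics:
    """The three video modalities: position, velocity, acceleration."""

    positions: np.ndarray
    velocities: np.ndarray
    accelerations: np.ndarray
    sampling_rate: float = 100.0

    def __iter__(self):
        # convenient (velocity, acceleration, position) ordering is NOT
        # implied here; iteration yields fields in declaration order
        yield self.positions
        yield self.velocities
        yield self.accelerations


def derive_velocity(
    positions: np.ndarray, sampling_rate: float = 100.0, scale_by_rate: bool = False
) -> np.ndarray:
    """Backward-difference velocity with ``v[0] = 0``."""
    p = np.asarray(positions, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
        squeeze = True
    else:
        squeeze = False
    if p.shape[0] < 2:
        raise InvalidInputError("need at least 2 frames to differentiate")
    if not np.all(np.isfinite(p)):
        raise InvalidInputError("positions contain NaN or infinite values")
    v = np.zeros_like(p)
    v[1:] = p[1:] - p[:-1]
    if scale_by_rate:
        v *= sampling_rate
    return v[:, 0] if squeeze else v


def derive_acceleration(
    velocities: np.ndarray, sampling_rate: float = 100.0, scale_by_rate: bool = False
) -> np.ndarray:
    """Backward-difference acceleration with ``a[0] = a[1] = a[T-1] = 0``."""
    v = np.asarray(velocities, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
        squeeze = True
    else:
        squeeze = False
    if v.shape[0] < 3:
        raise InvalidInputError("need at least 3 frames for acceleration")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("velocities contain NaN or infinite values")
    a = np.zeros_like(v)
    a[1:] = v[1:] - v[:-1]
    a[0] = 0.0
    a[1] = 0.0
    a[-1] = 0.0
    if scale_by_rate:
        a *= sampling_rate
    return a[:, 0] if squeeze else a


def augment(
    trajectory: JointTrajectory | np.ndarray,
    sampling_rate: float = 100.0,
    scale_by_rate: bool = False,
) -> AugmentedKinematics:
    """Derive the velocity and acceleration modalities from positions."""
    if isinstance(trajectory, JointTrajectory):
        p = trajectory.positions
        sampling_rate = trajectory.sampling_rate
    else:
        p = np.asarray(trajectory, dtype=float)
    v = derive_velocity(p, sampling_rate, scale_by_rate)
    a = derive_acceleration(v, sampling_rate, scale_by_rate)
    return AugmentedKinematics(
        positions=p.copy(), velocities=v, accelerations=a, sampling_rate=sampling_rate
    )
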