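"""Sagittal joint angles from segment orientations.

The trigonometric joint model works on four sagittal segment inclinations
(trunk, thigh, shank, foot).  In the stand-up neutral pose the conventions are
trunk = +90 deg, thigh = shank = -90 deg, foot = 0 deg; with those values every
joint angle below evaluates to 0 deg:

    ankle = -90 - theta_shank + theta_foot
    knee  = theta_thigh - theta_shank
    hip   = -(theta_trunk - theta_thigh - 180)

Leg segment angles live in [-270, 180] deg, the trunk (and any other segment)
in [-180, 180] deg, and joint angles in [-180, 180] deg.  Wrapping is applied
*after* the affine joint equations, which commute with consistent 360-degree
shifts of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SegmentOrientationSeries",
    "JointAngleSeries",
    "NEUTRAL_POSE",
    "joint_angles",
    "joints_to_segments",
    "joint_velocity",
    "wrap_segment",
    "wrap_joint",
]

#: Segment inclinations (deg) in the stand-up neutral pose.
NEUTRAL_POSE = {"trunk": 90.0, "thigh": -90.0, "shank": -90.0, "foot": 0.0}

_LEG_SEGMENTS = frozenset({"thigh", "shank", "foot"})


@dataclass
class SegmentOrientationSeries:
    """Sagittal inclination time series (deg) for one body side."""

    trunk: np.ndarray
    thigh: np.ndarray
    shank: np.ndarray
    foot: np.ndarray
    fs: float = 100.0
    side: str = "right"

    def __post_init__(self) -> None:
        self.trunk = np.asarray(self.trunk, dtype=float)
        self.thigh = np.asarray(self.thigh, dtype=float)
        self.shank = np.asarray(self.shank, dtype=float)
        self.foot = np.asarray(self.foot, dtype=float)
        n = len(self.trunk)
        if not (len(self.thigh) == len(self.shank) == len(self.foot) == n):
            raise ValueError("segment series must share one length")

    def __len__(self) -> int:
        return len(self.trunk)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs


@dataclass
class JointAngleSeries:
    """Hip/knee/ankle sagittal angles (deg) for one body side.

    ``velocity`` holds the joint angular velocities (deg/s, central
    differences); it is computed lazily by :meth:`angular_velocity`.
    """

    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    fs: float = 100.0
    side: str = "right"
    velocity: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.hip = np.asarray(self.hip, dtype=float)
        self.knee = np.asarray(self.knee, dtype=float)
        self.ankle = np.asarray(self.ankle, dtype=float)
        if not (len(self.hip) == len(self.knee) == len(self.ankle)):
            raise ValueError("joint series must share one length")

    def __len__(self) -> int:
        return len(self.hip)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def angular_velocity(self, joint: str) -> np.ndarray:
        if joint not in self.velocity:
            self.velocity[joint] = joint_velocity(getattr(self, joint), self.fs)
        return self.velocity[joint]


def wrap_joint(theta):
    """Map angles (deg) into [-180, 180) by 360-degree shifts."""
    return (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_segment(theta, kind: str = "leg"):
    """Map a segment angle into its convention range by 360-degree shifts.

    Leg segments (thigh/shank/foot) use [-270, 180); any other segment uses
    [-180, 180).  Idempotent.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("segment angle must be finite")
    lo = -270.0 if kind == "leg" else -180.0
    return (theta - lo) % 360.0 + lo


def joint_angles(segments: SegmentOrientationSeries, wrap: bool = True) -> JointAngleSeries:
    """Compute hip/knee/ankle sagittal angles from segment inclinations.

    Parameters
    ----------
    segments
        Equal-length trunk/thigh/shank/foot inclination series, degrees.
    wrap
        Wrap the results into [-180, 180).  Disable for round-trip algebra on
        unwrapped (continuous) series.
    """
    ankle = -90.0 - segments.shank + segments.foot
    knee = segments.thigh - segments.shank
    hip = -(segments.trunk - segments.thigh - 180.0)
    if wrap:
        hip, knee, ankle = wrap_joint(hip), wrap_joint(knee), wrap_joint(ankle)
    return JointAngleSeries(hip=hip, knee=knee, ankle=ankle, fs=segments.fs,
                            side=segments.side)


def joints_to_segments(joints: JointAngleSeries, trunk) -> SegmentOrientationSeries:
    """Invert the joint equations given a trunk inclination series.

    The joint model is affine and rank-3 in the four segment angles, so the
    trunk series closes the system:

        thigh = trunk - 180 + hip
        shank = thigh - knee
        foot  = ankle + 90 + shank

    Round-tripping through :func:`joint_angles` (with ``wrap=False``) is the
    identity to machine precision.
    """
    trunk = np.asarray(trunk, dtype=float)
    if trunk.shape != joints.hip.shape:
        raise ValueError(
            f"trunk series length {trunk.shape} != joint series length {joints.hip.shape}"
        )
    thigh = trunk - 180.0 + joints.hip
    shank = thigh - joints.knee
    foot = joints.ankle + 90.0 + shank
    return SegmentOrientationSeries(trunk=trunk, thigh=thigh, shank=shank,
                                    foot=foot, fs=joints.fs, side=joints.side)


def joint_velocity(angle, fs: float) -> np.ndarray:
    """Joint angular velocity (deg/s): central differences, one-sided ends."""
    angle = np.asarray(angle, dtype=float)
    if angle.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return np.gradient(angle) * fs
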