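"""Synthetic gait kinematics and raw IMU count streams.

This module replaces the hardware: it generates periodic sagittal joint
trajectories (sums of stride-locked harmonics shaped like normative hip,
knee and ankle curves), converts them to segment inclinations, and synthesizes
the raw 16-bit counts a tri-axial MEMS gyroscope/accelerometer pair would
report, including a 10-s static calibration prelude, constant gyroscope bias,
white noise, slow orientation drift, ADC quantization, and 180-degree turn
events that step up the drift rate.

The simulation is sagittal-plane only: the in-plane (mediolateral) gyro axis
carries the segment's angular rate, the out-of-plane axes carry bias and noise
only; the accelerometer senses the gravity unit vector rotated by the segment
inclination (segment linear acceleration is omitted by default so that the
accelerometer-inclination relationship stays exact).

Gyro counts encode the *backward-difference* rate (theta_k - theta_{k-1})*fs:
a rate gyro is the sensor a downstream integrator consumes, and emitting the
discrete increments makes rectangular integration reconstruct the angle
exactly, leaving ADC quantization as the only noiseless-path error.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .kinematics import (
    NEUTRAL_POSE,
    JointAngleSeries,
    SegmentOrientationSeries,
    joint_velocity,
    joints_to_segments,
)

__all__ = [
    "GaitProfile",
    "SensorParams",
    "RawImuTrial",
    "default_profile",
    "generate_joint_trajectories",
    "generate_trunk_series",
    "joints_to_segments",
    "synthesize_imu",
    "simulate_trial",
    "inject_turn",
    "make_regression_benchmark",
    "SENSOR_LAYOUT",
]

#: (segment, side) keys of the 7-sensor lower-body layout.
SENSOR_LAYOUT = (
    ("trunk", "center"),
    ("thigh", "right"), ("shank", "right"), ("foot", "right"),
    ("thigh", "left"), ("shank", "left"), ("foot", "left"),
)

_COUNT_LIMIT = 2 ** 15 - 1


@dataclass
class GaitProfile:
    """Stride-periodic sagittal joint trajectory description.

    Each joint angle is ``offset + sum_k A_k * sin(2*pi*k*t/T + phi_k)`` with
    stride period ``T = 2 * 60 / cadence`` seconds (two steps per stride).
    ``harmonic_coeffs`` maps joint name -> list of (amplitude deg, phase rad)
    for harmonics k = 1, 2, ...; an optional ``"trunk"`` entry adds sway on
    top of the neutral 90 deg + ``trunk_lean``.
    """

    cadence: float = 105.0            # steps/min
    n_cycles: int = 10                # strides
    terrain: str = "flat"
    speed_label: str = "normal"
    harmonic_coeffs: dict = field(default_factory=dict)
    offsets: dict = field(default_factory=dict)   # deg, per joint
    trunk_lean: float = 0.0           # deg, constant forward lean

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for joint, coeffs in self.harmonic_coeffs.items():
            for amp, _ in coeffs:
                if not np.isfinite(amp):
                    raise ValueError(f"non-finite amplitude for {joint}")

    @property
    def stride_period(self) -> float:
        """Stride duration in seconds (two steps)."""
        return 2.0 * 60.0 / self.cadence


@dataclass
class SensorParams:
    """IMU signal-chain parameters.

    ``gyro_scale`` (0.06 deg/s per count) and ``acc_scale`` (0.00024 g per
    count) are the fixed factors of a +/-2000 deg/s gyro and +/-8 g
    accelerometer read through a 16-bit ADC.  ``drift_slope`` is the
    orientation drift rate (deg/s) injected as a constant angular-rate offset
    during the motion phase only (the static prelude is drift-free, so static
    calibration cannot cancel it); a mapping keyed by segment name gives
    sensor-specific drift.
    """

    fs: float = 100.0
    gyro_noise_sd: float = 0.0        # deg/s
    gyro_bias: tuple = (0.0, 0.0, 0.0)  # deg/s per axis
    acc_noise_sd: float = 0.0         # g
    gyro_scale: float = 0.06
    acc_scale: float = 0.00024
    drift_slope: float | Mapping[str, float] = 0.0
    calibration_window: float = 10.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fs <= 200):
            raise ValueError("fs must be in (0, 200] Hz")
        if self.gyro_scale <= 0 or self.acc_scale <= 0:
            raise ValueError("scale factors must be positive")

    def drift_for(self, segment: str) -> float:
        if isinstance(self.drift_slope, Mapping):
            return float(self.drift_slope.get(segment, 0.0))
        return float(self.drift_slope)


@dataclass
class RawImuTrial:
    """Raw counts for a set of IMUs plus trial metadata.

    ``sensors`` maps (segment, side) -> {"gyro": (n,3) int array,
    "acc": (n,3) int array}.  ``truth`` (simulation only, not serialized with
    the counts) maps the same keys to the ground-truth inclination series.
    """

    t: np.ndarray
    sensors: dict
    fs: float
    calibration_window: float = 10.0
    turn_index: int | None = None
    meta: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_static(self) -> int:
        """Number of samples in the static calibration prelude."""
        return int(round(self.calibration_window * self.fs))

    def static_slice(self) -> slice:
        return slice(0, self.n_static)

    def motion_slice(self) -> slice:
        return slice(self.n_static, len(self.t))

    def validate(self) -> None:
        dt = np.diff(self.t)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs,
                                                           rtol=0, atol=1e-6)):
            raise ValueError("timestamps must be strictly increasing and uniform at 1/fs")
        for key, ch in self.sensors.items():
            for name in ("gyro", "acc"):
                arr = ch[name]
                if arr.shape != (len(self.t), 3):
                    raise ValueError(f"{key} {name} shape {arr.shape} != (n, 3)")
                if np.any(np.abs(arr) > _COUNT_LIMIT):
                    raise ValueError(f"{key} {name} counts exceed 16-bit range")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to integer, halves away from zero (unbiased 16-bit ADC model)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x).astype(np.int32)


# Normative-looking sagittal harmonic sets (amplitude deg, phase rad) per
# stride, loosely shaped on adult treadmill gait: hip ~ single oscillation
# -10..30 deg, knee ~ double bump 0..60 deg, ankle ~ -15..10 deg.
_FLAT_HARMONICS = {
    "hip": [(18.0, 1.25), (4.0, -0.5)],
    "knee": [(24.0, -1.85), (12.0, 2.2), (4.0, 0.3)],
    "ankle": [(9.0, -2.6), (6.5, 0.9)],
    "trunk": [(1.5, 0.0)],
}
_SPEED_TABLE = {"slow": (85.0, 0.85), "normal": (105.0, 1.0), "fast": (125.0, 1.15)}
_TERRAIN_ADJUST = {
    # (hip offset, knee offset, ankle offset, trunk lean) deg
    "flat": (8.0, 30.0, -2.0, 0.0),
    "ramp_ascend": (14.0, 30.0, 4.0, 5.0),
    "ramp_descend": (4.0, 30.0, -8.0, -3.0),
    "stair_ascend": (22.0, 38.0, 6.0, 6.0),
    "stair_descend": (6.0, 40.0, -10.0, -2.0),
}


def default_profile(terrain: str = "flat", speed: str = "normal",
                    n_cycles: int = 10) -> GaitProfile:
    """A realistic default gait profile for a terrain/speed condition."""
    if terrain not in _TERRAIN_ADJUST:
        raise ValueError(f"unknown terrain {terrain!r}")
    if speed not in _SPEED_TABLE:
        raise ValueError(f"unknown speed {speed!r}")
    cadence, amp_scale = _SPEED_TABLE[speed]
    hip_off, knee_off, ankle_off, lean = _TERRAIN_ADJUST[terrain]
    coeffs = {j: [(a * amp_scale, p) for a, p in h] for j, h in _FLAT_HARMONICS.items()}
    return GaitProfile(
        cadence=cadence, n_cycles=n_cycles, terrain=terrain, speed_label=speed,
        harmonic_coeffs=coeffs,
        offsets={"hip": hip_off, "knee": knee_off, "ankle": ankle_off},
        trunk_lean=lean,
    )


def _harmonic_series(coeffs, offset: float, t: np.ndarray, period: float,
                     phase_frac: float = 0.0) -> np.ndarray:
    theta = np.full_like(t, float(offset))
    tau = t / period + phase_frac
    for k, (amp, phase) in enumerate(coeffs, start=1):
        theta += amp * np.sin(2.0 * np.pi * k * tau + phase)
    return theta


def generate_joint_trajectories(profile: GaitProfile, sensor: SensorParams,
                                side: str = "right",
                                phase_frac: float = 0.0) -> JointAngleSeries:
    """Sample the profile's joint harmonics at the sensor rate.

    ``phase_frac`` shifts the trajectory by a fraction of the stride; the
    contralateral side of a symmetric gait uses ``phase_frac=0.5``.
    """
    period = profile.stride_period
    n = int(round(profile.n_cycles * period * sensor.fs))
    t = np.arange(n) / sensor.fs
    series = {}
    for joint in ("hip", "knee", "ankle"):
        coeffs = profile.harmonic_coeffs.get(joint, [])
        offset = profile.offsets.get(joint, 0.0)
        series[joint] = _harmonic_series(coeffs, offset, t, period, phase_frac)
    return JointAngleSeries(hip=series["hip"], knee=series["knee"],
                            ankle=series["ankle"], fs=sensor.fs, side=side)


def generate_trunk_series(profile: GaitProfile, n: int, fs: float,
                          phase_frac: float = 0.0) -> np.ndarray:
    """Trunk inclination: neutral 90 deg + lean + optional sway harmonics."""
    t = np.arange(n) / fs
    coeffs = profile.harmonic_coeffs.get("trunk", [])
    return _harmonic_series(coeffs, NEUTRAL_POSE["trunk"] + profile.trunk_lean,
                            t, profile.stride_period, phase_frac)


def _angle_map(segments) -> dict:
    if isinstance(segments, SegmentOrientationSeries):
        return {
            ("trunk", "center"): segments.trunk,
            ("thigh", segments.side): segments.thigh,
            ("shank", segments.side): segments.shank,
            ("foot", segments.side): segments.foot,
        }
    return dict(segments)


def synthesize_imu(segments, sensor: SensorParams) -> RawImuTrial:
    """Synthesize raw IMU counts from segment inclination series.

    ``segments`` is a :class:`SegmentOrientationSeries` (one side + trunk) or
    a mapping of (segment, side) -> inclination series sharing one length.
    A static prelude of ``sensor.calibration_window`` seconds at the initial
    pose is prepended; gyro bias and noise act everywhere, drift acts in the
    motion phase only.
    """
    angle_map = _angle_map(segments)
    lengths = {len(v) for v in angle_map.values()}
    if len(lengths) != 1:
        raise ValueError("all segment series must share one length")
    for key, theta in angle_map.items():
        if not np.all(np.isfinite(theta)):
            raise ValueError(f"segment series {key} contains non-finite values")
    n_motion = lengths.pop()
    fs = sensor.fs
    n_pre = int(round(sensor.calibration_window * fs))
    n = n_pre + n_motion
    t = np.arange(n) / fs
    rng = np.random.default_rng(sensor.seed)
    bias = np.asarray(sensor.gyro_bias, dtype=float)

    sensors, truth = {}, {}
    for key in sorted(angle_map):
        segment, _side = key
        theta_motion = np.asarray(angle_map[key], dtype=float)
        theta = np.concatenate([np.full(n_pre, theta_motion[0]), theta_motion])
        # backward-difference rate about the mediolateral (y) axis
        omega = np.empty(n)
        omega[0] = 0.0
        omega[1:] = np.diff(theta) * fs
        drift = np.zeros(n)
        drift[n_pre:] = sensor.drift_for(segment)

        gyro_dps = np.column_stack([
            np.full(n, bias[0]),
            omega + bias[1] + drift,
            np.full(n, bias[2]),
        ])
        if sensor.gyro_noise_sd > 0:
            gyro_dps = gyro_dps + rng.normal(0.0, sensor.gyro_noise_sd, (n, 3))

        rad = np.deg2rad(theta)
        acc_g = np.column_stack([np.sin(rad), np.zeros(n), np.cos(rad)])
        if sensor.acc_noise_sd > 0:
            acc_g = acc_g + rng.normal(0.0, sensor.acc_noise_sd, (n, 3))

        sensors[key] = {
            "gyro": _round_half_away(gyro_dps / sensor.gyro_scale),
            "acc": _round_half_away(acc_g / sensor.acc_scale),
        }
        truth[key] = theta

    trial = RawImuTrial(
        t=t, sensors=sensors, fs=fs,
        calibration_window=sensor.calibration_window,
        meta={
            "seed": sensor.seed,
            "drift_slope": (dict(sensor.drift_slope)
                            if isinstance(sensor.drift_slope, Mapping)
                            else float(sensor.drift_slope)),
            "gyro_scale": sensor.gyro_scale,
            "acc_scale": sensor.acc_scale,
        },
        truth=truth,
    )
    trial.validate()
    return trial


def simulate_trial(profile: GaitProfile, sensor: SensorParams) -> RawImuTrial:
    """Full 7-sensor trial: trunk + bilateral thigh/shank/foot.

    The left side runs half a stride out of phase.  Ground-truth segment and
    joint series are kept on the returned trial (``truth`` and
    ``meta["truth_joints"]``) for benchmarking.
    """
    angle_map: dict = {}
    joints_truth: dict = {}
    for side, frac in (("right", 0.0), ("left", 0.5)):
        joints = generate_joint_trajectories(profile, sensor, side=side,
                                             phase_frac=frac)
        trunk = generate_trunk_series(profile, len(joints), sensor.fs)
        seg = joints_to_segments(joints, trunk)
        angle_map[("thigh", side)] = seg.thigh
        angle_map[("shank", side)] = seg.shank
        angle_map[("foot", side)] = seg.foot
        joints_truth[side] = joints
    angle_map[("trunk", "center")] = generate_trunk_series(
        profile, len(angle_map[("thigh", "right")]), sensor.fs)

    trial = synthesize_imu(angle_map, sensor)
    trial.meta.update(terrain=profile.terrain, speed_label=profile.speed_label,
                      cadence=profile.cadence, n_cycles=profile.n_cycles)
    trial.meta["truth_joints"] = joints_truth
    return trial


def inject_turn(trial: RawImuTrial, at: float,
                multiplier: float = 2.0) -> RawImuTrial:
    """Mark a 180-degree turn and scale the post-turn drift rate.

    After ``at`` seconds the injected drift slope of every sensor is
    multiplied by ``multiplier`` (1.0 leaves the trial unchanged apart from
    the turn marker).  Returns a new trial; the input is not modified.
    """
    duration = len(trial) / trial.fs
    if not (0.0 <= at <= duration):
        raise ValueError(f"turn time {at} s outside trial [0, {duration:.2f}] s")
    out = copy.deepcopy(trial)
    turn_index = int(round(at * trial.fs))
    out.turn_index = turn_index
    out.meta["turn_multiplier"] = float(multiplier)
    gyro_scale = trial.meta.get("gyro_scale", 0.06)
    drift_meta = trial.meta.get("drift_slope", 0.0)
    start = max(turn_index, trial.n_static)
    for key, ch in out.sensors.items():
        segment = key[0]
        d = (drift_meta.get(segment, 0.0) if isinstance(drift_meta, Mapping)
             else float(drift_meta))
        extra_dps = (multiplier - 1.0) * d
        if extra_dps == 0.0:
            continue
        gyro = ch["gyro"].astype(float)
        gyro[start:, 1] += extra_dps / gyro_scale
        ch["gyro"] = _round_half_away(gyro)
    return out


def make_regression_benchmark(n_subjects: int = 5, n_cycles: int = 12,
                              drift_slope: float = 0.05, offset: float = -4.5,
                              noise_sd: float = 0.5, fs: float = 100.0,
                              seed: int = 0):
    """Multi-subject drift-corrupted joint-angle benchmark for the regressors.

    Each synthetic subject walks with a random cadence and amplitude scaling
    (drawn around the normal-speed defaults); the "measured" angle is the
    true ankle angle passed through the error chain of a fused-but-
    uncorrected estimate: slight amplitude attenuation and phase lag (the
    fixed-gain filter is a lagging low-pass on the correction path), a
    constant offset, a linear drift, and band-limited low-frequency noise
    (the fusion residual varies slowly, not sample-to-sample).  The lag term
    is what makes the angular-velocity input informative: the induced error
    is approximately -lag * angular velocity, invisible to an angle-only
    regressor.

    Returns ``(X, y, groups)``: X columns are [measured angle, measured
    angular velocity] (deg, deg/s), y is the reference angle, groups the
    subject index (for subject-wise cross-validation).
    """
    rng = np.random.default_rng(seed)
    X_parts, y_parts, g_parts = [], [], []
    for subject in range(n_subjects):
        cadence = rng.uniform(90.0, 120.0)
        amp = rng.uniform(0.85, 1.15)
        prof = default_profile("flat", "normal", n_cycles=n_cycles)
        prof.cadence = cadence
        prof.harmonic_coeffs = {j: [(a * amp, p) for a, p in h]
                                for j, h in prof.harmonic_coeffs.items()}
        sensor = SensorParams(fs=fs, seed=seed + 1000 + subject)
        joints = generate_joint_trajectories(prof, sensor)
        t = joints.t
        true = joints.ankle
        from scipy.ndimage import gaussian_filter1d

        smooth = gaussian_filter1d(rng.normal(0.0, 1.0, len(true)),
                                   sigma=0.2 * fs, mode="nearest")
        sd = smooth.std()
        if sd > 0:
            smooth *= noise_sd / sd
        lag = rng.uniform(0.01, 0.03)          # s, filter group delay
        atten = rng.uniform(0.95, 0.99)        # filter amplitude loss
        mean = true.mean()
        lagged = mean + atten * (np.interp(t - lag, t, true) - mean)
        measured = lagged + offset + drift_slope * t + smooth
        vel = joint_velocity(measured, fs)
        X_parts.append(np.column_stack([measured, vel]))
        y_parts.append(true)
        g_parts.append(np.full(len(true), subject))
    return (np.vstack(X_parts), np.concatenate(y_parts),
            np.concatenate(g_parts))
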