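"""Static IMU calibration from the 10-s stand-up prelude.

Every trial begins with the wearer standing still for ``window`` seconds.
Over that window the gyroscope offset per axis is the mean of the scaled
rates, and the accelerometer reference norm is the Euclidean norm of the
per-axis mean counts.  Afterwards

    gyro_calibrated [deg/s] = raw * gyro_scale - offset
    acc_calibrated  [g]     = raw / acc_norm

No pre-defined parameters carry over between trials: a fresh
:class:`StaticCalibrator` starts from zero state and is fit on each trial's
own prelude.  The offset is computed on *scaled* values (counts * 0.06) so
that the subtraction in the gyro equation is dimensionally consistent.

Dividing raw counts by the window-mean norm maps the static gravity vector to
unit length: the raw counts and the norm share the count unit, so the nominal
0.00024 g/count factor cancels; it is kept only for reporting raw axes in g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

GYRO_SCALE = 0.06      # deg/s per count (+/-2000 deg/s full scale, 16 bit)
ACC_SCALE = 0.00024    # g per count (+/-8 g full scale, 16 bit)

__all__ = [
    "GYRO_SCALE",
    "ACC_SCALE",
    "CalibrationState",
    "StaticCalibrator",
    "estimate_gyro_offset",
    "estimate_acc_norm",
    "calibrate_gyro",
    "calibrate_acc",
    "calibrate_trial",
]


@dataclass
class CalibrationState:
    """Per-sensor calibration parameters estimated from a static window."""

    gyro_offset: np.ndarray = field(
        default_factory=lambda: np.zeros(3))   # deg/s, starts at zero
    acc_norm: float = 0.0                      # counts, starts at zero
    gyro_scale: float = GYRO_SCALE
    acc_scale: float = ACC_SCALE
    window: float = 10.0                       # s

    @property
    def calibrated(self) -> bool:
        return self.acc_norm > 0


def _check_window(samples: np.ndarray, window: float, fs: float) -> np.ndarray:
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("static samples must be an (n, 3) array")
    need = int(round(window * fs))
    if samples.shape[0] < need:
        raise ValueError(
            f"static window needs >= {need} samples at fs={fs}, got {samples.shape[0]}")
    if not np.all(np.isfinite(samples)):
        raise ValueError("static samples contain non-finite values")
    return samples


def estimate_gyro_offset(static_samples, window: float = 10.0,
                         fs: float = 100.0,
                         gyro_scale: float = GYRO_SCALE) -> np.ndarray:
    """Gyro offset (deg/s per axis): mean of scaled counts over the window."""
    samples = _check_window(static_samples, window, fs)
    return samples.mean(axis=0) * gyro_scale


def estimate_acc_norm(static_samples, window: float = 10.0,
                      fs: float = 100.0) -> float:
    """Accelerometer reference norm (counts): norm of the per-axis means."""
    samples = _check_window(static_samples, window, fs)
    norm = float(np.linalg.norm(samples.mean(axis=0)))
    if norm == 0.0:
        raise ValueError("all-zero accelerometer window: sensor fault")
    return norm


def calibrate_gyro(raw, state: CalibrationState) -> np.ndarray:
    """Apply the gyro calibration: counts -> deg/s."""
    if not state.calibrated:
        raise ValueError("calibration state not estimated")
    return np.asarray(raw, dtype=float) * state.gyro_scale - state.gyro_offset


def calibrate_acc(raw, state: CalibrationState) -> np.ndarray:
    """Apply the accelerometer calibration: counts -> g (unit gravity)."""
    if state.acc_norm <= 0:
        raise ValueError("accelerometer norm not estimated (or zero)")
    return np.asarray(raw, dtype=float) / state.acc_norm


class StaticCalibrator(BaseEstimator, TransformerMixin):
    """Estimate and apply static calibration for one IMU.

    Parameters
    ----------
    window : float
        Static prelude length in seconds (default 10).
    fs : float
        Sampling rate in Hz.
    validate_posture : bool
        Reject windows that are not plausibly static: scaled gyro standard
        deviation above ``max_gyro_sd`` or accelerometer norm varying more
        than ``max_acc_var`` relative to its mean.  An incorrect posture
        during the stand-up steady-state corrupts the whole trial.

    ``fit`` consumes an (n, 6) array of static-window counts, columns
    ``gx,gy,gz,ax,ay,az``; ``transform`` maps (n, 6) counts to calibrated
    ``[deg/s x3, g x3]``.
    """

    def __init__(self, window: float = 10.0, fs: float = 100.0,
                 gyro_scale: float = GYRO_SCALE, acc_scale: float = ACC_SCALE,
                 validate_posture: bool = True, max_gyro_sd: float = 3.0,
                 max_acc_var: float = 0.05):
        self.window = window
        self.fs = fs
        self.gyro_scale = gyro_scale
        self.acc_scale = acc_scale
        self.validate_posture = validate_posture
        self.max_gyro_sd = max_gyro_sd
        self.max_acc_var = max_acc_var

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 6:
            raise ValueError("expected (n, 6) static counts gx,gy,gz,ax,ay,az")
        gyro, acc = X[:, :3], X[:, 3:]
        offset = estimate_gyro_offset(gyro, self.window, self.fs, self.gyro_scale)
        norm = estimate_acc_norm(acc, self.window, self.fs)
        if self.validate_posture:
            gyro_sd = float(np.max(np.std(gyro * self.gyro_scale, axis=0)))
            if gyro_sd > self.max_gyro_sd:
                raise ValueError(
                    f"static window rejected: gyro sd {gyro_sd:.2f} deg/s > "
                    f"{self.max_gyro_sd} (subject not standing still?)")
            norms = np.linalg.norm(acc, axis=1)
            rel = float(np.max(np.abs(norms - norms.mean()))) / max(norms.mean(), 1e-12)
            if rel > self.max_acc_var:
                raise ValueError(
                    f"static window rejected: accel norm varies {100 * rel:.1f}% > "
                    f"{100 * self.max_acc_var:.0f}%")
        self.state_ = CalibrationState(
            gyro_offset=offset, acc_norm=norm,
            gyro_scale=self.gyro_scale, acc_scale=self.acc_scale,
            window=self.window)
        return self

    def transform(self, X):
        if not hasattr(self, "state_"):
            raise ValueError("StaticCalibrator is not fitted")
        X = np.asarray(X, dtype=float)
        gyro = calibrate_gyro(X[:, :3], self.state_)
        acc = calibrate_acc(X[:, 3:], self.state_)
        return np.column_stack([gyro, acc])


def calibrate_trial(trial, window: float | None = None,
                    validate_posture: bool = True) -> dict:
    """Fit a :class:`StaticCalibrator` per sensor on a trial's prelude.

    Returns (segment, side) -> :class:`CalibrationState`.
    """
    window = trial.calibration_window if window is None else window
    gyro_scale = trial.meta.get("gyro_scale", GYRO_SCALE)
    acc_scale = trial.meta.get("acc_scale", ACC_SCALE)
    sl = slice(0, int(round(window * trial.fs)))
    states = {}
    for key, ch in trial.sensors.items():
        X = np.column_stack([ch["gyro"][sl], ch["acc"][sl]])
        cal = StaticCalibrator(window=window, fs=trial.fs,
                               gyro_scale=gyro_scale, acc_scale=acc_scale,
                               validate_posture=validate_posture).fit(X)
        states[key] = cal.state_
    return states
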