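"""Sagittal segment orientation from calibrated gyro/accelerometer streams.

Three estimators of the segment inclination theta(t) are provided:

* :func:`integrate_gyro` — rectangular integration of the angular rate; the
  drifting baseline (a rate bias b produces a linear trend of slope b).
* :class:`ComplementaryFilter` — the production filter:
  ``theta_k = g_gyro * (theta_{k-1} + omega_k / fs) + g_acc * acc_angle_k``
  with gains 0.98 / 0.02, trusting the gyro short-term and the accelerometer
  inclination long-term.
* :class:`SagittalKalmanFilter` — linear Kalman filter with state
  ``[angle, gyro bias]`` and the fixed 2x2 covariances
  ``Q = diag(0.005, 0.0003)`` and ``R = diag(0.0669, 0.039)``.

Both filters are initialized from the trigonometric accelerometer
inclination, since integration alone cannot observe the initial pose.

Kalman measurement model.  The angle channel observes the state directly
(``H`` row [1, 0], variance 0.0669).  The rate channel observes the gyro
bias: the raw rate is (true rate + bias), and the accelerometer-derived
angle differentiated numerically supplies an independent estimate of the
true rate, so ``z2 = omega - d(acc_angle)/dt`` measures the bias state
(``H`` row [0, 1], variance 0.039).  This is the only non-circular pairing
of a 2-vector measurement with the [angle, bias] state when the raw rate
already drives the prediction step.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DEFAULT_Q",
    "DEFAULT_R",
    "accel_inclination",
    "acc_angle_series",
    "unwrap_degrees",
    "integrate_gyro",
    "ComplementaryFilter",
    "SagittalKalmanFilter",
    "estimate_segment_angles",
]

DEFAULT_Q = np.array([[0.005, 0.0], [0.0, 0.0003]])
DEFAULT_R = np.array([[0.0669, 0.0], [0.0, 0.039]])


def accel_inclination(acc) -> np.ndarray | float:
    """Sagittal inclination (deg) of a quasi-static calibrated accel vector.

    ``atan2(a_anterior, a_vertical)`` with the anterior axis in column 0 and
    the vertical axis in column 2.  Rejects near-free-fall vectors
    (norm <= 0.5 g), for which gravity direction is unreliable.
    """
    acc = np.asarray(acc, dtype=float)
    single = acc.ndim == 1
    vec = np.atleast_2d(acc)
    norm = np.linalg.norm(vec, axis=1)
    if np.any(norm <= 0.5):
        raise ValueError("accelerometer norm <= 0.5 g: unreliable inclination")
    angle = np.degrees(np.arctan2(vec[:, 0], vec[:, 2]))
    return float(angle[0]) if single else angle


def unwrap_degrees(angle, reference: float | None = None) -> np.ndarray:
    """Remove 360-degree jumps; optionally shift near a reference angle."""
    out = np.unwrap(np.asarray(angle, dtype=float), period=360.0)
    if reference is not None:
        out = out + 360.0 * np.round((reference - out[0]) / 360.0)
    return out


def acc_angle_series(acc_g, reference: float | None = None) -> np.ndarray:
    """Per-sample accelerometer inclination, unwrapped for filtering."""
    return unwrap_degrees(accel_inclination(acc_g), reference)


def integrate_gyro(gyro, theta0: float, fs: float,
                   scheme: str = "rectangular") -> np.ndarray:
    """Cumulative integration of the angular rate (deg/s) from ``theta0``.

    Rectangular (Euler, matching a fixed-step real-time loop) by default;
    ``scheme="trapezoid"`` averages consecutive rates.
    """
    gyro = np.asarray(gyro, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not np.all(np.isfinite(gyro)):
        raise ValueError("gyro series contains non-finite values")
    theta = np.empty(len(gyro))
    theta[0] = theta0
    if scheme == "rectangular":
        inc = gyro[1:] / fs
    elif scheme == "trapezoid":
        inc = 0.5 * (gyro[1:] + gyro[:-1]) / fs
    else:
        raise ValueError(f"unknown integration scheme {scheme!r}")
    theta[1:] = theta0 + np.cumsum(inc)
    return theta


def _validate_pair(gyro, acc_angle):
    gyro = np.asarray(gyro, dtype=float)
    acc_angle = np.asarray(acc_angle, dtype=float)
    if gyro.shape != acc_angle.shape or gyro.ndim != 1:
        raise ValueError("gyro and acc_angle must be equal-length 1-d series")
    if not (np.all(np.isfinite(gyro)) and np.all(np.isfinite(acc_angle))):
        raise ValueError("filter inputs contain non-finite values")
    return gyro, acc_angle


class ComplementaryFilter(BaseEstimator, TransformerMixin):
    """Fixed-gain complementary filter for sagittal inclination.

    The output at sample 0 is the initial angle; from sample 1 the recurrence
    ``theta_k = gain_gyro * (theta_{k-1} + omega_k / fs) + gain_acc * z_k``
    applies, with ``z`` the accelerometer inclination.  With zero rate and a
    zero accelerometer target the output decays exactly geometrically,
    ``theta_k = theta_0 * gain_gyro**k``.

    Stateless transformer: ``transform(X)`` takes columns
    ``[omega deg/s, acc_angle deg]``.
    """

    def __init__(self, gain_gyro: float = 0.98, gain_acc: float = 0.02,
                 fs: float = 100.0):
        self.gain_gyro = gain_gyro
        self.gain_acc = gain_acc
        self.fs = fs

    def _check(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isclose(self.gain_gyro + self.gain_acc, 1.0):
            raise ValueError("complementary gains must sum to 1")

    def filter(self, gyro, acc_angle, theta0: float | None = None) -> np.ndarray:
        self._check()
        gyro, acc_angle = _validate_pair(gyro, acc_angle)
        if theta0 is None:
            theta0 = acc_angle[0]
        # IIR form: theta_k = gg*theta_{k-1} + u_k,
        # u_k = gg*omega_k/fs + ga*z_k; lfilter carries gg*theta_{k-1}
        # with the same op order as the explicit recurrence.
        u = self.gain_gyro * (gyro[1:] / self.fs) + self.gain_acc * acc_angle[1:]
        out = np.empty(len(gyro))
        out[0] = theta0
        if len(gyro) > 1:
            out[1:], _ = lfilter([1.0], [1.0, -self.gain_gyro], u,
                                 zi=[self.gain_gyro * theta0])
        return out

    def fit(self, X, y=None):
        self._check()
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return self.filter(X[:, 0], X[:, 1])


class SagittalKalmanFilter(BaseEstimator, TransformerMixin):
    """Linear Kalman filter, state [inclination deg, gyro bias deg/s].

    Prediction: ``theta_k = theta_{k-1} + (omega_k - bias) / fs`` with the
    raw rate as control input; the bias is a random walk.  Update: see the
    module docstring.  ``Q`` and ``R`` are per-step covariances.
    """

    def __init__(self, Q=None, R=None, fs: float = 100.0,
                 p0: tuple = (1.0, 0.1)):
        self.Q = Q
        self.R = R
        self.fs = fs
        self.p0 = p0

    def _matrices(self):
        Q = DEFAULT_Q if self.Q is None else np.asarray(self.Q, dtype=float)
        R = DEFAULT_R if self.R is None else np.asarray(self.R, dtype=float)
        for name, M in (("Q", Q), ("R", R)):
            if M.shape != (2, 2) or not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric 2x2")
            if np.any(np.linalg.eigvalsh(M) < -1e-12):
                raise ValueError(f"{name} must be positive semi-definite")
        return Q, R

    def filter(self, gyro, acc_angle, theta0: float | None = None,
               return_bias: bool = False):
        Q, R = self._matrices()
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        gyro, acc_angle = _validate_pair(gyro, acc_angle)
        dt = 1.0 / self.fs
        if theta0 is None:
            theta0 = acc_angle[0]
        n = len(gyro)
        # independent true-rate reference from the accelerometer inclination
        acc_rate = np.gradient(acc_angle) * self.fs if n > 1 else np.zeros(n)

        F = np.array([[1.0, -dt], [0.0, 1.0]])
        H = np.eye(2)
        I2 = np.eye(2)
        x = np.array([theta0, 0.0])
        P = np.diag(self.p0).astype(float)
        theta = np.empty(n)
        bias = np.empty(n)
        theta[0], bias[0] = x
        for k in range(1, n):
            x = F @ x + np.array([gyro[k] * dt, 0.0])
            P = F @ P @ F.T + Q
            z = np.array([acc_angle[k], gyro[k] - acc_rate[k]])
            S = H @ P @ H.T + R
            K = P @ H.T @ np.linalg.inv(S)
            x = x + K @ (z - H @ x)
            P = (I2 - K @ H) @ P
            theta[k], bias[k] = x
        return (theta, bias) if return_bias else theta

    def fit(self, X, y=None):
        self._matrices()
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return self.filter(X[:, 0], X[:, 1])


def estimate_segment_angles(trial, states, method: str = "complementary",
                            filter_params: dict | None = None) -> dict:
    """Estimate every sensor's inclination series for a whole trial.

    Parameters
    ----------
    trial : RawImuTrial
    states : mapping (segment, side) -> CalibrationState
    method : "complementary", "kalman" or "integration"
    filter_params : extra keyword arguments for the filter constructor.

    Returns (segment, side) -> inclination series (deg, full trial length).
    The initial angle is the accelerometer inclination of the mean calibrated
    gravity vector over the static prelude.
    """
    from .calibration import calibrate_acc, calibrate_gyro

    filter_params = dict(filter_params or {})
    filter_params.setdefault("fs", trial.fs)
    out = {}
    sl = trial.static_slice()
    for key, ch in trial.sensors.items():
        state = states[key]
        gyro_dps = calibrate_gyro(ch["gyro"], state)[:, 1]  # sagittal axis
        acc_g = calibrate_acc(ch["acc"], state)
        theta0 = accel_inclination(acc_g[sl].mean(axis=0))
        acc_ang = acc_angle_series(acc_g, reference=theta0)
        if method == "complementary":
            est = ComplementaryFilter(**filter_params).filter(
                gyro_dps, acc_ang, theta0)
        elif method == "kalman":
            est = SagittalKalmanFilter(**filter_params).filter(
                gyro_dps, acc_ang, theta0)
        elif method == "integration":
            est = integrate_gyro(gyro_dps, theta0, trial.fs)
        else:
            raise ValueError(f"unknown fusion method {method!r}")
        out[key] = est
    return out
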