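"""Agreement and benchmarking metrics for test-vs-reference signal pairs.

Implements the quantitative suite used to benchmark a wearable joint-angle
estimate against a reference system: range-normalized RMSE, Pearson
correlation, cross-approximate entropy (XApEn), linear drift slope and drift
ratio, the percentage drift increment across a 180-degree turn, Bland-Altman
limits of agreement, a one-sample t-test, and System Usability Scale scoring.

NRMSE divides the RMSE by the reference signal's range (max - min); on joint
angles with tens-of-degrees range this yields the dimensionless ~0.06-0.12
magnitudes conventional in gait benchmarking.  Lower XApEn means the two
series are more synchronous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "SusResponse",
    "nrmse",
    "pearson_rho",
    "xapen",
    "drift_slope",
    "drift_ratio",
    "turn_drift_increment",
    "bland_altman",
    "one_sample_ttest",
    "sus_score",
    "agreement_report",
    "trim_transients",
]


def _pair(test, ref):
    test = np.asarray(test, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if test.shape != ref.shape:
        raise ValueError(f"length mismatch: {test.shape} vs {ref.shape}")
    if test.size == 0:
        raise ValueError("empty series")
    return test, ref


def nrmse(test, ref) -> float:
    """RMSE normalized by the reference range (max - min), dimensionless."""
    test, ref = _pair(test, ref)
    span = float(ref.max() - ref.min())
    if span == 0.0:
        raise ValueError("constant reference: NRMSE undefined (zero range)")
    return float(np.sqrt(np.mean((test - ref) ** 2)) / span)


def pearson_rho(test, ref) -> float:
    """Sample Pearson correlation coefficient."""
    test, ref = _pair(test, ref)
    if test.size < 2:
        raise ValueError("need at least 2 samples")
    if np.std(test) == 0.0 or np.std(ref) == 0.0:
        raise ValueError("constant input: correlation undefined")
    return float(np.corrcoef(test, ref)[0, 1])


def xapen(test, ref, m: int = 2, r: float = 0.2,
          standardize: bool = True) -> float:
    """Cross-approximate entropy XApEn(m, r) of ``test`` patterns in ``ref``.

    Both series are standardized (zero mean, unit SD) before comparison, so
    ``r`` is a fraction of the reference SD.  Phi_m is the average log of the
    fraction of m-length reference templates within Chebyshev distance ``r``
    of each m-length test template; XApEn = Phi_m - Phi_{m+1}.  Zero means
    perfectly synchronous pattern statistics; larger means more asynchronous.
    """
    test, ref = _pair(test, ref)
    n = test.size
    if n < m + 2:
        raise ValueError(f"series length {n} < m + 2 = {m + 2}")
    if standardize:
        # a constant series keeps its (degenerate) template set unscaled
        test = (test - test.mean()) / (np.std(test) or 1.0)
        ref = (ref - ref.mean()) / (np.std(ref) or 1.0)

    def phi(mm: int) -> float:
        nt = n - mm + 1
        u = np.lib.stride_tricks.sliding_window_view(test, mm)  # (nt, mm)
        v = np.lib.stride_tricks.sliding_window_view(ref, mm)
        c = np.empty(nt)
        block = max(1, int(2e6 / max(nt, 1)))  # bound the distance buffer
        for start in range(0, nt, block):
            d = np.max(np.abs(u[start:start + block, None, :] - v[None, :, :]),
                       axis=2)
            c[start:start + block] = np.count_nonzero(d <= r, axis=1) / nt
        if np.any(c == 0.0):
            raise ValueError(
                "a template found no match within r; increase r or series length")
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def drift_slope(series, t) -> float:
    """Ordinary least-squares slope of the series against time (deg/s)."""
    series = np.asarray(series, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if series.shape != t.shape or series.size < 2:
        raise ValueError("need equal-length series and time with >= 2 samples")
    if np.ptp(t) == 0.0:
        raise ValueError("degenerate time vector")
    A = np.column_stack([t, np.ones_like(t)])
    slope, _ = np.linalg.lstsq(A, series, rcond=None)[0]
    return float(slope)


def drift_ratio(test_series, ref_series, t) -> float:
    """|drift slope of test| / |drift slope of reference|."""
    s_ref = drift_slope(ref_series, t)
    if abs(s_ref) < 1e-12:   # far below any physical drift rate
        raise ValueError("zero reference drift slope")
    return abs(drift_slope(test_series, t)) / abs(s_ref)


def turn_drift_increment(series, t, turn_index: int) -> float:
    """Percentage increase of the drift slope after a 180-degree turn.

    ``100 * (|slope_after| - |slope_before|) / |slope_before|`` with slopes
    fit separately before and after ``turn_index``.
    """
    series = np.asarray(series, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if not (2 <= turn_index <= len(series) - 2):
        raise ValueError("turn_index must leave >= 2 samples on each side")
    before = abs(drift_slope(series[:turn_index], t[:turn_index]))
    after = abs(drift_slope(series[turn_index:], t[turn_index:]))
    if before == 0.0:
        raise ValueError("zero pre-turn drift slope")
    return 100.0 * (after - before) / before


def bland_altman(test, ref) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD)."""
    test, ref = _pair(test, ref)
    if test.size < 2:
        raise ValueError("need at least 2 samples")
    d = test - ref
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def one_sample_ttest(values, mu0: float = 0.0,
                     alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided one-sample t-test: (t, p, reject at ``alpha``)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(values, ddof=1) == 0.0:
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(values, popmean=mu0)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


@dataclass
class SusResponse:
    """One user's answers to the 10-item usability questionnaire (1-5)."""

    items: tuple

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        if len(items) != 10:
            raise ValueError("SUS response needs exactly 10 items")
        if any(not 1 <= v <= 5 for v in items):
            raise ValueError("SUS items must be integers in 1..5")
        self.items = items

    def score(self) -> float:
        contrib = sum((v - 1) if i % 2 == 0 else (5 - v)
                      for i, v in enumerate(self.items))
        return contrib * 2.5


def sus_score(responses) -> tuple[list, float]:
    """Per-user SUS scores (0-100) and their mean.

    Odd questionnaire items (1, 3, 5, 7, 9) contribute (response - 1), even
    items contribute (5 - response); the sum is scaled by 2.5.
    """
    scored = [r.score() if isinstance(r, SusResponse) else SusResponse(r).score()
              for r in responses]
    if not scored:
        raise ValueError("no responses")
    return scored, float(np.mean(scored))


def trim_transients(series, t, lead: float = 2.0, tail: float = 2.0):
    """Drop the acceleration/deceleration transients at the trial ends.

    Removes the first ``lead`` and last ``tail`` seconds before drift-slope
    style analyses.
    """
    series = np.asarray(series, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    keep = (t >= t[0] + lead) & (t <= t[-1] - tail)
    if keep.sum() < 2:
        raise ValueError("trimming leaves fewer than 2 samples")
    return series[keep], t[keep]


@dataclass
class AgreementReport:
    """Bundle of agreement metrics for one test-vs-reference pair."""

    nrmse: float
    rho: float
    xapen: float
    drift_slope_test: float
    drift_slope_ref: float
    drift_ratio: float | None
    ba_mean_diff: float
    ba_limits: tuple

    def as_dict(self) -> dict:
        return {
            "nrmse": self.nrmse,
            "rho": self.rho,
            "xapen": self.xapen,
            "drift_slope_test": self.drift_slope_test,
            "drift_slope_ref": self.drift_slope_ref,
            "drift_ratio": self.drift_ratio,
            "ba_mean_diff": self.ba_mean_diff,
            "ba_lo": self.ba_limits[0],
            "ba_hi": self.ba_limits[1],
        }


def agreement_report(test, ref, t=None, xapen_m: int = 2,
                     xapen_r: float = 0.2) -> AgreementReport:
    """Compute the full agreement suite for a signal pair."""
    test, ref = _pair(test, ref)
    if t is None:
        t = np.arange(test.size, dtype=float)
    s_test = drift_slope(test, t)
    s_ref = drift_slope(ref, t)
    ratio = abs(s_test) / abs(s_ref) if s_ref != 0.0 else None
    mean, lo, hi = bland_altman(test, ref)
    return AgreementReport(
        nrmse=nrmse(test, ref),
        rho=pearson_rho(test, ref),
        xapen=xapen(test, ref, m=xapen_m, r=xapen_r),
        drift_slope_test=s_test,
        drift_slope_ref=s_ref,
        drift_ratio=ratio,
        ba_mean_diff=mean,
        ba_limits=(lo, hi),
    )
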