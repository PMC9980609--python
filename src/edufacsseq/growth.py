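"""Growth-curve metrics from OD600 time series.

Max V is the steepest slope of the growth curve: the maximum over sliding
windows of the least-squares slope of OD against time (plate-reader "Max V"
semantics, computed on raw OD by default). Lag time is the tangent-line
construction: the time at which the line through the max-slope window, at the
window midpoint, crosses the initial OD. Total growth is max(OD) - OD[0], and
AUC is the trapezoidal integral of blank-corrected OD (negatives floored at
zero). A log-OD mode gives the specific growth rate (1/h) instead of OD/h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GrowthCurve",
    "GrowthMetrics",
    "CorrelationResult",
    "max_v",
    "lag_time",
    "total_growth",
    "auc",
    "summarize",
    "correlate_growth_labeling",
]


@dataclass
class GrowthCurve:
    """An OD600 time series: strictly increasing times (h) and aligned OD."""

    times: np.ndarray
    od: np.ndarray
    blank: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.od = np.asarray(self.od, float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be 1-d arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class GrowthMetrics:
    max_v: float            # OD/h
    lag_time: float         # h
    lag_defined: bool       # False when the culture never grew
    total_growth: float     # delta OD
    auc: float              # OD*h


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


def _window_slopes(curve: GrowthCurve, window: int, log_od: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares slope (and fitted midpoint value/time) per window."""
    if window < 3:
        raise ValueError("window must be >= 3 points")
    if len(curve) < window:
        raise ValueError(f"curve has {len(curve)} points; window of {window} required")
    y = curve.od.astype(float)
    if log_od:
        y = np.log(np.maximum(y, 1e-9))
    t = curve.times
    n = len(t) - window + 1
    slopes = np.empty(n)
    mid_t = np.empty(n)
    mid_y = np.empty(n)
    for i in range(n):
        tw, yw = t[i:i + window], y[i:i + window]
        tm, ym = tw.mean(), yw.mean()
        dt = tw - tm
        slopes[i] = float(dt @ (yw - ym) / (dt @ dt))
        mid_t[i] = tm
        mid_y[i] = ym  # fitted value at the mean time equals the mean of y
    return slopes, mid_t, mid_y


def max_v(curve: GrowthCurve, window: int = 5, log_od: bool = False) -> float:
    """Steepest sliding-window regression slope (OD/h, or 1/h if log_od).

    Not clamped: a declining culture reports its (possibly negative) maximum
    slope.
    """
    slopes, _, _ = _window_slopes(curve, window, log_od)
    return float(slopes.max())


def lag_time(curve: GrowthCurve, window: int = 5) -> tuple[float, bool]:
    """Tangent-intercept lag: where the max-slope tangent meets the initial OD.

    Returns ``(lag_hours, defined)``. When the maximum slope is <= 0 the lag
    is undefined and reported as the full duration with ``defined=False``.
    The lag is clamped to [0, duration].
    """
    slopes, mid_t, mid_y = _window_slopes(curve, window, log_od=False)
    i = int(np.argmax(slopes))
    m = slopes[i]
    if m <= 0:
        return curve.duration, False
    lag = mid_t[i] - (mid_y[i] - curve.od[0]) / m
    return float(np.clip(lag, 0.0, curve.duration)), True


def total_growth(curve: GrowthCurve) -> float:
    """max(OD) - OD[0]; invariant to any constant offset."""
    if len(curve) < 2:
        raise ValueError("total_growth needs >= 2 points")
    return float(curve.od.max() - curve.od[0])


def auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the blank-corrected curve (OD*h).

    Blank-corrected values below zero are floored at 0 before integration,
    so the result is non-negative.
    """
    if len(curve) < 2:
        raise ValueError("auc needs >= 2 points")
    y = np.maximum(curve.od - curve.blank, 0.0)
    return float(np.trapezoid(y, curve.times))


def summarize(curve: GrowthCurve, window: int = 5) -> GrowthMetrics:
    lag, defined = lag_time(curve, window)
    return GrowthMetrics(
        max_v=max_v(curve, window),
        lag_time=lag,
        lag_defined=defined,
        total_growth=total_growth(curve),
        auc=auc(curve),
    )


def correlate_growth_labeling(max_vs, edu_fracs) -> CorrelationResult:
    """Pearson correlation of Max V against EdU-positive proportion.

    Two-sided p from the t distribution with n-2 degrees of freedom.
    """
    x = np.asarray(max_vs, float)
    y = np.asarray(edu_fracs, float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p_value=float(res.pvalue), n=n)
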