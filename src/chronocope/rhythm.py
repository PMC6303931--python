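"""Diurnal-rhythm quantification: LOWESS, fixed-24-h cosinor, AUC, strength.

The analysis chain mirrors the standard chronobiology workflow for short,
unevenly sampled time courses: a locally weighted regression (LOWESS, 5-point
window, tricube weights, no robustness iterations) smooths the series, a
sinusoid with the period fixed at 24 h is fitted by ordinary least squares on
the harmonic basis {1, cos, sin}, and summary metrics are derived from the
smoothed curve (area under the curve), the fit (amplitude, acrophase) and the
raw series (rhythm strength, i.e. the fraction of variance carried by the
24-h component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import InsufficientDataError, SingularDesignError, UndefinedStatisticError

__all__ = [
    "TimeSeries",
    "SineFit",
    "RhythmMetrics",
    "lowess_smooth",
    "fit_sine24",
    "compute_auc",
    "rhythm_strength_24h",
    "vmax",
    "rhythm_metrics",
]

_PERIOD_H = 24.0


@dataclass(frozen=True)
class TimeSeries:
    """One channel of one individual: (time in hCT hours, value) pairs.

    Times are strictly increasing and may exceed 24 across recording days.
    """

    times: np.ndarray
    values: np.ndarray
    channel: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise InsufficientDataError("times and values must be equal-length 1-D")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InsufficientDataError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(self.times, values, self.channel, self.units)

    def window(self, t_min: float, t_max: float) -> "TimeSeries":
        """The sub-series with ``t_min <= t < t_max``."""
        mask = (self.times >= t_min) & (self.times < t_max)
        return TimeSeries(self.times[mask], self.values[mask], self.channel, self.units)


@dataclass(frozen=True)
class SineFit:
    """Least-squares fixed-period sinusoid: mesor, amplitude, acrophase, R^2.

    The fitted curve is ``mesor + amplitude * cos(2*pi*(t - acrophase)/24)``
    with the acrophase (time of peak) in [0, 24) hCT.
    """

    mesor: float
    amplitude: float
    acrophase: float
    r_squared: float
    n: int

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.mesor + self.amplitude * np.cos(
            2.0 * np.pi * (t - self.acrophase) / _PERIOD_H
        )


@dataclass(frozen=True)
class RhythmMetrics:
    """Per-individual, per-channel rhythm summary."""

    auc: float
    amplitude: float
    acrophase: float
    rhythm_strength: float | None = None
    vmax: float | None = None


def lowess_smooth(ts: TimeSeries, window_points: int = 5) -> TimeSeries:
    """LOWESS smooth evaluated at the input times.

    Locally weighted *linear* regression with tricube weights over the
    ``window_points`` nearest neighbours (span ``min(1, k/n)``) and zero
    robustness iterations.  A series already on a straight line is returned
    unchanged up to rounding.
    """
    if window_points < 3:
        raise InsufficientDataError("window_points must be >= 3")
    n = len(ts)
    if n < 3:
        raise InsufficientDataError("LOWESS needs at least 3 points")
    frac = min(1.0, (window_points + 1e-9) / n)
    smoothed = _sm_lowess(
        ts.values, ts.times, frac=frac, it=0, return_sorted=False
    )
    return ts.with_values(np.asarray(smoothed, dtype=float))


def _harmonic_design(times: np.ndarray) -> np.ndarray:
    w = 2.0 * np.pi * times / _PERIOD_H
    return np.column_stack([np.ones_like(times), np.cos(w), np.sin(w)])


def fit_sine24(ts: TimeSeries) -> SineFit:
    """Fit ``M + A*cos(2*pi*(t - phi)/24)`` by closed-form OLS.

    The model is linear on the basis {1, cos(wt), sin(wt)}; the amplitude is
    ``hypot(a, b)`` and the acrophase the atan2-derived peak time folded into
    [0, 24).  A constant series yields amplitude 0 and (by convention) R^2 0.
    """
    n = len(ts)
    if n < 4:
        raise InsufficientDataError("sinusoid fit needs at least 4 points")
    folded = np.sort(np.unique(np.round(np.mod(ts.times, _PERIOD_H), 9)))
    if folded.size < 3:
        raise SingularDesignError(
            "need >= 3 distinct times modulo 24 h for a sinusoid fit"
        )
    design = _harmonic_design(ts.times)
    beta, _, rank, _ = np.linalg.lstsq(design, ts.values, rcond=None)
    if rank < 3:
        raise SingularDesignError("harmonic design is rank-deficient")
    mesor, a, b = (float(x) for x in beta)
    amplitude = float(np.hypot(a, b))
    acrophase = float(np.mod(np.arctan2(b, a) / (2.0 * np.pi) * _PERIOD_H, _PERIOD_H))
    residuals = ts.values - design @ beta
    sst = float(np.sum((ts.values - ts.values.mean()) ** 2))
    r2 = 0.0 if sst == 0.0 else float(1.0 - np.sum(residuals**2) / sst)
    return SineFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acrophase,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n=n,
    )


def compute_auc(
    ts: TimeSeries, window_points: int = 5, presmooth: bool = True
) -> float:
    """Trapezoidal area under the (LOWESS-smoothed) curve.

    Integrates over the observed window [t_first, t_last].  With fewer than
    three points the smoothing step is skipped (a two-point series is its own
    local line).
    """
    if len(ts) < 2:
        raise InsufficientDataError("AUC needs at least 2 points")
    series = ts
    if presmooth and len(ts) >= 3:
        series = lowess_smooth(ts, window_points=window_points)
    return float(np.trapezoid(series.values, series.times))


def rhythm_strength_24h(ts: TimeSeries) -> float:
    """Fraction of variance explained by the fixed-24-h harmonic (R^2).

    Computed on the unsmoothed series; dimensionless in [0, 1].  Requires at
    least 8 points spanning at least 48 h and non-zero variance.
    """
    if len(ts) < 8 or (ts.times[-1] - ts.times[0]) < 48.0:
        raise InsufficientDataError(
            "rhythm strength needs >= 8 points spanning >= 48 h"
        )
    if float(np.var(ts.values)) == 0.0:
        raise UndefinedStatisticError("rhythm strength undefined for constant series")
    return fit_sine24(ts).r_squared


def vmax(activity: TimeSeries, n_days: int = 3) -> float:
    """Mean of the per-24-h-window maxima over the first ``n_days`` days."""
    t0 = activity.times[0]
    span = activity.times[-1] - t0
    if span < n_days * _PERIOD_H - ACTIVITY_EDGE_TOL:
        raise InsufficientDataError(
            f"series spans {span:.1f} h; vmax over {n_days} days needs "
            f">= {n_days * 24} h"
        )
    maxima = []
    for d in range(n_days):
        window = activity.window(t0 + d * _PERIOD_H, t0 + (d + 1) * _PERIOD_H)
        if len(window) == 0:
            raise InsufficientDataError(f"no observations in 24-h window {d + 1}")
        maxima.append(float(window.values.max()))
    return float(np.mean(maxima))


#: Tolerance for a trace that ends one bin short of an exact day multiple.
ACTIVITY_EDGE_TOL = 1.0


def rhythm_metrics(
    ts: TimeSeries,
    window_points: int = 5,
    with_strength: bool = False,
    with_vmax: bool = False,
    n_days: int = 3,
) -> RhythmMetrics:
    """AUC + cosinor metrics for one series.

    The sinusoid is fitted on the LOWESS curve (amplitude, acrophase), the AUC
    integrates the same curve, and rhythm strength -- when requested -- is the
    harmonic R^2 of the raw series.
    """
    smoothed = lowess_smooth(ts, window_points=window_points)
    fit = fit_sine24(smoothed)
    return RhythmMetrics(
        auc=compute_auc(ts, window_points=window_points),
        amplitude=fit.amplitude,
        acrophase=fit.acrophase,
        rhythm_strength=rhythm_strength_24h(ts) if with_strength else None,
        vmax=vmax(ts, n_days=n_days) if with_vmax else None,
    )
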