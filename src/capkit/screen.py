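"""Per-strain metrics of the CAP knockdown screen.

Three readouts per strain: the maximum specific growth rate from a
logistic fit of the nutrient-rich growth curve, viability after a fixed
incubation in human whole blood (CFU/ml, possibly at the limit of
detection), and phage sensitivity as the area under the turbidity curve
during phage co-incubation — a lower AUC means stronger lysis, i.e. more
residual capsule.  ``screen_summary`` assembles the normalized screen
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import CfuSeries, GrowthCurve, logistic_od

__all__ = [
    "GrowthFit",
    "fit_growth_rate",
    "phage_sensitivity_auc",
    "blood_viability",
    "screen_summary",
]


@dataclass(frozen=True)
class GrowthFit:
    """Logistic-fit result: od(t) = K*od0*e^{mu t}/(K - od0 + od0 e^{mu t})."""

    mu_max: float
    carrying_capacity: float
    od0: float
    rss: float
    converged: bool
    note: str = ""

    def __post_init__(self) -> None:
        if self.mu_max < 0 or self.rss < 0:
            raise ValueError("mu_max and rss must be non-negative")


def _window_slope(times: np.ndarray, od: np.ndarray, window: int = 5) -> float:
    """Maximum sliding-window slope of ln(OD): a model-free growth rate."""
    logod = np.log(np.clip(od, 1e-9, None))
    best = 0.0
    for i in range(len(times) - window + 1):
        t, y = times[i:i + window], logod[i:i + window]
        slope = np.polyfit(t, y, 1)[0]
        best = max(best, slope)
    return best


def fit_growth_rate(curve: GrowthCurve, method: str = "logistic") -> GrowthFit:
    """Maximum specific growth rate from an OD600 time series.

    Default is nonlinear least squares of the logistic model with
    multi-start initialization over a grid of growth-rate guesses; the
    ``loglinear`` alternative reports the steepest sliding-window slope of
    ln(OD).  A curve with no net growth returns mu_max = 0 with a
    diagnostic note rather than failing.
    """
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od600, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points spanning the growth phase")
    if np.any(od <= 0):
        raise ValueError("OD values must be positive for growth fitting")

    od0_guess = max(od[0], 1e-6)
    k_guess = max(od.max(), od0_guess * 1.01)
    rss_flat = float(np.sum((od - od.mean()) ** 2))
    # no measurable growth: flat or monotone-decreasing series
    if od.max() <= od[0] * 1.02:
        return GrowthFit(mu_max=0.0, carrying_capacity=k_guess, od0=od0_guess,
                         rss=rss_flat, converged=True,
                         note="no net growth; mu_max set to 0")

    if method == "loglinear":
        mu = max(_window_slope(t, od), 0.0)
        return GrowthFit(mu_max=mu, carrying_capacity=k_guess, od0=od0_guess,
                         rss=float("nan"), converged=True, note="loglinear")
    if method != "logistic":
        raise ValueError("method must be 'logistic' or 'loglinear'")

    best = None
    for mu0 in (0.1, 0.3, 0.8, 1.5, 3.0):
        try:
            popt, _ = curve_fit(
                logistic_od, t, od, p0=(od0_guess, mu0, k_guess),
                bounds=([1e-9, 0.0, od0_guess * 0.1],
                        [k_guess * 2.0, 50.0, k_guess * 10.0]),
                maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((logistic_od(t, *popt) - od) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        mu = max(_window_slope(t, od), 0.0)
        return GrowthFit(mu_max=mu, carrying_capacity=k_guess, od0=od0_guess,
                         rss=float("nan"), converged=False,
                         note="logistic fit failed; loglinear fallback")
    (od0, mu, k), rss = best
    return GrowthFit(mu_max=float(mu), carrying_capacity=float(k),
                     od0=float(od0), rss=rss, converged=True)


def phage_sensitivity_auc(curve: GrowthCurve, window_h: float = 6.0) -> float:
    """Area under the turbidity curve over [0, window_h] (OD*h).

    Trapezoidal integration of OD600; lower AUC means greater phage
    sensitivity.  If the sampling grid extends past the window, the curve
    is linearly interpolated at the window boundary.
    """
    t = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od600, dtype=float)
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    if t[0] > 0 or t[-1] < window_h:
        raise ValueError(f"curve must cover [0, {window_h}] h")
    inside = (t >= 0) & (t <= window_h)
    tt, yy = t[inside], od[inside]
    if tt[-1] < window_h:
        tt = np.append(tt, window_h)
        yy = np.append(yy, np.interp(window_h, t, od))
    return float(np.trapezoid(yy, tt))


def blood_viability(series: CfuSeries, at_h: float = 6.0,
                    tol_h: float = 0.5) -> tuple[float, bool]:
    """Viable count (CFU/ml) at the requested incubation time.

    Returns (value, censored).  The nearest sampled time within ``tol_h``
    is used; interpolation of plate counts is deliberately not done.
    """
    t = np.asarray(series.times, dtype=float)
    i = int(np.argmin(np.abs(t - at_h)))
    if abs(t[i] - at_h) > tol_h:
        raise ValueError(f"no sample within {tol_h} h of t={at_h} h")
    return float(series.cfu_per_ml[i]), bool(series.censored[i])


def _minmax(values: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; a degenerate range maps to 1."""
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi - lo <= 0:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def screen_summary(fits: Sequence[GrowthFit],
                   viabilities: Sequence[tuple[float, bool]],
                   aucs: Sequence[float],
                   strains: Sequence[str]) -> pd.DataFrame:
    """Assemble the normalized screen table, one row per strain.

    Each metric is min-max normalized to [0, 1]; higher score means more
    wild-type-like (faster growth, higher blood viability, higher phage
    AUC).  Censored viabilities are pinned to score 0 regardless of the
    LOD value.  Strain order is preserved from the input.
    """
    n = len(strains)
    if not (len(fits) == len(viabilities) == len(aucs) == n):
        raise ValueError("all metrics must cover the same strain set")
    growth = np.array([f.mu_max for f in fits], dtype=float)
    viab = np.array([v for v, _ in viabilities], dtype=float)
    cens = np.array([c for _, c in viabilities], dtype=bool)
    auc = np.asarray(aucs, dtype=float)

    viab_score = _minmax(viab)
    viab_score[cens] = 0.0
    df = pd.DataFrame({
        "strain": list(strains),
        "growth_rate": growth,
        "blood_viability": viab,
        "blood_censored": cens,
        "phage_auc": auc,
        "growth_score": _minmax(growth),
        "viability_score": viab_score,
        "phage_score": _minmax(auc),
    })
    return df
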