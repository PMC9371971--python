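"""Dose-toxicity regression and TD50-based maximum tolerated dose.

Per-dose-group severe-toxicity fractions (endpoint: >10% body-weight loss
or death) are fitted by nonlinear least squares to the log-dose logistic

    p(d) = 1 / (1 + (TD50 / d)^h)

with multi-start initialization over a log-spaced TD50 grid.  Uncertainty
comes from a nonparametric bootstrap that resamples mice within dose
groups.  The maximum tolerated dose is reported as the TD50 of this
endpoint (an optional safety multiplier is exposed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import ToxCohort, toxicity_probability

__all__ = ["ToxFit", "fit_td50", "mtd_from_fit", "mtd_fold_change"]


@dataclass(frozen=True)
class ToxFit:
    """Fitted log-dose logistic with bootstrap uncertainty on TD50 (CFU)."""

    td50: float
    hill: float
    converged: bool
    n_boot: int = 0
    td50_se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    boot_td50: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.converged and (self.td50 <= 0 or self.hill <= 0):
            raise ValueError("converged fit requires td50 > 0 and hill > 0")


_LN10 = math.log(10.0)


def _p_of_logdose(x: np.ndarray, log_td50: float, hill: float) -> np.ndarray:
    # p = 1/(1 + 10^(hill*(log_td50 - x))), the logistic on log10 dose
    return 1.0 / (1.0 + 10.0 ** (hill * (log_td50 - x)))


def _jac(x: np.ndarray, log_td50: float, hill: float) -> np.ndarray:
    p = _p_of_logdose(x, log_td50, hill)
    q = _LN10 * p * (1.0 - p)
    return np.column_stack([-hill * q, (x - log_td50) * q])


def _ls_fit(log_doses: np.ndarray, fractions: np.ndarray,
            starts: list[tuple[float, float]]) -> tuple[float, float, float] | None:
    best = None
    for x0, h0 in starts:
        try:
            popt, _ = curve_fit(_p_of_logdose, log_doses, fractions,
                                p0=(x0, h0), jac=_jac,
                                bounds=([log_doses.min() - 3, 0.05],
                                        [log_doses.max() + 3, 50.0]),
                                maxfev=10000)
        except RuntimeError:
            continue
        rss = float(np.sum((_p_of_logdose(log_doses, *popt) - fractions) ** 2))
        if best is None or rss < best[2]:
            best = (float(popt[0]), float(popt[1]), rss)
    return best


def fit_td50(cohort: ToxCohort, n_boot: int = 0, seed: int | None = None,
             hill_starts: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)) -> ToxFit:
    """Least-squares fit of group toxicity fractions on log10 dose.

    Requires at least three dose groups and an identifiable response (not
    all-toxic, not all-safe).  With ``n_boot`` > 0, mice are resampled with
    replacement within their dose groups and the fit repeated (started from
    the point estimate) to form a percentile confidence interval for TD50.
    """
    doses = cohort.doses
    if doses.size < 3:
        raise ValueError("need at least 3 dose groups to identify TD50")
    fractions = cohort.fractions
    if np.all(fractions >= 1.0) or np.all(fractions <= 0.0):
        raise ValueError("TD50 not identifiable: cohort is all-toxic or all-safe")
    x = np.log10(doses)
    starts = [(x0, h0) for x0 in np.linspace(x.min(), x.max(), 3)
              for h0 in hill_starts]
    best = _ls_fit(x, fractions, starts)
    if best is None:
        return ToxFit(td50=float("nan"), hill=float("nan"), converged=False)
    log_td50, hill, _ = best
    td50 = 10.0 ** log_td50

    if n_boot <= 0:
        return ToxFit(td50=td50, hill=hill, converged=True)

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        bf = np.array([grp[rng.integers(0, grp.size, grp.size)].mean()
                       for grp in cohort.outcomes])
        if np.all(bf >= 1.0) or np.all(bf <= 0.0):
            continue  # unidentifiable resample
        res = _ls_fit(x, bf, [(log_td50, hill)])
        if res is not None:
            boot.append(10.0 ** res[0])
    boot = np.asarray(boot)
    if boot.size < max(10, n_boot // 10):
        return ToxFit(td50=td50, hill=hill, converged=True, n_boot=boot.size)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ToxFit(td50=td50, hill=hill, converged=True, n_boot=boot.size,
                  td50_se=float(np.std(boot, ddof=1)),
                  ci_low=float(lo), ci_high=float(hi), boot_td50=boot)


def mtd_from_fit(fit: ToxFit, multiplier: float = 1.0
                 ) -> tuple[float, tuple[float, float]]:
    """Maximum tolerated dose from a converged fit: MTD = multiplier * TD50.

    Under the study's severe-toxicity endpoint the MTD is identified with
    the TD50 itself (multiplier 1).  Returns (mtd, (ci_low, ci_high));
    the interval is NaN when the fit carried no bootstrap.
    """
    if not fit.converged:
        raise ValueError("cannot derive an MTD from a non-converged fit")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return multiplier * fit.td50, (multiplier * fit.ci_low,
                                   multiplier * fit.ci_high)


def mtd_fold_change(fit_a: ToxFit, fit_b: ToxFit
                    ) -> tuple[float, tuple[float, float]]:
    """TD50 ratio a/b with a paired-bootstrap percentile interval.

    Antisymmetric under argument swap: f(a,b) * f(b,a) = 1.  The interval
    is NaN when either fit lacks bootstrap replicates.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must be converged")
    ratio = fit_a.td50 / fit_b.td50
    na, nb = fit_a.boot_td50.size, fit_b.boot_td50.size
    if na == 0 or nb == 0:
        return ratio, (float("nan"), float("nan"))
    m = min(na, nb)
    ratios = fit_a.boot_td50[:m] / fit_b.boot_td50[:m]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return ratio, (float(lo), float(hi))
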