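"""Inducible capsular-polysaccharide (CAP) state dynamics.

The iCAP gene circuit places the *kfiC* glycosyltransferase under a
lac promoter, so the surface CAP level is set by the IPTG concentration.
This module models the population-level CAP state ``C(t)`` as a fraction of
the fully induced level: a Hill dose-response sets the steady-state target
for a given IPTG concentration, and the state relaxes exponentially toward
that target with separate on/off rates.  Maps from CAP fraction to the
observable layer thickness (TEM) and to the clearance-protection multiplier
used by the pharmacokinetic model live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CapKinetics",
    "InductionSchedule",
    "CapTrajectory",
    "dose_response",
    "cap_trajectory",
    "cap_level_function",
    "thickness_from_cap",
    "protection_factor",
    "THICKNESS_BARE_NM",
    "THICKNESS_FULL_NM",
]

#: Mean outer-layer thickness of the uninduced / fully induced state (nm),
#: the two endpoints of the measured thickness shift.
THICKNESS_BARE_NM = 44.0
THICKNESS_FULL_NM = 81.0

#: Default relaxation rate (1/h).  Operationalizes "near-maximum by 6 h" on
#: induction and "complete repression by 6 h" on decay as 95% / 5% residual:
#: exp(-k*6) = 0.05  =>  k = ln(20)/6.
K_SIX_HOUR = math.log(20.0) / 6.0


@dataclass(frozen=True)
class CapKinetics:
    """Parameters of the inducible CAP circuit.

    ec50 : IPTG concentration at half-maximal steady-state CAP (uM).
    hill_n : Hill coefficient of the dose-response (dimensionless, > 0).
    k_on : relaxation rate toward a higher target during induction (1/h).
    k_off : relaxation rate toward a lower target after inducer removal (1/h).
    basal : leaky CAP fraction at zero inducer, in [0, 1).
    """

    ec50: float = 0.1
    hill_n: float = 2.0
    k_on: float = K_SIX_HOUR
    k_off: float = K_SIX_HOUR
    basal: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("relaxation rates must be positive")
        if not 0 <= self.basal < 1:
            raise ValueError("basal fraction must be in [0, 1)")


@dataclass(frozen=True)
class InductionSchedule:
    """Piecewise-constant IPTG concentration over contiguous time segments.

    ``bounds`` has length n+1 (h, strictly increasing, starting at the
    schedule origin); ``iptg`` has length n (uM, >= 0).
    """

    bounds: tuple[float, ...]
    iptg: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        c = np.asarray(self.iptg, dtype=float)
        if b.size != c.size + 1:
            raise ValueError("need len(bounds) == len(iptg) + 1")
        if c.size == 0:
            raise ValueError("schedule needs at least one segment")
        if np.any(np.diff(b) <= 0):
            raise ValueError("segment bounds must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("IPTG concentrations must be non-negative")

    @property
    def span(self) -> tuple[float, float]:
        return self.bounds[0], self.bounds[-1]

    def concentration_at(self, t: float) -> float:
        """IPTG concentration at time t (right-open segments, last closed)."""
        lo, hi = self.span
        if not lo <= t <= hi:
            raise ValueError(f"time {t} outside schedule span {self.span}")
        idx = int(np.searchsorted(self.bounds, t, side="right")) - 1
        idx = min(idx, len(self.iptg) - 1)
        return self.iptg[idx]

    @classmethod
    def constant(cls, iptg: float, horizon: float, start: float = 0.0
                 ) -> "InductionSchedule":
        return cls((start, horizon), (iptg,))

    @classmethod
    def step(cls, t_on: float, horizon: float, iptg: float,
             pre: float = 0.0, start: float = 0.0) -> "InductionSchedule":
        """Inducer off until ``t_on``, then constant ``iptg`` until horizon."""
        if not start < t_on < horizon:
            raise ValueError("need start < t_on < horizon")
        return cls((start, t_on, horizon), (pre, iptg))


@dataclass(frozen=True)
class CapTrajectory:
    """CAP fraction of maximum over time; c is bounded to [0, 1]."""

    times: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and c must have equal length")
        if np.any((c < -1e-12) | (c > 1 + 1e-12)):
            raise ValueError("CAP fraction must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "c", np.clip(c, 0.0, 1.0))


def dose_response(iptg: float | np.ndarray, kin: CapKinetics) -> float | np.ndarray:
    """Steady-state CAP fraction for a constant IPTG concentration.

    c_ss = basal + (1 - basal) * iptg^n / (ec50^n + iptg^n), monotone
    non-decreasing in iptg.  With the default calibration (ec50 = 0.1 uM,
    n = 2) the response saturates (>= 0.9) by ~1 uM IPTG.
    """
    x = np.asarray(iptg, dtype=float)
    if np.any(x < 0):
        raise ValueError("IPTG concentration must be non-negative")
    with np.errstate(divide="ignore"):
        frac = x ** kin.hill_n / (kin.ec50 ** kin.hill_n + x ** kin.hill_n)
    out = kin.basal + (1.0 - kin.basal) * frac
    return float(out) if np.isscalar(iptg) else out


def _segment_targets(schedule: InductionSchedule, kin: CapKinetics,
                     c0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment (start value, target, rate) from the piecewise closed form."""
    n = len(schedule.iptg)
    starts = np.empty(n)
    targets = np.empty(n)
    rates = np.empty(n)
    c = c0
    for i in range(n):
        tgt = float(dose_response(schedule.iptg[i], kin))
        k = kin.k_on if tgt > c else kin.k_off
        starts[i], targets[i], rates[i] = c, tgt, k
        dt = schedule.bounds[i + 1] - schedule.bounds[i]
        c = tgt + (c - tgt) * math.exp(-k * dt)
    return starts, targets, rates


def cap_level_function(schedule: InductionSchedule, kin: CapKinetics,
                       c0: float = 0.0):
    """Closed-form C(t) as a vectorized callable over the schedule span.

    Within each segment C relaxes exponentially toward the segment's
    steady-state target; the rate is k_on when approaching from below and
    k_off from above, and C is continuous across segment boundaries.
    """
    if not 0.0 <= c0 <= 1.0:
        raise ValueError("initial CAP fraction must be in [0, 1]")
    starts, targets, rates = _segment_targets(schedule, kin, c0)
    bounds = np.asarray(schedule.bounds, dtype=float)

    def c_of_t(t):
        tt = np.asarray(t, dtype=float)
        if np.any(tt < bounds[0] - 1e-9) or np.any(tt > bounds[-1] + 1e-9):
            raise ValueError("time outside schedule span")
        idx = np.clip(np.searchsorted(bounds, tt, side="right") - 1,
                      0, len(starts) - 1)
        dt = tt - bounds[idx]
        val = targets[idx] + (starts[idx] - targets[idx]) * np.exp(-rates[idx] * dt)
        return float(val) if np.isscalar(t) else val

    return c_of_t


def cap_trajectory(schedule: InductionSchedule, kin: CapKinetics,
                   c0: float, grid: Sequence[float]) -> CapTrajectory:
    """Evaluate the CAP state on a time grid inside the schedule span."""
    g = np.asarray(grid, dtype=float)
    lo, hi = schedule.span
    if g.size == 0 or g.min() < lo - 1e-9 or g.max() > hi + 1e-9:
        raise ValueError("grid must lie within the schedule span")
    fn = cap_level_function(schedule, kin, c0)
    return CapTrajectory(times=g, c=np.asarray(fn(g), dtype=float))


def thickness_from_cap(c: float | np.ndarray) -> float | np.ndarray:
    """Outer-layer thickness (nm) for a CAP fraction: linear 44 -> 81 nm."""
    x = np.asarray(c, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("CAP fraction must be in [0, 1]")
    out = THICKNESS_BARE_NM + x * (THICKNESS_FULL_NM - THICKNESS_BARE_NM)
    return float(out) if np.isscalar(c) else out


def protection_factor(c: float | np.ndarray, p_min: float) -> float | np.ndarray:
    """Immune-clearance multiplier psi(c) = p_min**c.

    Log-linear interpolation between no protection (1 at c = 0) and the
    maximal protection multiplier p_min at c = 1; strictly decreasing in c
    whenever p_min < 1.
    """
    if not 0 < p_min <= 1:
        raise ValueError("p_min must lie in (0, 1]")
    x = np.asarray(c, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("CAP fraction must be in [0, 1]")
    out = p_min ** x
    return float(out) if np.isscalar(c) else out
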