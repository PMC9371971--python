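"""Synthetic-data generators for every input the pipeline consumes.

The wet-lab study deposits no raw data, so each analysis stage is exercised
against generated inputs carrying the statistical structure the analysis
assumes: logistic plate-reader growth (with an optional phage-lysis event),
exponential killing in whole blood observed through serial-dilution plating
with a limit of detection, Bernoulli severe-toxicity outcomes from a
log-dose logistic, annular TEM micrographs with a known thickness field,
and biodistribution CFU-per-gram tables derived from a pharmacokinetic
trajectory.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "GrowthParams",
    "GrowthCurve",
    "CfuSeries",
    "ToxCohort",
    "TEMImage",
    "TEMGeometry",
    "DEFAULT_LOD",
    "generate_growth_curve",
    "generate_blood_killing",
    "generate_tox_cohort",
    "generate_tem_image",
    "generate_biodistribution",
]

#: Limit of detection of the blood plating assay (CFU/ml).
DEFAULT_LOD = 2.0e2


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters with an optional phage-lysis event.

    od0 : initial OD600 (> 0)
    mu_max : maximum specific growth rate (1/h, >= 0)
    carrying_capacity : plateau OD600 (> od0)
    lysis_delay : onset time of phage lysis (h) or None
    lysis_rate : post-onset exponential OD decay rate (1/h)
    noise_cv : coefficient of variation of multiplicative lognormal noise
    """

    od0: float
    mu_max: float
    carrying_capacity: float
    lysis_delay: float | None = None
    lysis_rate: float = 0.0
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.od0 <= 0:
            raise ValueError("od0 must be positive")
        if self.od0 >= self.carrying_capacity:
            raise ValueError("od0 must be below the carrying capacity")
        for name in ("mu_max", "lysis_rate", "noise_cv"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.lysis_delay is not None and self.lysis_delay < 0:
            raise ValueError("lysis_delay must be non-negative")


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 time series for one strain under one condition."""

    times: np.ndarray
    od600: np.ndarray
    strain_label: str = ""
    condition_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.shape != od.shape:
            raise ValueError("times and od600 must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("od600 must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od600", od)


def logistic_od(t: np.ndarray, od0: float, mu: float, k: float) -> np.ndarray:
    """Closed-form logistic OD(t) = K*od0*e^{mu t} / (K - od0 + od0 e^{mu t})."""
    t = np.asarray(t, dtype=float)
    e = np.exp(mu * t)
    return k * od0 * e / (k - od0 + od0 * e)


def generate_growth_curve(params: GrowthParams, times: Sequence[float],
                          seed: int, strain_label: str = "",
                          condition_label: str = "") -> GrowthCurve:
    """Logistic growth with optional lysis and multiplicative noise.

    The noiseless mean follows the logistic closed form; if a lysis onset is
    set, OD decays exponentially at ``lysis_rate`` from the value reached at
    onset.  Identical (params, times, seed) give identical output.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("times must be a non-empty strictly increasing grid")
    mean = logistic_od(t, params.od0, params.mu_max, params.carrying_capacity)
    if params.lysis_delay is not None:
        onset = params.lysis_delay
        od_onset = float(logistic_od(np.array([onset]), params.od0,
                                     params.mu_max, params.carrying_capacity)[0])
        post = t >= onset
        mean = np.where(post, od_onset * np.exp(-params.lysis_rate * (t - onset)),
                        mean)
    rng = np.random.default_rng(seed)
    od = mean * _lognormal_factors(rng, params.noise_cv, t.size)
    return GrowthCurve(times=t, od600=od, strain_label=strain_label,
                       condition_label=condition_label)


# ---------------------------------------------------------------------------
# blood-killing CFU series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CfuSeries:
    """Viable-count time series with limit-of-detection censoring.

    Censored points carry the LOD as their value with the flag set.
    """

    times: np.ndarray
    cfu_per_ml: np.ndarray
    lod: float
    censored: np.ndarray
    strain_label: str = ""
    condition_label: str = ""

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.cfu_per_ml, dtype=float)
        c = np.asarray(self.censored, dtype=bool)
        if not (t.shape == v.shape == c.shape):
            raise ValueError("times, cfu_per_ml and censored must align")
        if np.any(v < 0):
            raise ValueError("cfu_per_ml must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cfu_per_ml", v)
        object.__setattr__(self, "censored", c)


#: Plating protocol constants: volume plated (ml) and the colony-count band
#: the serial dilution targets.
_PLATE_VOLUME_ML = 0.1
_COUNT_BAND = (30.0, 300.0)


def _plate_once(rng: np.random.Generator, conc: float) -> float:
    """Simulate serial-dilution plating of a true concentration (CFU/ml).

    Picks the decade dilution whose expected colony count falls in the
    30-300 band (or the undiluted plate when even that is below 30), draws a
    Poisson colony count and scales back to CFU/ml.
    """
    expected_undiluted = conc * _PLATE_VOLUME_ML
    if expected_undiluted <= _COUNT_BAND[1]:
        dil = 0
    else:
        dil = int(math.ceil(math.log10(expected_undiluted / _COUNT_BAND[1])))
    colonies = rng.poisson(conc * _PLATE_VOLUME_ML / 10.0 ** dil)
    return colonies * 10.0 ** dil / _PLATE_VOLUME_ML


def generate_blood_killing(n0: float, k_kill: float, lod: float,
                           times: Sequence[float], seed: int,
                           noise: bool = True, strain_label: str = "",
                           condition_label: str = "") -> CfuSeries:
    """Exponential killing in whole blood observed through plating.

    Expected count n0*exp(-k_kill*t); observed counts are Poisson colony
    counts at an automatically chosen serial dilution scaled back to CFU/ml;
    estimates below the LOD are reported censored at the LOD.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    if k_kill < 0:
        raise ValueError("k_kill must be non-negative")
    if lod <= 0:
        raise ValueError("lod must be positive")
    expected = n0 * np.exp(-k_kill * t)
    rng = np.random.default_rng(seed)
    if noise:
        observed = np.array([_plate_once(rng, c) for c in expected])
    else:
        observed = expected.copy()
    censored = observed < lod
    observed = np.where(censored, lod, observed)
    return CfuSeries(times=t, cfu_per_ml=observed, lod=lod, censored=censored,
                     strain_label=strain_label, condition_label=condition_label)


# ---------------------------------------------------------------------------
# dose-toxicity cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToxCohort:
    """Per-mouse severe-toxicity outcomes grouped by administered dose."""

    doses: np.ndarray              # one dose per group (CFU)
    outcomes: tuple[np.ndarray, ...]  # per group, boolean per mouse

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if np.any(d <= 0):
            raise ValueError("doses must be positive")
        if len(self.outcomes) != d.size:
            raise ValueError("one outcome array per dose group required")
        object.__setattr__(self, "doses", d)
        object.__setattr__(
            self, "outcomes",
            tuple(np.asarray(o, dtype=bool) for o in self.outcomes))

    @property
    def n_per_dose(self) -> np.ndarray:
        return np.array([o.size for o in self.outcomes])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([o.mean() if o.size else np.nan for o in self.outcomes])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        mouse = 0
        for d, grp in zip(self.doses, self.outcomes):
            for o in grp:
                rows.append((f"m{mouse:04d}", d, bool(o)))
                mouse += 1
        return pd.DataFrame(rows, columns=["mouse_id", "dose_cfu", "severe_tox"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ToxCohort":
        doses = np.sort(df["dose_cfu"].unique())
        outcomes = tuple(
            df.loc[df["dose_cfu"] == d, "severe_tox"].to_numpy(dtype=bool)
            for d in doses)
        return cls(doses=doses, outcomes=outcomes)


def toxicity_probability(dose: float | np.ndarray, td50: float,
                         hill: float) -> float | np.ndarray:
    """Log-dose logistic p(dose) = 1 / (1 + (td50/dose)^hill)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose must be positive")
    out = 1.0 / (1.0 + (td50 / d) ** hill)
    return float(out) if np.isscalar(dose) else out


def generate_tox_cohort(doses: Sequence[float], td50: float, hill: float,
                        n_per_dose: int | Sequence[int], seed: int) -> ToxCohort:
    """Bernoulli severe-toxicity outcomes from a log-dose logistic."""
    d = np.asarray(doses, dtype=float)
    if td50 <= 0:
        raise ValueError("td50 must be positive")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    n = np.broadcast_to(np.asarray(n_per_dose, dtype=int), d.shape)
    if np.any(n < 1):
        raise ValueError("n_per_dose must be >= 1")
    rng = np.random.default_rng(seed)
    p = toxicity_probability(d, td50, hill)
    outcomes = tuple(rng.random(ni) < pi for ni, pi in zip(n, p))
    return ToxCohort(doses=d, outcomes=outcomes)


# ---------------------------------------------------------------------------
# TEM micrographs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TEMGeometry:
    """Rendering geometry for a synthetic micrograph.

    cell_radius_nm : distance from the centroid to the inner ring boundary.
    nm_per_px : physical pixel size.
    wobble : amplitude of a low-order radial perturbation of the cell
        outline (fraction of the radius); kept small so the shape stays
        star-shaped about the centroid and the ray-cast ground truth is
        unambiguous.
    n_sectors : number of angular sectors with independently drawn
        thickness; within a sector the thickness is constant.
    margin_nm : background margin around the outer boundary.
    """

    cell_radius_nm: float = 600.0
    nm_per_px: float = 4.0
    wobble: float = 0.0
    wobble_order: int = 2
    n_sectors: int = 90
    margin_nm: float = 60.0

    def __post_init__(self) -> None:
        if self.cell_radius_nm <= 0 or self.nm_per_px <= 0:
            raise ValueError("cell radius and nm_per_px must be positive")
        if not 0 <= self.wobble < 0.3:
            raise ValueError("wobble must be in [0, 0.3)")
        if self.n_sectors < 1:
            raise ValueError("n_sectors must be >= 1")


@dataclass(frozen=True)
class TEMImage:
    """Grayscale micrograph with physical scale and optional ground truth.

    ``truth`` (when present) holds the noiseless ring mask, the per-angle
    thickness field (360 samples, nm) and the per-angle inner radius (nm).
    """

    pixels: np.ndarray
    nm_per_px: float
    truth: dict | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        object.__setattr__(self, "pixels", px)


# rendered intensity levels (arbitrary units in [0, 1]); the ring is the
# dark phase, as in ruthenium-red-stained sections
_BG_LEVEL = 0.75
_RING_LEVEL = 0.25
RING_CONTRAST = _BG_LEVEL - _RING_LEVEL


def _sample_mixture(rng: np.random.Generator,
                    components: Sequence[tuple[float, float, float]],
                    n: int) -> np.ndarray:
    means = np.array([c[0] for c in components])
    sds = np.array([c[1] for c in components])
    weights = np.array([c[2] for c in components])
    idx = rng.choice(len(components), size=n, p=weights)
    return rng.normal(means[idx], sds[idx])


def generate_tem_image(thickness_spec: Sequence[tuple[float, float, float]],
                       geometry: TEMGeometry, noise_sd: float,
                       seed: int) -> TEMImage:
    """Render a noisy annular micrograph with a known thickness field.

    ``thickness_spec`` lists one or two Gaussian components as
    (mean_nm, sd_nm, weight); weights must sum to 1.  The ring is drawn as
    the dark phase around a convex cell body; its local thickness is
    constant within each angular sector and drawn from the mixture, so the
    per-angle ground-truth histogram follows the specified distribution.
    Additive Gaussian pixel noise with SD ``noise_sd`` (intensity units on a
    ring contrast of 0.5) is applied after a light optical blur.
    """
    comps = [(float(m), float(s), float(w)) for m, s, w in thickness_spec]
    if not comps or len(comps) > 2:
        raise ValueError("thickness_spec must list one or two components")
    if any(m <= 0 or s < 0 or w <= 0 for m, s, w in comps):
        raise ValueError("component means must be > 0, SDs >= 0, weights > 0")
    if abs(sum(w for *_, w in comps) - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    geo = geometry

    # per-sector thickness, then a dense 360-sample per-angle field
    sector_thick = _sample_mixture(rng, comps, geo.n_sectors)
    sector_thick = np.clip(sector_thick, 2.0 * geo.nm_per_px * 1.001, None)
    if np.any(sector_thick >= geo.cell_radius_nm):
        raise ValueError("ring thicker than the cell radius")
    if min(m for m, *_ in comps) < 2.0 * geo.nm_per_px:
        raise ValueError("nm_per_px too coarse: ring thinner than 2 px")

    angles = np.linspace(0.0, 2.0 * np.pi, 360, endpoint=False)
    sector_of = np.minimum((angles / (2 * np.pi) * geo.n_sectors).astype(int),
                           geo.n_sectors - 1)
    truth_thickness = sector_thick[sector_of]

    phase = rng.uniform(0, 2 * np.pi)
    r_in_of_angle = geo.cell_radius_nm * (
        1.0 + geo.wobble * np.cos(geo.wobble_order * angles + phase))

    max_extent = (r_in_of_angle + truth_thickness).max() + geo.margin_nm
    half_px = int(math.ceil(max_extent / geo.nm_per_px))
    size = 2 * half_px + 1
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = float(half_px)
    dx, dy = xx - cx, yy - cy
    r_nm = np.hypot(dx, dy) * geo.nm_per_px
    theta = np.mod(np.arctan2(-dy, dx), 2 * np.pi)  # ccw from +x, y up

    ang_idx = np.minimum((theta / (2 * np.pi) * 360).astype(int), 359)
    r_in_px_field = r_in_of_angle[ang_idx]
    r_out_px_field = r_in_px_field + truth_thickness[ang_idx]
    ring = (r_nm >= r_in_px_field) & (r_nm < r_out_px_field)

    image = np.full((size, size), _BG_LEVEL)
    image[ring] = _RING_LEVEL
    image = ndimage.gaussian_filter(image, sigma=0.8)  # light optical blur
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)

    truth = {
        "ring_mask": ring,
        "angles": angles,
        "thickness_nm": truth_thickness,
        "inner_radius_nm": r_in_of_angle,
        "centroid_px": (cy, cx),
    }
    return TEMImage(pixels=image, nm_per_px=geo.nm_per_px, truth=truth)


# ---------------------------------------------------------------------------
# biodistribution tables
# ---------------------------------------------------------------------------

def generate_biodistribution(pk, organ_masses: dict[str, float],
                             sampling_cv: float, seed: int,
                             at_h: float | None = None) -> pd.DataFrame:
    """Per-organ CFU/g table from a pharmacokinetic trajectory.

    ``organ_masses`` maps compartment names (``blood``, ``peripheral``,
    ``tumor_0`` ...) to organ masses in grams.  CFU/g is the compartment CFU
    divided by the organ mass, perturbed by mean-one lognormal noise with
    the stated coefficient of variation (homogenate plating variability).
    """
    if any(m <= 0 for m in organ_masses.values()):
        raise ValueError("organ masses must be positive")
    t = pk.times[-1] if at_h is None else at_h
    state = pk.at(t)
    rng = np.random.default_rng(seed)
    rows = []
    for organ, mass in organ_masses.items():
        if organ not in state:
            raise KeyError(f"trajectory has no compartment named {organ!r}")
        cfu = state[organ]
        if cfu < 0:
            raise ValueError(f"negative compartment value for {organ!r}")
        noisy = cfu / mass * _lognormal_factors(rng, sampling_cv, 1)[0]
        rows.append((organ, mass, noisy, t))
    return pd.DataFrame(rows, columns=["organ", "mass_g", "cfu_per_g", "time_h"])
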