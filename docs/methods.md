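# Methods

`capkit` re-implements, at desk scale and against synthetic data, the
quantitative procedures surrounding a programmable capsular-polysaccharide
(CAP) encapsulation system in the probiotic *E. coli* Nissle 1917 (EcN):
a knockdown-screen metric set, the inducible-circuit (iCAP) kinetics, a
compartmental bacterial pharmacokinetics (PK) model, dose–toxicity
TD₅₀/MTD estimation, and a TEM ring-thickness measurement pipeline.  The
animal experiments behind the headline in-vivo numbers are not
reproducible from printed data, so every analysis here is validated by
recovery and property studies on generated inputs whose structure matches
the assays.

## Synthetic-data generators

All generators are pure functions of `(parameters, seed)`.

**Growth curves.** Plate-reader OD₆₀₀ follows the logistic closed form
`OD(t) = K·od₀·e^{µt} / (K − od₀ + od₀·e^{µt})` with optional phage lysis:
after a sharp onset time the OD decays exponentially.  The logistic form
was chosen because the assayed curves plateau and because it gives an
exact oracle for the growth-rate estimator.  Measurement noise is
multiplicative mean-one lognormal; the default CV of 5% is a plausible
plate-reader figure (no measured value is available) and is configurable.

**Blood killing.** Viable counts decay as `n₀·e^{−k·t}` and are observed
through simulated serial-dilution plating: a decade dilution is chosen to
target 30–300 colonies, the colony count is Poisson, and the scaled-back
estimate is censored at the limit of detection (LOD, default 2×10²
CFU ml⁻¹).  Values at the LOD count as observed; values below are
reported at the LOD with a censoring flag.

**Toxicity cohorts.** Per-mouse severe-toxicity outcomes (endpoint:
>10% body-weight loss or death) are Bernoulli draws from the log-dose
logistic `p(d) = 1/(1 + (TD₅₀/d)^h)`.

**TEM micrographs.** A cell is rendered as a circle (optional low-order
radial wobble keeps it star-shaped, so the ray-cast ground truth is
unambiguous) surrounded by a dark ring.  The ring thickness is constant
within each of 90 angular sectors and drawn per sector from a one- or
two-component Gaussian mixture, so the per-angle ground-truth histogram
follows the specified distribution; defaults are cell radius 600 nm,
4 nm px⁻¹, light optical blur (σ 0.8 px) and additive Gaussian noise on a
ring contrast of 0.5.  Sectors must stay wider than the blur kernel or
angular averaging would wash out genuine bimodality; 90 sectors (≈10 px
arcs at the default geometry) balance that against per-image effective
sample size.  The generator stores the ring mask and per-angle thickness
as ground truth.  Real micrographs differ in ways the generator does not
emulate — irregular cell outlines, staining gradients, touching cells —
so passing tests demonstrate correctness of the measurement chain, not
robustness to every TEM artifact.

## Inducible CAP state

The population-level CAP fraction `C(t) ∈ [0, 1]` obeys, per constant-
inducer segment, exponential relaxation toward the Hill steady state
`c_ss = basal + (1 − basal)·I^n / (EC₅₀^n + I^n)` with rate `k_on` when
approaching from below and `k_off` from above.  Defaults: EC₅₀ = 0.1 µM
and n = 2, which saturate the response (≥ 0.9) by ~1 µM IPTG; `k_on =
k_off = ln(20)/6 ≈ 0.499 h⁻¹`, which operationalizes "near-maximum by
6 h" and "complete repression by 6 h" as 95% / 5% thresholds — the
densitometric time courses give timescales, not rates, and symmetry of
on/off rates is an assumption.  Basal leakiness defaults to 0 (the
uninduced circuit is phage-immune).  Two maps connect the state to
observables: thickness `44 + 37·C` nm (linear between the measured
uninduced and fully induced means) and the protection multiplier
`ψ(C) = p_min^C`, a log-linear interpolation between no protection and
the full-capsule multiplier, applied to immune-killing rates.

## Pharmacokinetic model

Compartments: blood `B`, peripheral organs of the mononuclear phagocyte
system `P` (liver/spleen pooled), and tumors `T_i`:

    dB/dt  = −[k_clear·ψ(C) + k_mps + n·k_entry]·B + k_escape·Σ T_i
    dP/dt  = k_mps·B − delta_p·ψ(C)·P
    dT_i/dt = k_entry·B + r_t·T_i·(1 − T_i/K) − k_escape·T_i

CAP modes: `none` (C ≡ 0), `static` (C ≡ 1), `transient` (pre-induced,
C decays from 1), `in_situ` (schedule-driven, e.g. inducer water from
24 h).  The i.v. route places the dose in blood, i.t. in the treated
tumor.  Integration uses LSODA with rtol 1e-8 / atol 1e-6 CFU; tiny
negative excursions (below 1e-12 of the dose) are clipped with a warning.

Design choices that were genuinely open:

- **ψ(C) multiplies both `k_clear` and `delta_p`.**  Protection is
  protection from host immune killing wherever it happens.  This is also
  what makes the transient strategy meaningful in the model: tumor
  seeding and peripheral influx both scale with ∫B dt, so if organisms
  were eliminated from organs at a CAP-independent rate, a transient
  capsule could never improve the late tumor-to-(blood+peripheral)
  specificity ratio over no capsule — the benefit in circulation would be
  mirrored one-for-one in the peripheral compartment.  With CAP-dependent
  organ killing, a static capsule leaves a persistent peripheral
  reservoir while the transient capsule is cleared everywhere after
  decay, which is precisely the claimed safety mechanism.
- **Escape is first-order and CAP-independent**, and the default i.v.
  calibration sets `k_escape = 0`: with appreciable escape, late blood
  and peripheral levels settle into a quasi-steady state proportional to
  tumor burden, and the specificity ratio then forgets the delivery
  history.  Escape matters — and is switched on — in the intratumoral
  translocation analyses.
- **Default rates** (versioned in `src/capkit/data/defaults.yaml`) come
  from closed-form decay arithmetic against in-vivo landmarks: an
  unencapsulated strain falls below the blood LOD (≈400 CFU total at
  200 CFU ml⁻¹ in ~2 ml mouse blood) within 0.5 h of a 5×10⁶ CFU dose
  (`k_clear = 20 h⁻¹`), while a fully encapsulated strain stays
  detectable through ~4 h (`p_min = 0.1`, `k_mps = 0.25 h⁻¹`,
  `k_entry = 0.03 h⁻¹`); `delta_p = 0.3 h⁻¹`, `r_t = 0.1 h⁻¹`,
  `K = 10⁹` CFU.
- `C(t)` is a population-level scalar; per-cell CAP heterogeneity (the
  bimodal TEM observation) is out of scope for the PK model.

The translocation property — in-situ induction strictly increases the
distal/treated fraction at 72 h whenever `p_min < 1`, `k_entry > 0`,
`k_escape > 0` — follows from a comparison argument: induction lowers the
blood clearance rate pointwise while the escaping flux from the treated
tumor is unchanged, so `B(t)` is pointwise (weakly, then strictly after
induction starts) larger, and the distal tumor integrates `k_entry·B`.
It is checked over random parameter draws.

## Screen metrics

Growth rate is the `µ` of a logistic nonlinear least-squares fit
(multi-start over rate guesses; honest convergence flag; a sliding-window
log-linear slope is available as `method="loglinear"`).  Curves with no
net growth return µ = 0 with a diagnostic instead of a spurious fit.
Phage sensitivity is the trapezoidal AUC of raw turbidity over 6 h (raw,
not log/baseline-subtracted, since the statistic is "area under the
turbidity curve"); lower AUC means more lysis, hence more residual
capsule.  Blood viability is the CFU ml⁻¹ at the 6-h sample (nearest
sample within 0.5 h; plate counts are not interpolated), censored-aware.
The screen table min–max normalizes each metric to [0, 1] with censored
viabilities pinned to 0; a degenerate (single-strain) range maps to 1.
The normalization is a presentation choice, not a measured quantity.

## Dose–toxicity

Group toxicity fractions are fitted by least squares to the log-dose
logistic (multi-start over a log-spaced TD₅₀ grid × slope grid, analytic
Jacobian).  Least squares on fractions, rather than per-mouse binomial
likelihood, matches the stated regression method; identifiability
requires ≥3 dose groups with a non-degenerate response, and all-toxic or
all-safe cohorts raise.  Uncertainty comes from resampling mice within
dose groups (percentile intervals; bootstrap refits start from the point
estimate).  MTD is reported as the TD₅₀ of the severe-toxicity endpoint
(a configurable multiplier is exposed; identity is the default).  Fold
changes between strains use paired bootstrap replicates.  Recovery
studies use six log-spaced doses spanning the 1–7×10⁷ CFU escalation
range with 10 mice per dose; an uninformative dose grid (no doses on the
steep part of the curve) inflates TD₅₀ bias well beyond 15% regardless of
the fitting method.

## TEM thickness pipeline

Gaussian blur (default σ 2 px) → global threshold → keep the largest
dark connected component with ring topology (exactly one hole).  The
default threshold seeds a two-phase split with Otsu and then cuts at the
midpoint of the class medians, i.e. at half the ring contrast: a raw Otsu
cut on a blurred, background-dominated image sits inside the edge ramp
and systematically dilates the ring by ~0.15 px per boundary (Jaccard
0.985 versus 1.0 on a noiseless annulus).  Otsu and mean thresholds
remain available.

Thickness is measured along 360 rays from the mask centroid on a
bilinearly interpolated mask profile at 0.25 px steps (integer sampling
quantizes thickness to 2 nm at the default scale); rays with no or
multiple disjoint crossings are dropped and counted.  Ray casting
overestimates thickness where the ray is oblique to the layer (elongated
cells); the `normal` method instead reports the Euclidean distance from
the inner crossing through the ring to the exterior (via distance
transform) and recovers a constant-width band on ellipses within 2%.

Per-cell samples are pooled (five cells per condition by default) into
histograms; 1- and 2-component Gaussian mixtures are fitted by EM
(multi-start, seeded) and selected by BIC, with one safeguard: a
BIC-preferred 2-component fit must itself be bimodal (two local maxima of
the fitted density).  Neighbouring rays are correlated — the effective
sample size is the number of independent thickness patches, not the ray
count — which inflates BIC's apparent evidence for a split on unimodal
data, and a mixture whose density has one mode describes a unimodal
layer.  Degenerate samples return a point mass.

## Assay formulas

Exact evaluations of the printed formulas: phagocytic index
`(engulfed/counted)·(containing/counted)·100`; tumor volume `L·W·H·0.5`
(subcutaneous) or `L·W²·0.5` (mammary tumors with unreliable z); relative
growth `v(t)/v(t₀)` with a percent option; LOD censoring with the
at-the-floor-counts-as-observed convention.  The antisense sRNA designer
returns the reverse complement of the 24-nt window ending at the start
codon's third base (covering 21 nt of upstream ribosome-binding-site
region); the window anchor is a parameter since the printed rule does not
fix whether bases beyond the start codon are included.  Coordinates are
0-based; non-ATG/GTG start codons warn rather than fail.

## Pipeline and reproducibility

A single config seed feeds a counter-based derivation scheme (one
`SeedSequence` spawn key per stage), so adding a stage does not perturb
earlier streams.  Delimited outputs are comma-separated UTF-8 with LF
newlines and fixed column order; two runs of the same config produce
byte-identical tables, verified by SHA-256 in the run manifest.  Configs
are strict: unknown keys and a missing seed are schema errors.

## Problem sizes

The recovery studies use 100 replicate growth curves (CV 5%), 200
simulated toxicity cohorts (6 doses × 10 mice) with 100–200 bootstrap
resamples, 100 random-parameter translocation draws, and 100 synthetic
micrographs for component selection — sizes at which the Monte-Carlo
error of each summary is comfortably below the property margins being
checked.

## Known limitations

- The PK structure is a reconstruction from stated compartments and
  claims; the original model's equations are not public, and alternative
  structures (more organs, CAP-dependent escape) are deliberately kept
  drop-in behind `PKParams`.
- Noise magnitudes for OD and plating are placeholders (no measured
  values exist); they are config-exposed.
- The thickness pipeline assumes one cell per image and a star-shaped
  ring about the centroid; touching cells and strongly concave outlines
  are out of scope.
- The screen normalization and the protection-factor functional form are
  modeling conveniences; only their monotonicity is load-bearing.
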