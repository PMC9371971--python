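# capkit

Quantitative analyses for a programmable bacterial capsular-polysaccharide
(CAP) encapsulation system in the probiotic *E. coli* Nissle 1917.

Engineered bacteria are promising cancer therapeutics, but systemic dosing
is caught between rapid immune clearance (forcing higher doses) and
toxicity from the doses that survive.  An inducible capsule (iCAP: the
*kfiC* glycosyltransferase under a lac promoter, driven by IPTG) lets the
bacterial surface be shielded *transiently*: encapsulated during delivery,
then cleared once the inducer is withdrawn and the capsule decays.  This
package implements the full quantitative tool-chain around that system,
for computational biologists who want to reproduce, probe or extend its
analyses:

- **synthetic data generators** for every assay input (logistic growth
  with phage lysis, exponential blood killing observed through Poisson
  plating with LOD censoring, Bernoulli dose–toxicity cohorts, annular
  TEM micrographs with ground truth, biodistribution tables);
- **screen metrics** — maximum specific growth rate µₘ from a logistic
  fit, blood viability at 6 h (censoring-aware), phage-sensitivity AUC;
- **iCAP state dynamics** — Hill dose–response
  c_ss = basal + (1−basal)·I^n/(EC₅₀^n + I^n), exponential on/off
  kinetics, thickness map 44 + 37·C nm, protection factor ψ(C) = p_min^C;
- **bacterial pharmacokinetics** — blood / peripheral (liver+spleen) /
  tumor compartments with CAP-modulated immune killing, logistic
  intratumoral growth, tumor specificity and inter-tumor translocation;
- **dose–toxicity** — least-squares log-dose logistic
  p(d) = 1/(1+(TD₅₀/d)^h), bootstrap intervals, MTD = TD₅₀ of the
  severe-toxicity endpoint, fold changes;
- **TEM thickness pipeline** — blur → threshold → ring segmentation →
  radial thickness about the centroid → pooled histograms → 1-vs-2
  component Gaussian fits with BIC + bimodality safeguard;
- **assay formulas** — phagocytic index, tumor volumes (L·W·H·0.5 and
  L·W²·0.5), relative growth, LOD censoring, 24-nt antisense sRNA design.

The scientific background and every modeling decision are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Run the numbered analyses in order (each is a thin driver over the
library and writes under `results/`):

```sh
python analysis/01_generate_inputs.py --seed 0
python analysis/04_pk_simulation.py   --seed 0
python analysis/05_dose_toxicity.py   --seed 0
python analysis/06_tem_thickness.py   --seed 0
```

The PK comparison prints:

```
tumor specificity at 72 h (tumor CFU / (blood + peripheral)):
  none      1.95e+07
  static    2.43e+03
  transient 1.21e+08
  transient / none   = 6.21
  transient / static = 4.97e+04

translocation fraction (distal/treated) at 72 h: 0.0037 uninduced vs
0.0183 with IPTG water from 24 h (4.9-fold increase)
```

i.e. a transiently encapsulated dose ends up with ~6× the tumor
specificity of a bare strain and ~5×10⁴ that of a permanently
encapsulated one (whose protected peripheral reservoir persists), and
switching the capsule on *in situ* after intratumoral injection raises
the distal-tumor translocation fraction ~5-fold.

The dose–toxicity fits on cohorts generated at the three strains' TD₅₀
values print:

```
EcN_iCAP   TD50 = 4.5e+07 CFU (hill 3.9); MTD = 4.5e+07 [3.23e+07, 7.38e+07]
EcN        TD50 = 5.1e+06 CFU (hill 19.6); MTD = 5.1e+06 [4.79e+06, 5.58e+06]
EcN_dkfiC  TD50 = 8.84e+06 CFU (hill 2.6); MTD = 8.84e+06 [5.36e+06, 1.32e+07]

MTD fold change, transient capsule over wild type: 8.82 [6.06, 14.76]
```

— the transient-capsule strain tolerates roughly an order of magnitude
more bacteria.  The TEM stage recovers the thickness shift and the
intermediate-induction bimodality:

```
iptg_0       5 cells, 1 component(s): 46.0 nm (sd 4.6, w 1.00)
iptg_0p1uM   5 cells, 2 component(s): 46.9 nm (sd 5.6, w 0.48), 80.9 nm (sd 5.5, w 0.52)
iptg_1uM     5 cells, 1 component(s): 81.3 nm (sd 4.8, w 1.00)
```

A `capkit` command-line interface wraps the same stages
(`capkit generate | screen | simulate | fit-tox | measure-tem | run`);
`capkit run --seed 0 --out results/run` executes the whole pipeline and
writes a SHA-256 manifest — two runs of one config are byte-identical.

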