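#!/usr/bin/env python
"""Pharmacokinetic mode comparison and inducible translocation.

Simulates an i.v. dose of 5e6 CFU under three encapsulation modes (none,
static, transient) and an i.t. dose with and without in-situ induction
from 24 h.  Finding: transient encapsulation protects bacteria through
the delivery window but clears them from blood and peripheral organs
once the capsule decays, maximizing 72-h tumor specificity; in-situ
induction raises the distal/treated translocation fraction severalfold.
"""

import argparse
import json

from capkit.pipeline import default_config, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    cfg = default_config(args.seed)
    cfg["stages"] = ["simulate"]
    run_pipeline(cfg, args.out)
    summary = json.loads(open(f"{args.out}/pk_summary.json").read())

    spec = summary["tumor_specificity_72h"]
    print("tumor specificity at 72 h (tumor CFU / (blood + peripheral)):")
    for mode in ("none", "static", "transient"):
        print(f"  {mode:9s} {spec[mode]:.3g}")
    print(f"  transient / none   = {spec['transient'] / spec['none']:.2f}")
    print(f"  transient / static = {spec['transient'] / spec['static']:.3g}")

    frac = summary["translocation_fraction_72h"]
    f0 = frac["no_induction"]["1"]
    f1 = frac["in_situ"]["1"]
    print(f"\ntranslocation fraction (distal/treated) at 72 h: "
          f"{f0:.4f} uninduced vs {f1:.4f} with IPTG water from 24 h "
          f"({f1 / f0:.1f}-fold increase)")


if __name__ == "__main__":
    main()
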