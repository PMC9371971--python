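#!/usr/bin/env python
"""Dose-toxicity fits and TD50-based maximum tolerated dose per strain.

Fits the log-dose logistic to each generated cohort (transient-capsule
strain, wild type, capsule knockout) with bootstrap uncertainty and
reports the MTD fold change of the transient strain over the wild type.
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
    cfg["stages"] = ["fit_tox"]
    run_pipeline(cfg, args.out)
    fits = json.loads(open(f"{args.out}/tox_fits.json").read())

    for strain in ("EcN_iCAP", "EcN", "EcN_dkfiC"):
        f = fits[strain]
        lo, hi = f["mtd_ci"]
        print(f"{strain:10s} TD50 = {f['td50_cfu']:.3g} CFU "
              f"(hill {f['hill']:.1f}); MTD = {f['mtd_cfu']:.3g} "
              f"[{lo:.3g}, {hi:.3g}]")
    fc = fits.get("mtd_fold_change_iCAP_over_EcN")
    if fc:
        print(f"\nMTD fold change, transient capsule over wild type: "
              f"{fc['ratio']:.2f} [{fc['ci'][0]:.2f}, {fc['ci'][1]:.2f}]")


if __name__ == "__main__":
    main()
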