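#!/usr/bin/env python
"""Knockdown-screen metrics: growth rate, blood viability, phage AUC.

Reads the generated panel (wild type, five knockdowns, the kfiC knockout)
and assembles the normalized screen table.  Expected pattern: growth in
rich media is nearly flat across strains, while capsule-synthesis
knockdowns lose blood viability; the knockout strain is phage-immune
(high AUC) yet most blood-sensitive.
"""

import argparse

import pandas as pd

from capkit.pipeline import default_config, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()

    cfg = default_config(args.seed)
    cfg["stages"] = ["screen"]
    run_pipeline(cfg, args.out)
    table = pd.read_csv(f"{args.out}/screen_table.csv")
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:.3g}"))
    spread = table["growth_rate"].max() - table["growth_rate"].min()
    print(f"\ngrowth-rate spread across strains: {spread:.3f} 1/h "
          "(fitness barely affected by knockdown)")
    worst = table.loc[table["viability_score"].idxmin(), "strain"]
    print(f"lowest blood viability: {worst}")


if __name__ == "__main__":
    main()
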