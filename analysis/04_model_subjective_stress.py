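#!/usr/bin/env python
"""Model subjective stress ratings.

Fits the four competing regression models of z-scored stress ratings
(surprise, irreducible, estimation and volatility uncertainty — all with
previous-rating and shock-count terms), compares them by BIC + random-
effects BMS, and runs group-level one-sample t-tests on the winning model's
coefficients. Writes results/analysis/stress_fits.csv and stress_bms.json.
"""

import argparse
import json

import pandas as pd

from uncstress.pipeline import PipelineConfig, run_pipeline
from uncstress.stress import group_coefficient_test


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=45)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    run_pipeline(PipelineConfig(
        n_subjects=args.subjects, master_seed=args.seed, outdir=args.out,
        stages=("simulate", "stress"), include_physio=False,
    ))
    bms = json.loads(open(f"{args.out}/stress_bms.json").read())
    for m, f, phi in zip(bms["models"], bms["frequencies"], bms["exceedance"]):
        print(f"{m:>12s}: frequency {f:.2f}, exceedance {phi:.3f}")
    winner = bms["models"][bms["exceedance"].index(max(bms["exceedance"]))]
    print(f"\nselected stress model: {winner}")

    fits = pd.read_csv(f"{args.out}/stress_fits.csv")
    win = fits[fits.model == winner]
    print("\ngroup-level coefficient tests (winning model):")
    for col in ("beta_lag", "beta_shocks", f"beta_{winner}"):
        t, p, mean = group_coefficient_test(win[col].to_numpy())
        print(f"  {col:>18s}: mean {mean:+.3f}, t({len(win) - 1})={t:.2f}, p={p:.4f}")


if __name__ == "__main__":
    main()
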