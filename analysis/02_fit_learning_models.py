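#!/usr/bin/env python
"""Fit the three learning models to every subject's choices.

Rescorla-Wagner (fixed learning rate), Sutton K1 (error-driven learning
rate) and the 3-level Hierarchical Gaussian Filter are MAP-fit to each
subject's trial-by-trial shock predictions; approximate log model evidence
comes from a Laplace approximation. Writes results/analysis/fits.csv.
"""

import argparse

import pandas as pd

from uncstress.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=45)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    run_pipeline(PipelineConfig(
        n_subjects=args.subjects, master_seed=args.seed, outdir=args.out,
        stages=("simulate", "fit-learning"), include_physio=False,
    ))
    fits = pd.read_csv(f"{args.out}/fits.csv")
    print(fits.groupby("model")["log_evidence"].describe().round(1))
    wide = fits.pivot(index="subject", columns="model", values="log_evidence")
    best = wide.idxmax(axis=1).value_counts()
    print(f"\nper-subject best model counts:\n{best}")


if __name__ == "__main__":
    main()
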