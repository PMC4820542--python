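#!/usr/bin/env python
"""Random-effects Bayesian model selection over the learning models.

Takes the per-subject log evidences from the learning-model fits and
estimates population model frequencies and exceedance probabilities.
Writes results/analysis/bms.json.
"""

import argparse
import json

from uncstress.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=45)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    run_pipeline(PipelineConfig(
        n_subjects=args.subjects, master_seed=args.seed, outdir=args.out,
        stages=("simulate", "fit-learning", "bms"), include_physio=False,
    ))
    bms = json.loads(open(f"{args.out}/bms.json").read())
    for m, f, phi in zip(bms["models"], bms["frequencies"], bms["exceedance"]):
        print(f"{m:>10s}: frequency {f:.2f}, exceedance {phi:.3f}")
    winner = bms["models"][bms["exceedance"].index(max(bms["exceedance"]))]
    print(f"\nselected model: {winner}")


if __name__ == "__main__":
    main()
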