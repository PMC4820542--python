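#!/usr/bin/env python
"""Simulate the synthetic cohort.

Generates 45 subjects performing the 320-trial aversive learning task: HGF
agents making shock predictions, stress ratings every 4-6 trials, pupil and
skin-conductance traces, an 8-sample cortisol panel for a 20-subject subset,
and PSS questionnaire scores. Writes per-subject CSVs and a manifest under
results/analysis/cohort/.
"""

import argparse

import numpy as np

from uncstress.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=45)
    ap.add_argument("--out", default="results/analysis")
    ap.add_argument("--no-physio", action="store_true",
                    help="skip the (slow) physiological traces")
    args = ap.parse_args()

    report = run_pipeline(PipelineConfig(
        n_subjects=args.subjects, master_seed=args.seed, outdir=args.out,
        stages=("simulate",), include_physio=not args.no_physio,
    ))
    print(f"wrote {args.subjects}-subject cohort to {args.out}/cohort "
          f"in {report['runtime_s']} s")


if __name__ == "__main__":
    main()
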