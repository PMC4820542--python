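#!/usr/bin/env python
"""Analyse pupil diameter and skin conductance.

Preprocesses each subject's traces, fits the convolution GLM with robust
regression, epochs outcome-locked responses with 2x2 median splits
(irreducible uncertainty x surprise) followed by repeated-measures ANOVA,
and measures the inverted-U tuning of baseline arousal with belief.
Writes results/analysis/physio_fits.csv and physio_anova.json.
"""

import argparse
import json

import numpy as np
import pandas as pd

from uncstress.cohort import simulate_cohort
from uncstress.groupstats import twoway_rm_anova
from uncstress.physio import (
    build_physio_design,
    baseline_tuning,
    epoch_median_split,
    preprocess_pupil,
    preprocess_scr,
    robust_fit,
)
from uncstress.task import TaskConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=22,
                    help="physiology subset size (pupil was recorded in 22)")
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    cohort = simulate_cohort(TaskConfig(), master_seed=args.seed,
                             n_subjects=args.subjects, include_physio=True)
    rows, cells = [], {"pupil": [], "scr": []}
    for sub in cohort.subjects:
        for modality, series, prep in (
            ("pupil", sub.pupil, preprocess_pupil),
            ("scr", sub.scr, lambda s: preprocess_scr(s, sub.schedule)),
        ):
            clean = prep(series)
            design = build_physio_design(sub.schedule, sub.trajectory, modality,
                                         n_samples=len(clean.values))
            fit = robust_fit(design, clean.values, mask=clean.mask)
            tuning = baseline_tuning(clean, sub.schedule, sub.trajectory)
            es = epoch_median_split(clean, sub.schedule, sub.trajectory)
            cells[modality].append([
                np.nanmean(es.condition_means[(u, s)])
                for u in (False, True) for s in (False, True)
            ])
            rows.append({
                "subject": sub.subject, "modality": modality,
                "uncertainty_beta": fit.beta[design.columns.index("uncertainty")],
                "surprise_beta": fit.beta[design.columns.index("surprise")],
                "tuning_r": tuning.r,
            })
    fits = pd.DataFrame(rows)
    fits.to_csv(f"{args.out}/physio_fits.csv", index=False)

    anova_out = {}
    for modality in ("pupil", "scr"):
        res = twoway_rm_anova(np.asarray(cells[modality]))
        anova_out[modality] = {
            "uncertainty": {"F": res.factor_a.F, "p": res.factor_a.p,
                            "eta2p": res.factor_a.eta_sq_partial},
            "surprise": {"F": res.factor_b.F, "p": res.factor_b.p,
                         "eta2p": res.factor_b.eta_sq_partial},
            "interaction": {"F": res.interaction.F, "p": res.interaction.p},
        }
        m = fits[fits.modality == modality]
        print(f"{modality}: mean uncertainty beta {m.uncertainty_beta.mean():+.3f}, "
              f"mean baseline tuning r {m.tuning_r.mean():.2f}, "
              f"ANOVA uncertainty F={res.factor_a.F:.2f} (p={res.factor_a.p:.4f}), "
              f"surprise F={res.factor_b.F:.2f} (p={res.factor_b.p:.4f})")
    with open(f"{args.out}/physio_anova.json", "w") as fh:
        json.dump(anova_out, fh, indent=2)


if __name__ == "__main__":
    main()
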