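"""Cohort file layouts and validation.

Per-subject directories ``sub-XX/`` hold ``trials.csv`` (trial, block,
stimulus, contingency, outcome, choice, RT, onset times, rating flag),
``ratings.csv`` (rating_index, trial_index, value) and optional
``pupil.csv`` / ``scr.csv`` (time_s, value, artifact_flag). Cohort-level
files: ``cortisol.csv`` (subject, sample_1..8), ``subjects.csv``
(ground-truth parameters incl. PSS) and ``manifest.json`` (config + seeds).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from uncstress.cohort import Cohort, SimulatedSubject


def _subject_dir(root: Path, subject: int) -> Path:
    return root / f"sub-{subject:02d}"


def write_subject(sub: SimulatedSubject, root: Path) -> None:
    d = _subject_dir(root, sub.subject)
    d.mkdir(parents=True, exist_ok=True)
    trials = sub.schedule.to_frame()
    trials["choice"] = sub.choices
    trials["rt_ms"] = sub.response_times_ms
    trials.to_csv(d / "trials.csv", index=False)

    prompts = sub.schedule.rating_trials
    pd.DataFrame(
        {
            "rating_index": np.arange(1, len(sub.ratings) + 1),
            "trial_index": prompts,
            "value": sub.ratings,
        }
    ).to_csv(d / "ratings.csv", index=False)

    for name, series in (("pupil", sub.pupil), ("scr", sub.scr)):
        if series is None:
            continue
        flag = series.mask.astype(int) if len(series.mask) else np.zeros(len(series.values), int)
        if name == "pupil":
            for t0, t1 in series.blink_intervals_s:
                i0, i1 = int(t0 * series.rate_hz), int(t1 * series.rate_hz) + 1
                flag[i0: min(i1, len(flag))] = 1
        pd.DataFrame(
            {"time_s": series.times_s, "value": series.values, "artifact_flag": flag}
        ).to_csv(d / f"{name}.csv", index=False)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    for sub in cohort.subjects:
        write_subject(sub, root)

    cort = pd.DataFrame(
        cohort.cortisol.values, columns=[f"sample_{i}" for i in range(1, 9)]
    )
    cort.insert(0, "subject", np.arange(len(cort)))
    cort.to_csv(root / "cortisol.csv", index=False)

    rows = []
    for s in cohort.subjects:
        gt = s.ground_truth
        rows.append(
            {
                "subject": s.subject,
                "omega": gt.hgf.omega,
                "theta": gt.hgf.theta,
                "zeta": gt.resp.zeta,
                "rating_lag": gt.rating_coeffs["lag"],
                "rating_shocks": gt.rating_coeffs["shocks"],
                "rating_uncertainty": gt.rating_coeffs["irreducible"],
                "pupil_uncertainty": gt.pupil_coeffs["uncertainty"],
                "scr_uncertainty": gt.scr_coeffs["uncertainty"],
                "pss": gt.pss,
            }
        )
    pd.DataFrame(rows).to_csv(root / "subjects.csv", index=False)

    manifest = {
        "n_subjects": len(cohort.subjects),
        "master_seed": cohort.master_seed,
        "task_config": {
            k: v for k, v in dataclasses.asdict(cohort.config).items()
            if not isinstance(v, tuple) or k == "probability_classes"
        },
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return root


def validate_inputs(path: str | Path) -> dict:
    """Schema and invariant checks on a cohort directory.

    Returns ``{"ok": bool, "problems": [str, ...], "n_subjects": int}`` with
    line-level diagnostics for each violated invariant.
    """
    root = Path(path)
    problems: list[str] = []
    sub_dirs = sorted(root.glob("sub-*"))
    if not sub_dirs:
        problems.append("no sub-XX directories found")

    for d in sub_dirs:
        tpath = d / "trials.csv"
        if not tpath.exists():
            problems.append(f"{d.name}: missing trials.csv")
            continue
        try:
            trials = pd.read_csv(tpath)
        except Exception as e:  # noqa: BLE001 - report as a parse diagnostic
            problems.append(f"{d.name}/trials.csv: parse error: {e}")
            continue
        required = {"trial", "stimulus", "p_snake_given_A", "outcome", "is_rating"}
        missing = required - set(trials.columns)
        if missing:
            problems.append(f"{d.name}/trials.csv: missing columns {sorted(missing)}")
            continue
        p = trials["p_snake_given_A"].to_numpy(float)
        p_shown = np.where(trials["stimulus"].to_numpy() == "A", p, 1.0 - p)
        if np.any((p_shown < 0) | (p_shown > 1)):
            bad = int(np.flatnonzero((p_shown < 0) | (p_shown > 1))[0])
            problems.append(
                f"{d.name}/trials.csv row {bad + 2}: reciprocity violation "
                "(p(snake|A) + p(snake|B) != 1 cannot hold)"
            )
        u = trials["outcome"].to_numpy()
        if not np.isin(u, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(u, (0, 1)))[0])
            problems.append(f"{d.name}/trials.csv row {bad + 2}: non-binary outcome")

        rpath = d / "ratings.csv"
        if rpath.exists():
            ratings = pd.read_csv(rpath)
            n_prompts = int(trials["is_rating"].sum())
            if len(ratings) != n_prompts:
                problems.append(
                    f"{d.name}/ratings.csv: {len(ratings)} rows but "
                    f"{n_prompts} rating prompts in trials.csv"
                )
            elif not np.all(np.diff(ratings["trial_index"].to_numpy()) > 0):
                problems.append(f"{d.name}/ratings.csv: trial_index not increasing")
        else:
            problems.append(f"{d.name}: missing ratings.csv")

    cpath = root / "cortisol.csv"
    if cpath.exists():
        cort = pd.read_csv(cpath)
        expected = [f"sample_{i}" for i in range(1, 9)]
        if [c for c in expected if c not in cort.columns]:
            problems.append("cortisol.csv: expected columns sample_1..sample_8")
        else:
            vals = cort[expected].to_numpy(float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                problems.append("cortisol.csv: non-positive concentrations")

    return {"ok": not problems, "problems": problems, "n_subjects": len(sub_dirs)}
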