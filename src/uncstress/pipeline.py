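"""End-to-end pipeline: cohort simulation through group statistics.

Stages run in dependency order on a seeded synthetic cohort and write one
machine-readable output per stage under the output directory, plus a final
``report.json`` tying them together. All randomness derives from the master
seed via per-subject, per-stream seed derivation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from uncstress import io as cohort_io
from uncstress._utils import subject_seed
from uncstress.bms import rfx_bms
from uncstress.cohort import Cohort, simulate_cohort
from uncstress.endocrine import paired_wilcoxon, prepare_panel, skillings_mack
from uncstress.groupstats import accuracy, rt_tuning, sensitivity_coupling
from uncstress.learning import MODEL_NAMES, fit_model
from uncstress.physio import baseline_tuning, build_physio_design, robust_fit
from uncstress.stress import (
    RATING_MODELS,
    build_rating_design,
    compare_rating_models,
    fit_rating_model,
)
from uncstress.task import TaskConfig

log = logging.getLogger("uncstress")

ALL_STAGES = ("simulate", "fit-learning", "bms", "stress", "physio", "cortisol", "group")
LEARNING_MODELS = ("rw", "sutton_k1", "hgf")


@dataclass
class PipelineConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    n_subjects: int = 45
    master_seed: int = 0
    outdir: str = "results/pipeline"
    stages: tuple[str, ...] = ALL_STAGES
    models: tuple[str, ...] = LEARNING_MODELS
    include_physio: bool = True
    n_restarts: int = 3

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")
        needs = {"fit-learning": "simulate", "bms": "fit-learning",
                 "stress": "simulate", "physio": "simulate", "group": "stress"}
        for stage, dep in needs.items():
            if stage in self.stages and dep not in self.stages:
                raise ValueError(f"stage {stage!r} requires {dep!r}")


def _stage_fit_learning(cohort: Cohort, cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    from uncstress.learning import trajectory_for_subject

    rows, traj_rows = [], []
    for sub in cohort.subjects:
        for model in cfg.models:
            fit = fit_model(
                sub.choices, sub.schedule.outcome, sub.schedule.stimulus, model,
                n_restarts=cfg.n_restarts,
                seed=subject_seed(cfg.master_seed, sub.subject, f"fit-{model}"),
            )
            row = {"subject": sub.subject, "model": model,
                   "log_evidence": fit.log_evidence, "converged": fit.converged}
            row.update({f"param_{k}": v for k, v in fit.params_native.items()})
            rows.append(row)
            traj = trajectory_for_subject(model, fit.params_native,
                                          sub.schedule.outcome, sub.schedule.stimulus)
            t = pd.DataFrame({
                "subject": sub.subject, "model": model,
                "trial": np.arange(1, traj.n_trials + 1),
                "mu1hat": traj.mu1hat, "sigma1hat": traj.sigma1hat,
                "delta1": traj.delta1,
            })
            for name in ("mu2", "sigma2", "mu3", "sigma3"):
                val = getattr(traj, name)
                t[name] = val if val is not None else np.nan
            traj_rows.append(t)
        log.info("fit-learning: subject %d done", sub.subject)
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "fits.csv", index=False)
    pd.concat(traj_rows, ignore_index=True).to_csv(outdir / "trajectories.csv",
                                                   index=False)
    return fits


def _stage_stress(cohort: Cohort, cfg: PipelineConfig, outdir: Path):
    from uncstress._utils import zscore

    rows, bics = [], []
    for sub in cohort.subjects:
        z = zscore(sub.ratings)
        sub_bics = []
        for model in RATING_MODELS:
            design = build_rating_design(sub.trajectory, sub.schedule, z, model)
            res = fit_rating_model(design)
            sub_bics.append(res.bic)
            rows.append(
                {"subject": sub.subject, "model": model, "bic": res.bic,
                 "r_squared": res.r_squared,
                 **{f"beta_{c}": b for c, b in zip(res.columns, res.beta)}}
            )
        bics.append(sub_bics)
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "stress_fits.csv", index=False)
    bms = compare_rating_models(
        np.asarray(bics), seed=subject_seed(cfg.master_seed, 0, "stress-bms")
    )
    (outdir / "stress_bms.json").write_text(json.dumps({
        "models": bms.models,
        "alpha": bms.alpha.tolist(),
        "frequencies": bms.frequencies.tolist(),
        "exceedance": bms.exceedance.tolist(),
    }, indent=2))
    return fits, bms


def _stage_physio(cohort: Cohort, cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    for sub in cohort.subjects:
        for modality in ("pupil", "scr"):
            series = getattr(sub, modality)
            if series is None:
                continue
            design = build_physio_design(sub.schedule, sub.trajectory, modality,
                                         n_samples=len(series.values))
            res = robust_fit(design, series.values, mask=series.mask)
            tuning = baseline_tuning(series, sub.schedule, sub.trajectory)
            row = {"subject": sub.subject, "modality": modality,
                   "tuning_r": tuning.r, "tuning_amplitude": tuning.amplitude}
            row.update({f"beta_{c}": b for c, b in zip(res.columns, res.beta)})
            rows.append(row)
        log.info("physio: subject %d done", sub.subject)
    fits = pd.DataFrame(rows)
    fits.to_csv(outdir / "physio_fits.csv", index=False)
    return fits


def _stage_cortisol(cohort: Cohort, outdir: Path) -> dict:
    import warnings as _warnings

    panel = prepare_panel(cohort.cortisol)
    sm = skillings_mack(panel)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        baseline = np.nanmean(panel.values[:, :2], axis=1)
    z20, p20 = paired_wilcoxon(baseline, panel.values[:, 5])
    out = {
        "skillings_mack_T": sm.statistic, "df": sm.df, "p": sm.p_value,
        "wilcoxon_baseline_vs_20min": {"Z": z20, "p": p20},
        "excluded_subjects": panel.excluded_subjects,
        "n_subjects": panel.n_subjects,
    }
    (outdir / "cortisol_stats.json").write_text(json.dumps(out, indent=2))
    return out


def _stage_group(cohort: Cohort, stress_fits: pd.DataFrame,
                 physio_fits: pd.DataFrame | None, fits: pd.DataFrame | None,
                 outdir: Path) -> dict:
    irr = stress_fits[stress_fits.model == "irreducible"].set_index("subject")
    summaries = []
    for sub in cohort.subjects:
        row = {
            "subject": sub.subject,
            "accuracy": accuracy(sub.choices, sub.schedule.outcome),
            "stress_unc_beta": float(irr.loc[sub.subject, "beta_irreducible"]),
            "rating_mean": float(np.mean(sub.ratings)),
            "rating_var": float(np.var(sub.ratings)),
            "pss": sub.ground_truth.pss,
            "pupil_unc_beta": np.nan,
            "scr_unc_beta": np.nan,
            "theta": np.nan,
        }
        if fits is not None:
            hgf = fits[(fits.subject == sub.subject) & (fits.model == "hgf")]
            if len(hgf):
                row["theta"] = float(hgf["param_theta"].iloc[0])
        if physio_fits is not None and len(physio_fits):
            for modality in ("pupil", "scr"):
                m = physio_fits[(physio_fits.subject == sub.subject)
                                & (physio_fits.modality == modality)]
                if len(m):
                    row[f"{modality}_unc_beta"] = float(m["beta_uncertainty"].iloc[0])
        tuning = rt_tuning(sub.response_times_ms, sub.trajectory)
        row["rt_tuning_r"] = tuning.r
        summaries.append(row)
    df = pd.DataFrame(summaries)
    df.to_csv(outdir / "subject_summaries.csv", index=False)
    report: dict = {"mean_accuracy": float(df["accuracy"].mean()),
                    "mean_rt_tuning_r": float(df["rt_tuning_r"].mean())}
    if df["pupil_unc_beta"].notna().sum() >= 10 and df["theta"].notna().sum() >= 10:
        report["coupling"] = sensitivity_coupling(df)
    (outdir / "summary.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Execute the enabled stages in order; returns the report dict."""
    if cfg is None:
        cfg = PipelineConfig()
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"config": {"n_subjects": cfg.n_subjects,
                               "master_seed": cfg.master_seed,
                               "stages": list(cfg.stages),
                               "models": list(cfg.models)},
                    "stages": {}}

    cohort = None
    fits = stress_fits = physio_fits = None
    stress_bms = None
    try:
        if "simulate" in cfg.stages:
            cohort = simulate_cohort(cfg.task, cfg.master_seed, cfg.n_subjects,
                                     include_physio=cfg.include_physio)
            cohort_io.write_cohort(cohort, outdir / "cohort")
            report["stages"]["simulate"] = {"n_subjects": cfg.n_subjects}
        if "fit-learning" in cfg.stages:
            fits = _stage_fit_learning(cohort, cfg, outdir)
            report["stages"]["fit-learning"] = {"n_fits": len(fits)}
        if "bms" in cfg.stages:
            wide = fits.pivot(index="subject", columns="model", values="log_evidence")
            wide = wide[list(cfg.models)]
            bms = rfx_bms(wide.to_numpy(), models=list(cfg.models),
                          seed=subject_seed(cfg.master_seed, 0, "bms"))
            (outdir / "bms.json").write_text(json.dumps({
                "models": bms.models,
                "frequencies": bms.frequencies.tolist(),
                "exceedance": bms.exceedance.tolist(),
            }, indent=2))
            report["stages"]["bms"] = {"winner": bms.winner(),
                                       "exceedance": bms.exceedance.tolist()}
        if "stress" in cfg.stages:
            stress_fits, stress_bms = _stage_stress(cohort, cfg, outdir)
            report["stages"]["stress"] = {"winner": stress_bms.winner(),
                                          "exceedance": stress_bms.exceedance.tolist()}
        if "physio" in cfg.stages and cfg.include_physio:
            physio_fits = _stage_physio(cohort, cfg, outdir)
            report["stages"]["physio"] = {"n_fits": len(physio_fits)}
        if "cortisol" in cfg.stages:
            report["stages"]["cortisol"] = _stage_cortisol(cohort, outdir)
        if "group" in cfg.stages:
            report["stages"]["group"] = _stage_group(
                cohort, stress_fits, physio_fits, fits, outdir)
    except Exception as e:
        stage = next((s for s in cfg.stages if s not in report["stages"]), "?")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    report["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
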