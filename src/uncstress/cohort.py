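"""Synthetic cohort generation.

Generates complete synthetic subjects for the aversive learning task:
choices and response times from a 3-level HGF agent, subjective stress
ratings from the lag + shocks + irreducible-uncertainty regression model,
pupil and skin-conductance traces from the convolution GLM run generatively,
an 8-sample cortisol panel with missing cells and a post-stressor elevation,
and Perceived Stress Scale (PSS) scores rank-coupled to the metavolatility
parameter.

Population defaults describe a realistic cohort: 45 subjects, group-mean
rating coefficients 0.25 (previous rating), 0.074 (shocks) and 0.099
(irreducible uncertainty), pupil/SCR uncertainty sensitivities 0.11 / 0.044,
a cortisol elevation at the 20-minutes-into-task sample, 17.5% missing
cortisol cells (28 of 160), and a theta-PSS rank correlation of 0.39.
Between-subject spread in the uncertainty sensitivities is driven partly by
a shared latent factor, so that subjective and physiological sensitivity are
positively coupled across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from uncstress._utils import subject_seed
from uncstress.endocrine import CortisolPanel
from uncstress.learning import (
    BeliefTrajectory,
    HGFParams,
    ResponseParams,
    trajectory_for_subject,
)
from uncstress.physio import (
    PUPIL_RATE,
    SCR_RATE,
    PhysioTimeSeries,
    build_physio_design,
)
from uncstress.task import TaskConfig, TaskSchedule, generate_schedule

DEFAULT_RATING_COEFFS = {
    "intercept": 0.0,
    "lag": 0.25,
    "shocks": 0.074,
    "irreducible": 0.099,
}

DEFAULT_PUPIL_COEFFS = {
    "stimulus": 0.3,
    "outcome": 0.3,
    "shock": 0.8,
    "rating": 0.2,
    "surprise": 0.5,
    "uncertainty": 0.11,
    "luminance": 1.0,
}

DEFAULT_SCR_COEFFS = {
    "stimulus": 0.2,
    "outcome": 0.3,
    "shock": 1.0,
    "rating": 0.2,
    "surprise": 0.4,
    "uncertainty": 0.044,
}


@dataclass
class GroundTruth:
    """Generating parameters for one synthetic subject."""

    hgf: HGFParams
    resp: ResponseParams
    rating_coeffs: dict
    rating_noise_sd: float = 0.25
    pupil_coeffs: dict = field(default_factory=lambda: dict(DEFAULT_PUPIL_COEFFS))
    scr_coeffs: dict = field(default_factory=lambda: dict(DEFAULT_SCR_COEFFS))
    physio_noise_sd: float = 0.25
    rt_intercept_ms: float = 400.0
    rt_slope_ms: float = 800.0
    rt_noise_sd_ms: float = 100.0
    miss_rate: float = 0.02
    pss: float = np.nan


@dataclass
class SimulatedSubject:
    subject: int
    schedule: TaskSchedule
    ground_truth: GroundTruth
    choices: np.ndarray  # 1 = predicted snake, 0 = no snake, NaN = missing
    response_times_ms: np.ndarray  # NaN on missed trials
    trajectory: BeliefTrajectory
    ratings: np.ndarray
    pupil: PhysioTimeSeries | None = None
    scr: PhysioTimeSeries | None = None


def draw_ground_truth(
    rng: np.random.Generator,
    coupling: float = 0.2,
    omega_mean: float = -3.0,
    omega_sd: float = 1.0,
    theta_logit_mean: float = -2.0,
    theta_logit_sd: float = 0.7,
) -> GroundTruth:
    """Draw one subject's generating parameters from the population model.

    ``coupling`` scales the shared latent factor linking the subjective and
    physiological uncertainty sensitivities (0 = independent sensitivities).
    """
    omega = float(rng.normal(omega_mean, omega_sd))
    theta = float(1.0 / (1.0 + np.exp(-rng.normal(theta_logit_mean, theta_logit_sd))))
    theta = min(max(theta, 1e-4), 1.0 - 1e-4)

    f = rng.normal()  # shared sensitivity factor
    coeffs = dict(DEFAULT_RATING_COEFFS)
    coeffs["lag"] = float(np.clip(rng.normal(0.25, 0.1), -0.9, 0.9))
    coeffs["shocks"] = float(rng.normal(0.074, 0.05))
    coeffs["irreducible"] = float(0.099 + coupling * f + rng.normal(0.0, 0.15))

    pupil = dict(DEFAULT_PUPIL_COEFFS)
    pupil["uncertainty"] = float(0.11 + 0.05 * coupling / 0.2 * f + rng.normal(0.0, 0.04))
    scr = dict(DEFAULT_SCR_COEFFS)
    scr["uncertainty"] = float(0.044 + 0.02 * coupling / 0.2 * f + rng.normal(0.0, 0.02))

    return GroundTruth(
        hgf=HGFParams(omega=omega, theta=theta),
        resp=ResponseParams(zeta=1.0),
        rating_coeffs=coeffs,
        pupil_coeffs=pupil,
        scr_coeffs=scr,
    )


def simulate_agent(
    schedule: TaskSchedule,
    hgf: HGFParams,
    resp: ResponseParams | None = None,
    seed: int = 0,
    rt_intercept_ms: float = 400.0,
    rt_slope_ms: float = 800.0,
    rt_noise_sd_ms: float = 100.0,
    miss_rate: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, BeliefTrajectory]:
    """Simulate one HGF agent's choices and response times on a schedule.

    Choices are Bernoulli draws from the unit-square sigmoid probability of
    predicting the snake outcome. RT is affine in the trial's irreducible
    uncertainty plus Gaussian noise, truncated at the decision window; trials
    whose RT exceeds the window (or a `miss_rate` lapse) are missing, but
    outcomes still drive belief updates.
    """
    if resp is None:
        resp = ResponseParams()
    rng = np.random.default_rng(seed)
    traj = trajectory_for_subject(
        "hgf", {"omega": hgf.omega, "theta": hgf.theta}, schedule.outcome,
        schedule.stimulus, base_hgf=hgf,
    )
    z = resp.zeta
    p = np.clip(traj.mu1hat, 1e-12, 1 - 1e-12)
    p_snake = p**z / (p**z + (1 - p) ** z)
    choices = (rng.random(schedule.n_trials) < p_snake).astype(float)

    window = schedule.onset_prediction_ms - schedule.onset_decision_ms
    rt = rt_intercept_ms + rt_slope_ms * traj.sigma1hat + rng.normal(
        0.0, rt_noise_sd_ms, schedule.n_trials
    )
    missed = (rt >= window) | (rng.random(schedule.n_trials) < miss_rate)
    rt = np.where(missed, np.nan, np.maximum(rt, 100.0))
    choices[missed] = np.nan
    return choices, rt, traj


def simulate_ratings(
    traj: BeliefTrajectory,
    schedule: TaskSchedule,
    coeffs: dict | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    uncertainty: str = "irreducible",
) -> np.ndarray:
    """Generate the rating series from the autoregressive stress model.

    rating(k) = intercept + lag*rating(k-1) + shocks*(snakes since last
    rating) + beta_u * uncertainty(i(k)) + noise. The first rating starts at
    the AR stationary mean intercept/(1-lag).
    """
    if coeffs is None:
        coeffs = dict(DEFAULT_RATING_COEFFS)
    lag = coeffs["lag"]
    if abs(lag) >= 1.0:
        raise ValueError("lag coefficient must satisfy |lag| < 1 (stationarity)")
    rng = np.random.default_rng(seed)
    prompts = schedule.rating_trials
    n = len(prompts)
    unc_series = {
        "irreducible": traj.sigma1hat,
        "estimation": traj.sigma2,
        "volatility": traj.sigma3,
    }[uncertainty]
    if unc_series is None:
        raise ValueError(f"trajectory lacks the {uncertainty!r} series")
    beta_u = coeffs.get(uncertainty, coeffs.get("irreducible", 0.0))

    ratings = np.empty(n)
    ratings[0] = coeffs["intercept"] / (1.0 - lag)
    for k in range(1, n):
        shocks = int(schedule.outcome[prompts[k - 1]: prompts[k]].sum())
        ratings[k] = (
            coeffs["intercept"]
            + lag * ratings[k - 1]
            + coeffs["shocks"] * shocks
            + beta_u * unc_series[prompts[k] - 1]
            + rng.normal(0.0, noise_sd)
        )
    return ratings


def simulate_physio(
    traj: BeliefTrajectory,
    schedule: TaskSchedule,
    modality: str = "pupil",
    coeffs: dict | None = None,
    noise_sd: float = 0.25,
    drift_amplitude: float = 0.5,
    seed: int = 0,
    blink_rate_per_min: float = 12.0,
    kernel: np.ndarray | None = None,
) -> PhysioTimeSeries:
    """Generate a physiological trace by running the convolution GLM forward.

    signal = sum_j coeff_j * (regressor_j (*) kernel) + linear drift +
    Gaussian noise. Pupil traces additionally receive luminance
    constrictions (part of the design) and seeded blink gaps (sharp dips,
    annotated); SCR traces receive movement artifacts around task breaks.
    """
    if modality not in ("pupil", "scr"):
        raise ValueError(f"unknown modality {modality!r}")
    if coeffs is None:
        coeffs = dict(DEFAULT_PUPIL_COEFFS if modality == "pupil" else DEFAULT_SCR_COEFFS)
    rng = np.random.default_rng(seed)
    rate = PUPIL_RATE if modality == "pupil" else SCR_RATE

    design = build_physio_design(
        schedule, traj, modality=modality, kernel=kernel,
        add_derivatives=False, add_drift=False, standardize=False,
    )
    x = np.zeros(design.X.shape[0])
    for name, c in coeffs.items():
        if name in design.columns:
            x += c * design.X[:, design.columns.index(name)]
    n = len(x)
    x += drift_amplitude * np.linspace(-1.0, 1.0, n)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)

    blink_intervals: list[tuple[float, float]] = []
    break_times = [schedule.trial_end_ms[b - 1] / 1000.0 for b in schedule.break_after_trial]
    if modality == "pupil" and blink_rate_per_min > 0:
        duration_s = n / rate
        n_blinks = rng.poisson(blink_rate_per_min * duration_s / 60.0)
        for t0 in np.sort(rng.uniform(0.0, duration_s - 0.3, n_blinks)):
            t1 = t0 + rng.uniform(0.08, 0.25)
            i0, i1 = int(t0 * rate), min(n, int(t1 * rate) + 1)
            x[i0:i1] -= 3.0  # lid occlusion dropout
            blink_intervals.append((float(t0), float(t1)))
    if modality == "scr":
        for tb in break_times:
            i0 = int(tb * rate)
            i1 = min(n, i0 + int(5 * rate))
            x[i0:i1] += rng.normal(0.0, 8 * max(noise_sd, 0.05), max(0, i1 - i0))

    return PhysioTimeSeries(
        values=x,
        rate_hz=rate,
        blink_intervals_s=blink_intervals,
        break_times_s=break_times,
    )


def simulate_cortisol(
    n_subjects: int = 20,
    baseline_mean: float = 6.9,
    effect: float = 0.5,
    missing_rate: float = 0.175,
    seed: int = 0,
    between_sd: float = 0.4,
    within_sd: float = 0.25,
    effect_sample: int = 5,
) -> CortisolPanel:
    """Simulate a subjects x 8 cortisol panel in nmol/l.

    Values are log-normal around `baseline_mean` with between- and
    within-subject variation on the log scale; the sample collected 20 min
    into the task (index 5) is elevated by `effect` log units. Cells are
    deleted independently at `missing_rate`.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    log_mu = np.log(baseline_mean)
    subj = rng.normal(log_mu, between_sd, size=(n_subjects, 1))
    logv = subj + rng.normal(0.0, within_sd, size=(n_subjects, 8))
    logv[:, effect_sample] += effect
    values = np.exp(logv)
    if missing_rate > 0:
        drop = rng.random(values.shape) < missing_rate
        values[drop] = np.nan
    return CortisolPanel(values=values)


def simulate_questionnaires(thetas, rho: float = 0.39, seed: int = 0) -> np.ndarray:
    """PSS scores rank-coupled to metavolatility via a Gaussian copula.

    The latent Pearson correlation is 2*sin(pi*rho/6) so the population
    Spearman correlation equals `rho`. Scores are discretized to the 0-40
    PSS range via the normal CDF.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [-1, 1]")
    th = np.asarray(thetas, dtype=float)
    n = len(th)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    rng = np.random.default_rng(seed)
    r_latent = 2.0 * np.sin(np.pi * rho / 6.0)
    ranks = stats.rankdata(th, method="average")
    z1 = stats.norm.ppf((ranks - 0.5) / n)
    z2 = r_latent * z1 + np.sqrt(max(0.0, 1.0 - r_latent**2)) * rng.normal(size=n)
    return np.round(40.0 * stats.norm.cdf(z2))


def simulate_subject(
    schedule: TaskSchedule,
    gt: GroundTruth,
    subject: int,
    master_seed: int,
    include_physio: bool = True,
) -> SimulatedSubject:
    """Assemble one complete synthetic subject (seeded per stream)."""
    choices, rts, traj = simulate_agent(
        schedule, gt.hgf, gt.resp, seed=subject_seed(master_seed, subject, "agent"),
        rt_intercept_ms=gt.rt_intercept_ms, rt_slope_ms=gt.rt_slope_ms,
        rt_noise_sd_ms=gt.rt_noise_sd_ms, miss_rate=gt.miss_rate,
    )
    ratings = simulate_ratings(
        traj, schedule, gt.rating_coeffs, gt.rating_noise_sd,
        seed=subject_seed(master_seed, subject, "ratings"),
    )
    pupil = scr = None
    if include_physio:
        pupil = simulate_physio(
            traj, schedule, "pupil", gt.pupil_coeffs, gt.physio_noise_sd,
            seed=subject_seed(master_seed, subject, "pupil"),
        )
        scr = simulate_physio(
            traj, schedule, "scr", gt.scr_coeffs, gt.physio_noise_sd,
            seed=subject_seed(master_seed, subject, "scr"),
        )
    return SimulatedSubject(
        subject=subject,
        schedule=schedule,
        ground_truth=gt,
        choices=choices,
        response_times_ms=rts,
        trajectory=traj,
        ratings=ratings,
        pupil=pupil,
        scr=scr,
    )


@dataclass
class Cohort:
    subjects: list[SimulatedSubject]
    cortisol: CortisolPanel
    pss: np.ndarray
    config: TaskConfig
    master_seed: int


def simulate_cohort(
    config: TaskConfig | None = None,
    master_seed: int = 0,
    n_subjects: int | None = None,
    include_physio: bool = True,
    cortisol_subset: int = 20,
    coupling: float = 0.2,
    pss_rho: float = 0.39,
) -> Cohort:
    """Simulate a full cohort: each subject gets their own seeded schedule
    (outcomes sampled per subject), agent, ratings and physiology; a subset
    contributes cortisol panels; PSS scores are coupled to metavolatility."""
    if config is None:
        config = TaskConfig()
    if n_subjects is None:
        n_subjects = config.n_subjects
    pop_rng = np.random.default_rng(subject_seed(master_seed, 0, "population"))
    subjects = []
    for s in range(n_subjects):
        schedule = generate_schedule(config, seed=subject_seed(master_seed, s, "schedule"))
        # redraw parameter sets whose filter diverges on this outcome sequence
        for _ in range(50):
            gt = draw_ground_truth(pop_rng, coupling=coupling)
            sub = simulate_subject(schedule, gt, s, master_seed,
                                   include_physio=include_physio)
            if sub.trajectory.valid:
                break
        else:  # pragma: no cover - 50 consecutive divergent draws
            raise RuntimeError(f"could not draw a stable agent for subject {s}")
        subjects.append(sub)
    panel = simulate_cortisol(
        n_subjects=min(cortisol_subset, n_subjects),
        seed=subject_seed(master_seed, 0, "cortisol"),
    )
    thetas = np.array([s.ground_truth.hgf.theta for s in subjects])
    if n_subjects >= 3:
        pss = simulate_questionnaires(thetas, rho=pss_rho,
                                      seed=subject_seed(master_seed, 0, "pss"))
    else:
        pss = np.full(n_subjects, np.nan)
    for s, score in zip(subjects, pss):
        s.ground_truth.pss = float(score)
    return Cohort(subjects=subjects, cortisol=panel, pss=pss,
                  config=config, master_seed=master_seed)
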