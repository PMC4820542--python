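"""Trial-by-trial learning filters and per-subject model fitting.

Implements the 3-level binary Hierarchical Gaussian Filter (HGF),
Rescorla-Wagner (symmetric, independent-cue and dual-learning-rate variants)
and the Sutton K1 meta-learning-rate filter, together with a unit-square
sigmoid choice likelihood and MAP fitting with a Laplace approximation to
the log model evidence.

All filters emit a :class:`BeliefTrajectory` whose first-level quantities are
defined identically across models: mu1hat(k) is the pre-outcome predicted
probability that the *snake* outcome occurs on trial k given the shown
stimulus, sigma1hat = mu1hat*(1-mu1hat) is the irreducible (Bernoulli)
uncertainty of that prediction, and delta1 = u - mu1hat is the outcome
prediction error. Level-2/3 moments exist only for the HGF.

HGF update equations (binary, 3 levels, kappa fixed):

    mu1hat = s(mu2),  s = logistic sigmoid
    delta1 = u - mu1hat
    sigma2hat = sigma2 + exp(kappa*mu3 + omega)
    pi2 = 1/sigma2hat + mu1hat*(1 - mu1hat);  sigma2 <- 1/pi2
    mu2 <- mu2 + sigma2 * delta1
    w2 = exp(kappa*mu3 + omega) / sigma2hat
    delta2 = (sigma2 + (mu2 - mu2_old)**2) / sigma2hat - 1
    sigma3hat = sigma3 + theta
    pi3 = 1/sigma3hat + (kappa**2/2) * w2 * (w2 + (2*w2 - 1)*delta2)
    sigma3 <- 1/pi3;  mu3 <- mu3 + (kappa/2) * sigma3 * w2 * delta2

omega is the constant component of the level-2 log-volatility (baseline
update speed); theta ("metavolatility") is the step size of the volatility
level. A trajectory is flagged invalid if pi3 <= 0 or any moment becomes
non-finite; fitters treat invalid trajectories as evidence -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from uncstress._utils import FitError

MISSING = np.nan


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p) - np.log1p(-p)


@dataclass
class HGFParams:
    """Perceptual parameters of the 3-level binary HGF."""

    omega: float = -3.0
    theta: float = 0.1
    kappa: float = 1.0
    theta_max: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def validate(self) -> None:
        if not (0.0 < self.theta < self.theta_max):
            raise ValueError(f"theta must lie in (0, {self.theta_max})")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")


@dataclass
class ResponseParams:
    """Unit-square sigmoid observation model; zeta is the inverse-temperature
    exponent (zeta=1 is probability matching)."""

    zeta: float = 1.0

    def validate(self) -> None:
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")


@dataclass
class RWParams:
    """Rescorla-Wagner parameters.

    variant 'symmetric' tracks one p(snake|A) with the reciprocal belief for
    B; 'independent_cues' keeps separate values per stimulus;
    'dual_alpha' is symmetric but selects alpha_shock / alpha_noshock by the
    trial's outcome.
    """

    alpha: float = 0.2
    v0: float = 0.5
    variant: str = "symmetric"
    alpha_shock: float = 0.2
    alpha_noshock: float = 0.2

    def validate(self) -> None:
        for a in (self.alpha, self.alpha_shock, self.alpha_noshock):
            if not (0.0 <= a <= 1.0):
                raise ValueError("learning rates must lie in [0, 1]")
        if not (0.0 <= self.v0 <= 1.0):
            raise ValueError("v0 must lie in [0, 1]")
        if self.variant not in ("symmetric", "independent_cues", "dual_alpha"):
            raise ValueError(f"unknown RW variant {self.variant!r}")


@dataclass
class SuttonK1Params:
    """Sutton K1: the log learning-rate gain beta is itself adapted by the
    correlation of successive prediction errors (trace h)."""

    mu_gain: float = 0.02
    beta0: float = -1.6
    h0: float = 0.0
    v0: float = 0.5

    def validate(self) -> None:
        if self.mu_gain <= 0:
            raise ValueError("mu_gain must be positive")


@dataclass
class BeliefTrajectory:
    """Per-trial belief quantities for one subject under one model."""

    mu1hat: np.ndarray
    sigma1hat: np.ndarray
    delta1: np.ndarray
    mu2: np.ndarray | None = None
    sigma2: np.ndarray | None = None
    sigma2hat: np.ndarray | None = None
    mu3: np.ndarray | None = None
    sigma3: np.ndarray | None = None
    sigma3hat: np.ndarray | None = None
    delta2: np.ndarray | None = None
    learning_rate2: np.ndarray | None = None
    valid: bool = True
    model: str = ""

    @property
    def n_trials(self) -> int:
        return len(self.mu1hat)


def _as_binary(outcomes) -> np.ndarray:
    u = np.asarray(outcomes, dtype=float)
    if u.ndim != 1 or len(u) < 1:
        raise ValueError("outcomes must be a non-empty 1-D sequence")
    if not np.all((u == 0) | (u == 1)):
        raise ValueError("outcomes must be binary (0/1)")
    return u


def hgf_filter(outcomes, params: HGFParams) -> BeliefTrajectory:
    """Run the 3-level binary HGF over an outcome sequence.

    Beliefs are over p(snake|A); the symmetric task structure means the
    prediction for a trial showing B is 1 - s(mu2). Here outcomes are coded
    from the agent's belief axis directly (callers pass outcomes re-coded to
    the A-axis via :func:`recode_outcomes` when stimuli alternate).
    """
    u = _as_binary(outcomes)
    params.validate()
    n = len(u)
    k = params.kappa

    mu1hat = np.full(n, np.nan)
    sigma1hat = np.full(n, np.nan)
    delta1 = np.full(n, np.nan)
    mu2 = np.full(n, np.nan)
    sigma2 = np.full(n, np.nan)
    sigma2hat = np.full(n, np.nan)
    mu3 = np.full(n, np.nan)
    sigma3 = np.full(n, np.nan)
    sigma3hat = np.full(n, np.nan)
    delta2 = np.full(n, np.nan)
    lr2 = np.full(n, np.nan)

    m2, s2 = params.mu2_0, params.sigma2_0
    m3, s3 = params.mu3_0, params.sigma3_0
    valid = True

    for t in range(n):
        log_ev = k * m3 + params.omega
        if abs(m2) > 700.0 or log_ev > 700.0:
            valid = False
            break
        p = 1.0 / (1.0 + math.exp(-m2))
        mu1hat[t] = p
        sigma1hat[t] = p * (1.0 - p)
        d1 = u[t] - p
        delta1[t] = d1

        ev = math.exp(log_ev)
        s2h = s2 + ev
        sigma2hat[t] = s2h
        pi2 = 1.0 / s2h + p * (1.0 - p)
        s2_new = 1.0 / pi2
        m2_new = m2 + s2_new * d1
        lr2[t] = s2_new

        w2 = ev / s2h
        d2 = (s2_new + (m2_new - m2) ** 2) / s2h - 1.0
        delta2[t] = d2
        s3h = s3 + params.theta
        sigma3hat[t] = s3h
        pi3 = 1.0 / s3h + 0.5 * k * k * w2 * (w2 + (2.0 * w2 - 1.0) * d2)
        if pi3 <= 0 or not math.isfinite(pi3):
            valid = False
            break
        s3_new = 1.0 / pi3
        m3_new = m3 + 0.5 * k * s3_new * w2 * d2

        m2, s2, m3, s3 = m2_new, s2_new, m3_new, s3_new
        mu2[t], sigma2[t], mu3[t], sigma3[t] = m2, s2, m3, s3
        if not (math.isfinite(m2) and math.isfinite(m3)):
            valid = False
            break

    return BeliefTrajectory(
        mu1hat=mu1hat,
        sigma1hat=sigma1hat,
        delta1=delta1,
        mu2=mu2,
        sigma2=sigma2,
        sigma2hat=sigma2hat,
        mu3=mu3,
        sigma3=sigma3,
        sigma3hat=sigma3hat,
        delta2=delta2,
        learning_rate2=lr2,
        valid=valid,
        model="hgf",
    )


def recode_outcomes(outcomes, stimuli) -> np.ndarray:
    """Re-code outcomes onto the stimulus-A belief axis.

    With reciprocal contingencies a single belief v = p(snake|A) suffices:
    observing outcome u after stimulus B is evidence (1-u) about A.
    """
    u = _as_binary(outcomes)
    s = np.asarray(stimuli)
    if len(s) != len(u):
        raise ValueError("stimuli and outcomes must have equal length")
    return np.where(s == 0, u, 1.0 - u)


def _project_prediction(v_A: float, stim: int) -> float:
    return v_A if stim == 0 else 1.0 - v_A


def rw_filter(outcomes, stimuli, params: RWParams) -> BeliefTrajectory:
    """Rescorla-Wagner delta rule on the probability scale of the shown cue."""
    u = _as_binary(outcomes)
    s = np.asarray(stimuli, dtype=int)
    if len(s) != len(u):
        raise ValueError("stimuli and outcomes must have equal length")
    params.validate()
    n = len(u)

    mu1hat = np.empty(n)
    delta1 = np.empty(n)

    if params.variant == "independent_cues":
        v = [params.v0, params.v0]  # per-stimulus p(snake|stim)
        for t in range(n):
            p = v[s[t]]
            mu1hat[t] = p
            d = u[t] - p
            delta1[t] = d
            v[s[t]] = p + params.alpha * d
    else:
        v_A = params.v0  # p(snake|A); p(snake|B) = 1 - v_A
        for t in range(n):
            p = _project_prediction(v_A, s[t])
            mu1hat[t] = p
            d = u[t] - p
            delta1[t] = d
            if params.variant == "dual_alpha":
                a = params.alpha_shock if u[t] == 1 else params.alpha_noshock
            else:
                a = params.alpha
            p_new = p + a * d
            v_A = p_new if s[t] == 0 else 1.0 - p_new

    return BeliefTrajectory(
        mu1hat=mu1hat,
        sigma1hat=mu1hat * (1.0 - mu1hat),
        delta1=delta1,
        model=f"rw_{params.variant}",
    )


def sutton_k1_filter(outcomes, stimuli, params: SuttonK1Params) -> BeliefTrajectory:
    """Sutton K1 filter with symmetric cue coupling.

    Per trial: delta = u - v; beta += mu_gain*delta*h; alpha = min(1, e^beta);
    v += alpha*delta; h = (h + alpha*delta) * max(0, 1 - alpha).
    """
    u = _as_binary(outcomes)
    s = np.asarray(stimuli, dtype=int)
    if len(s) != len(u):
        raise ValueError("stimuli and outcomes must have equal length")
    params.validate()
    n = len(u)

    mu1hat = np.empty(n)
    delta1 = np.empty(n)
    v_A = params.v0
    beta = params.beta0
    h = params.h0
    for t in range(n):
        p = _project_prediction(v_A, s[t])
        mu1hat[t] = p
        d = u[t] - p
        delta1[t] = d
        beta = beta + params.mu_gain * d * h
        alpha = min(1.0, math.exp(min(beta, 50.0)))
        p_new = min(1.0, max(0.0, p + alpha * d))
        h = (h + alpha * d) * max(0.0, 1.0 - alpha)
        v_A = p_new if s[t] == 0 else 1.0 - p_new

    return BeliefTrajectory(
        mu1hat=mu1hat,
        sigma1hat=mu1hat * (1.0 - mu1hat),
        delta1=delta1,
        model="sutton_k1",
    )


def choice_loglik(traj: BeliefTrajectory, choices, resp: ResponseParams | None = None) -> float:
    """Unit-square sigmoid choice log-likelihood.

    P(predict snake) = mu1hat^zeta / (mu1hat^zeta + (1-mu1hat)^zeta).
    `choices` are 1 = predicted snake, 0 = predicted no snake, NaN = missing
    (skipped). Returns -inf for invalid trajectories.
    """
    if resp is None:
        resp = ResponseParams()
    resp.validate()
    if not traj.valid:
        return -np.inf
    c = np.asarray(choices, dtype=float)
    if len(c) != traj.n_trials:
        raise ValueError("choices must align with the trajectory")
    obs = ~np.isnan(c)
    p = np.clip(traj.mu1hat[obs], 1e-12, 1.0 - 1e-12)
    z = resp.zeta
    pz = p**z
    qz = (1.0 - p) ** z
    p_snake = pz / (pz + qz)
    ll = np.where(c[obs] == 1, np.log(p_snake), np.log1p(-p_snake))
    return float(ll.sum())


# ---------------------------------------------------------------------------
# MAP fitting with Laplace-approximate model evidence
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    model: str
    params_est: np.ndarray
    params_native: dict
    log_evidence: float
    neg_log_joint: float
    converged: bool
    n_restarts_used: int = 0


@dataclass
class Prior:
    """Gaussian prior in estimation space."""

    mean: float
    sd: float

    def logpdf(self, x: float) -> float:
        return float(stats.norm.logpdf(x, self.mean, self.sd))


# Default estimation-space priors (configurable per call).
DEFAULT_PRIORS: dict[str, dict[str, Prior]] = {
    "hgf": {"omega": Prior(-3.0, 4.0), "theta_logit": Prior(-2.0, 2.0)},
    "rw": {"alpha_logit": Prior(0.0, 2.0)},
    "rw_independent": {"alpha_logit": Prior(0.0, 2.0)},
    "rw_dual": {
        "alpha_shock_logit": Prior(0.0, 2.0),
        "alpha_noshock_logit": Prior(0.0, 2.0),
    },
    "sutton_k1": {"log_mu_gain": Prior(-4.0, 2.0)},
}

MODEL_NAMES = tuple(DEFAULT_PRIORS)


def project_to_shown(traj: BeliefTrajectory, stimuli, outcomes) -> BeliefTrajectory:
    """Project an A-axis HGF trajectory onto the shown stimulus per trial.

    mu1hat becomes the predicted probability of *snake on this trial* given
    the stimulus actually shown; delta1 = outcome - mu1hat. sigma1hat and the
    level-2/3 moments are invariant under the reciprocal flip.
    """
    s = np.asarray(stimuli)
    u = np.asarray(outcomes, dtype=float)
    mu1 = np.where(s == 0, traj.mu1hat, 1.0 - traj.mu1hat)
    return replace(traj, mu1hat=mu1, sigma1hat=mu1 * (1.0 - mu1), delta1=u - mu1)


def _traj_for(model: str, est: np.ndarray, outcomes_A, stimuli, base_hgf: HGFParams):
    """Map estimation-space parameters to a shown-axis trajectory."""
    if model == "hgf":
        theta = float(_sigmoid(est[1]) * base_hgf.theta_max)
        theta = min(max(theta, 1e-8), base_hgf.theta_max - 1e-8)
        p = replace(base_hgf, omega=float(est[0]), theta=theta)
        traj = hgf_filter(outcomes_A, p)
        shown = recode_outcomes(outcomes_A, stimuli)
        return project_to_shown(traj, stimuli, shown), {"omega": p.omega, "theta": p.theta}
    if model == "rw":
        a = float(_sigmoid(est[0]))
        return (
            rw_filter(recode_to_shown(outcomes_A, stimuli), stimuli, RWParams(alpha=a)),
            {"alpha": a},
        )
    if model == "rw_independent":
        a = float(_sigmoid(est[0]))
        return (
            rw_filter(
                recode_to_shown(outcomes_A, stimuli),
                stimuli,
                RWParams(alpha=a, variant="independent_cues"),
            ),
            {"alpha": a},
        )
    if model == "rw_dual":
        a1, a0 = float(_sigmoid(est[0])), float(_sigmoid(est[1]))
        return (
            rw_filter(
                recode_to_shown(outcomes_A, stimuli),
                stimuli,
                RWParams(alpha_shock=a1, alpha_noshock=a0, variant="dual_alpha"),
            ),
            {"alpha_shock": a1, "alpha_noshock": a0},
        )
    if model == "sutton_k1":
        g = float(np.exp(est[0]))
        return (
            sutton_k1_filter(
                recode_to_shown(outcomes_A, stimuli), stimuli, SuttonK1Params(mu_gain=g)
            ),
            {"mu_gain": g},
        )
    raise ValueError(f"unknown model {model!r}")


def recode_to_shown(outcomes_A, stimuli) -> np.ndarray:
    """Inverse of :func:`recode_outcomes`: A-axis outcomes back to shown-cue."""
    return recode_outcomes(outcomes_A, stimuli)  # the map is an involution


def trajectory_for_subject(model: str, params_native: dict, outcomes, stimuli,
                           base_hgf: HGFParams | None = None) -> BeliefTrajectory:
    """Run the named filter with native-space parameters on raw task data."""
    if base_hgf is None:
        base_hgf = HGFParams()
    if model == "hgf":
        p = replace(base_hgf, **params_native)
        traj = hgf_filter(recode_outcomes(outcomes, stimuli), p)
        return project_to_shown(traj, stimuli, outcomes)
    if model in ("rw", "rw_independent", "rw_dual"):
        variant = {"rw": "symmetric", "rw_independent": "independent_cues",
                   "rw_dual": "dual_alpha"}[model]
        return rw_filter(outcomes, stimuli, RWParams(variant=variant, **params_native))
    if model == "sutton_k1":
        return sutton_k1_filter(outcomes, stimuli, SuttonK1Params(**params_native))
    raise ValueError(f"unknown model {model!r}")


def _fd_hessian(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return H


def laplace_evidence(neg_log_joint, x_map: np.ndarray) -> tuple[float, bool]:
    """Laplace approximation to the log marginal likelihood.

    log p(y) ~ -nlj(x_map) + (d/2) log 2pi - (1/2) log |H|, where H is the
    finite-difference Hessian of `neg_log_joint` at the mode. Returns
    (log evidence, hessian_ok); when the Hessian is not positive definite
    the caller should treat the fit as non-converged.
    """
    x_map = np.atleast_1d(np.asarray(x_map, dtype=float))
    d = len(x_map)
    H = _fd_hessian(neg_log_joint, x_map)
    sign, logdet = np.linalg.slogdet(H)
    ok = bool(sign > 0 and np.isfinite(logdet))
    if not ok:
        return -np.inf, False
    nlj = float(neg_log_joint(x_map))
    return float(-nlj + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet), True


def fit_model(
    choices,
    outcomes,
    stimuli,
    model: str,
    priors: dict[str, Prior] | None = None,
    resp: ResponseParams | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    base_hgf: HGFParams | None = None,
) -> ModelFit:
    """MAP-fit one learning model to one subject's choices.

    Choices enter through the unit-square sigmoid likelihood; outcomes drive
    belief updates on every trial (including missed-choice trials). The log
    model evidence is the Laplace approximation
    log p(y) ~ log p(y, theta_MAP) + (d/2) log 2pi - (1/2) log |H|,
    with H the finite-difference Hessian of the negative log joint at the MAP.
    """
    if priors is None:
        priors = DEFAULT_PRIORS[model]
    if base_hgf is None:
        base_hgf = HGFParams()
    prior_list = list(priors.values())
    d = len(prior_list)
    outcomes_A = recode_outcomes(outcomes, stimuli)
    choices_A = np.asarray(choices, dtype=float)

    def neg_log_joint(est: np.ndarray) -> float:
        try:
            traj, _ = _traj_for(model, est, outcomes_A, stimuli, base_hgf)
        except (ValueError, OverflowError):
            return 1e10
        ll = choice_loglik(traj, choices_A, resp)
        if not np.isfinite(ll):
            return 1e10
        lp = sum(pr.logpdf(est[i]) for i, pr in enumerate(prior_list))
        return -(ll + lp)

    rng = np.random.default_rng(seed)
    starts = [np.array([pr.mean for pr in prior_list])]
    for _ in range(n_restarts - 1):
        starts.append(np.array([rng.normal(pr.mean, pr.sd) for pr in prior_list]))

    best = None
    for x0 in starts:
        res = optimize.minimize(neg_log_joint, x0, method="BFGS",
                                options={"maxiter": 300})
        if not res.success:
            res2 = optimize.minimize(neg_log_joint, res.x, method="Nelder-Mead",
                                     options={"maxiter": 500, "xatol": 1e-6, "fatol": 1e-8})
            if res2.fun < res.fun:
                res = res2
        if res.fun >= 1e9:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(f"all restarts failed for model {model!r}")

    x_map = np.asarray(best.x, dtype=float)
    nlj = float(best.fun)
    log_ev, converged = laplace_evidence(neg_log_joint, x_map)
    if not converged:
        # fall back to the prior-curvature penalty so evidence stays finite
        logdet = float(np.sum(np.log([1.0 / pr.sd**2 for pr in prior_list])))
        log_ev = -nlj + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet

    _, native = _traj_for(model, x_map, outcomes_A, stimuli, base_hgf)
    return ModelFit(
        model=model,
        params_est=x_map,
        params_native=native,
        log_evidence=float(log_ev),
        neg_log_joint=nlj,
        converged=converged,
        n_restarts_used=len(starts),
    )
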