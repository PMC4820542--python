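"""Regression models of subjective stress ratings.

Four competing models predict the z-scored stress rating at prompt k
(k = 2..65; the first rating has no lag term and is dropped). All share an
intercept, the previous rating Stress(k-1), and the number of shocks
received since the last rating. The fourth column is model specific:

- ``surprise``:    sum of |delta1| over trials since the last rating
- ``irreducible``: sigma1hat (pre-outcome Bernoulli variance) at trial i(k)
- ``estimation``:  sigma2 (posterior level-2 variance) at trial i(k)
- ``volatility``:  sigma3 (posterior level-3 variance) at trial i(k)
- ``combined``:    all three uncertainties (optional supplementary model)

Shock/surprise windows are the half-open trial interval (i(k-1), i(k)],
i.e. the rating trial itself is included. Models are fit per subject by OLS;
BIC = k*ln(n) - 2*loglik (Gaussian MLE) feeds random-effects BMS via
evidence = -BIC/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from uncstress._utils import DegenerateInputError
from uncstress.bms import BMSResult, rfx_bms
from uncstress.learning import BeliefTrajectory
from uncstress.task import TaskSchedule

RATING_MODELS = ("surprise", "irreducible", "estimation", "volatility")


@dataclass
class StressDesign:
    model: str
    source: str  # 'subjective' (model trajectory) or 'objective' (true p)
    X: np.ndarray  # rows = ratings 2..n, columns per `columns`
    y: np.ndarray  # rating values 2..n
    columns: list[str]


@dataclass
class RegressionResult:
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    r_squared: float
    resid_var: float
    bic: float
    loglik: float
    n: int
    k: int
    columns: list[str]


def shocks_between(schedule: TaskSchedule, i_prev: int, i_curr: int) -> int:
    """Number of snake outcomes on trials in (i_prev, i_curr] (1-based)."""
    return int(schedule.outcome[i_prev:i_curr].sum())


def build_rating_design(
    traj: BeliefTrajectory,
    schedule: TaskSchedule,
    ratings: np.ndarray,
    model: str = "irreducible",
    source: str = "subjective",
) -> StressDesign:
    """Build the design matrix for one stress-rating model.

    ``ratings`` must align with ``schedule.rating_trials``. The first rating
    is dropped (no lag available). With ``source='objective'`` the
    irreducible-uncertainty column uses p(1-p) from the true block
    contingency of the shown stimulus instead of the model belief.
    """
    if model not in RATING_MODELS + ("combined",):
        raise ValueError(f"unknown rating model {model!r}")
    if source not in ("subjective", "objective"):
        raise ValueError(f"unknown source {source!r}")
    ratings = np.asarray(ratings, dtype=float)
    prompts = schedule.rating_trials  # 1-based trial indices
    if len(ratings) != len(prompts):
        raise ValueError("ratings must align with the schedule's rating prompts")

    n = len(prompts) - 1
    lag = ratings[:-1]
    shocks = np.array(
        [shocks_between(schedule, prompts[j], prompts[j + 1]) for j in range(n)],
        dtype=float,
    )
    idx = prompts[1:] - 1  # 0-based trial index of each retained rating

    if source == "objective":
        p = schedule.p_snake_given_shown
        sigma1 = p * (1.0 - p)
    else:
        sigma1 = traj.sigma1hat

    def uncertainty_column(name: str) -> np.ndarray:
        if name == "surprise":
            absd = np.abs(traj.delta1)
            return np.array(
                [absd[prompts[j]: prompts[j + 1]].sum() for j in range(n)]
            )
        if name == "irreducible":
            return sigma1[idx]
        if name == "estimation":
            if traj.sigma2 is None:
                raise ValueError("trajectory has no level-2 variance")
            return traj.sigma2[idx]
        if name == "volatility":
            if traj.sigma3 is None:
                raise ValueError("trajectory has no level-3 variance")
            return traj.sigma3[idx]
        raise ValueError(name)

    columns = ["intercept", "lag", "shocks"]
    cols = [np.ones(n), lag, shocks]
    extra = (
        ["irreducible", "estimation", "volatility"] if model == "combined" else [model]
    )
    for name in extra:
        columns.append(name)
        cols.append(uncertainty_column(name))

    return StressDesign(
        model=model,
        source=source,
        X=np.column_stack(cols),
        y=ratings[1:],
        columns=columns,
    )


def fit_rating_model(design: StressDesign) -> RegressionResult:
    """OLS fit of one rating design; BIC from the Gaussian MLE likelihood.

    BIC counts the regression coefficients plus the residual variance as
    free parameters: BIC = (p+1)*ln(n) - 2*loglik.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n <= p:
        raise ValueError("need more ratings than design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        sds = X.std(axis=0)
        bad = [c for c, s in zip(design.columns, sds) if s == 0 and c != "intercept"]
        raise DegenerateInputError(
            f"rank-deficient design (rank {rank} < {p}); "
            f"constant/collinear columns: {bad or 'correlated regressors'}"
        )
    res = sm.OLS(y, X).fit()
    resid_var = float(np.mean(res.resid**2))  # MLE variance
    loglik = float(res.llf)
    k = p + 1
    bic = k * np.log(n) - 2.0 * loglik
    return RegressionResult(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        r_squared=float(res.rsquared),
        resid_var=resid_var,
        bic=float(bic),
        loglik=loglik,
        n=n,
        k=k,
        columns=design.columns,
    )


def compare_rating_models(
    bics: np.ndarray,
    models: list[str] | None = None,
    seed: int = 0,
    **bms_kwargs,
) -> BMSResult:
    """Random-effects BMS over per-subject BICs (subjects x models).

    Uses evidence = -BIC/2 per subject and model.
    """
    bics = np.asarray(bics, dtype=float)
    if models is None:
        models = list(RATING_MODELS)
    return rfx_bms(-bics / 2.0, models=models, seed=seed, **bms_kwargs)


def group_coefficient_test(betas: np.ndarray) -> tuple[float, float, float]:
    """Two-sided one-sample t-test of per-subject coefficients against zero.

    Returns (t, p, mean beta).
    """
    b = np.asarray(betas, dtype=float)
    if len(b) < 3:
        raise ValueError("need at least 3 subjects")
    if b.std(ddof=1) == 0:
        raise DegenerateInputError("coefficients have zero variance")
    from scipy import stats

    t, p = stats.ttest_1samp(b, 0.0)
    return float(t), float(p), float(b.mean())
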