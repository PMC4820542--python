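"""Salivary cortisol statistics.

The cortisol panel is subjects x 8 samples (nmol/l): two separate-day
baselines, arrival, pre-task, 10/20/30 min into task, and post-task. Missing
cells (damaged samples) are permitted. Analysis is on natural-log values;
subjects with an outlying baseline (more than 3 s.d. above the population
baseline mean) are excluded. The omnibus change-over-time test is the
Skillings-Mack statistic, a rank-based repeated-measures test that tolerates
missing data and reduces to Friedman's test on complete panels. Follow-up
contrasts use the paired Wilcoxon signed-rank test with a normal
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

SAMPLE_LABELS = (
    "baseline_day1",
    "baseline_day2",
    "arrival",
    "pre_task",
    "task_10min",
    "task_20min",
    "task_30min",
    "post_task",
)


@dataclass
class CortisolPanel:
    values: np.ndarray  # subjects x samples, NaN = missing
    labels: tuple[str, ...] = SAMPLE_LABELS
    units: str = "nmol/l"
    log_transformed: bool = False
    excluded_subjects: list[int] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class SMResult:
    statistic: float
    df: int
    p_value: float


def prepare_panel(
    panel: CortisolPanel, exclude_baseline_outliers: bool = True, n_sd: float = 3.0
) -> CortisolPanel:
    """Log-transform a raw panel and drop baseline-outlier subjects.

    The exclusion criterion is computed on raw concentrations: a subject is
    excluded when their mean separate-day baseline exceeds the population
    baseline mean by more than `n_sd` standard deviations.
    """
    v = np.asarray(panel.values, dtype=float)
    obs = ~np.isnan(v)
    if np.any(v[obs] <= 0):
        raise ValueError("cortisol concentrations must be positive before log")

    excluded: list[int] = []
    if exclude_baseline_outliers:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            baselines = np.nanmean(v[:, :2], axis=1)
        finite = np.isfinite(baselines)
        mu = np.nanmean(baselines[finite])
        sd = np.nanstd(baselines[finite])
        if sd > 0:
            excluded = [
                int(i)
                for i in np.flatnonzero(finite & (baselines > mu + n_sd * sd))
            ]
    keep = np.setdiff1d(np.arange(v.shape[0]), excluded)
    return CortisolPanel(
        values=np.log(v[keep]),
        labels=panel.labels,
        units=f"log({panel.units})",
        log_transformed=True,
        excluded_subjects=excluded,
    )


def skillings_mack(panel: CortisolPanel | np.ndarray) -> SMResult:
    """Skillings-Mack omnibus test for repeated measures with missing cells.

    Within each subject the observed cells are ranked (ties averaged) and
    centred; rank sums per treatment are weighted by sqrt(12/(k_i + 1)) with
    k_i the subject's number of observed cells. Under the null the weighted
    sums A have covariance Sigma with Sigma_jj = sum over subjects observing
    j of (k_i - 1) and Sigma_jj' = -(number of subjects observing both j and
    j'). T = A' Sigma^- A (Moore-Penrose generalized inverse) is referred to
    a chi-square distribution with t-1 degrees of freedom.
    """
    v = panel.values if isinstance(panel, CortisolPanel) else np.asarray(panel, float)
    n, t = v.shape
    if t < 2:
        raise ValueError("need at least 2 treatments")
    A = np.zeros(t)
    Sigma = np.zeros((t, t))
    used = 0
    for i in range(n):
        obs = ~np.isnan(v[i])
        k_i = int(obs.sum())
        if k_i < 2:
            continue
        used += 1
        ranks = stats.rankdata(v[i, obs])
        w = np.sqrt(12.0 / (k_i + 1.0))
        centred = w * (ranks - (k_i + 1.0) / 2.0)
        idx = np.flatnonzero(obs)
        A[idx] += centred
        for a_, j in enumerate(idx):
            Sigma[j, j] += k_i - 1
            for jp in idx[a_ + 1:]:
                Sigma[j, jp] -= 1
                Sigma[jp, j] -= 1
    if used == 0:
        raise ValueError("no subject has >= 2 observed cells")
    try:
        Sinv = np.linalg.pinv(Sigma)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise ValueError("degenerate covariance in Skillings-Mack test") from e
    T = float(A @ Sinv @ A)
    df = t - 1
    p = float(stats.chi2.sf(T, df))
    return SMResult(statistic=max(T, 0.0), df=df, p_value=p)


def paired_wilcoxon(sample_a, sample_b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Pairs with a missing value are dropped; zero differences are discarded
    (Wilcoxon's rule); the variance is tie-corrected. Returns (Z, two-sided
    p). Warns below 6 effective pairs, where the normal approximation is
    poor.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must be paired (equal length)")
    ok = ~(np.isnan(a) | np.isnan(b))
    d = b[ok] - a[ok]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    if n < 6:
        warnings.warn("fewer than 6 effective pairs; normal approximation is poor")
    r = stats.rankdata(np.abs(d))
    w_plus = float(r[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie correction on the variance of W+
    _, counts = np.unique(r, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        return 0.0, 1.0
    z = (w_plus - mean_w) / np.sqrt(var_w)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))
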