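"""Group-level statistics.

Correlations with a normality gate (Kolmogorov-Smirnov against a fitted
normal chooses Spearman over Pearson), one-sample t-tests, a closed-form 2x2
repeated-measures ANOVA with partial eta squared, response-time tuning
curves (shared Bernoulli-variance machinery with the physiology module), and
the cross-measure sensitivity-coupling report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from uncstress._utils import DegenerateInputError
from uncstress.physio import TuningResult, bernoulli_tuning


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    Pairs containing NaN are dropped (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def normality_gate(x, alpha: float = 0.05) -> str:
    """Recommend 'pearson' or 'spearman' from a KS test against a fitted
    normal distribution (spearman when normality is rejected)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if x.std() == 0:
        raise DegenerateInputError("normality test undefined for a constant vector")
    _, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return "spearman" if p < alpha else "pearson"


@dataclass
class AnovaEffect:
    F: float
    df: tuple[int, int]
    p: float
    eta_sq_partial: float


@dataclass
class TwoWayRMAnova:
    factor_a: AnovaEffect
    factor_b: AnovaEffect
    interaction: AnovaEffect


def twoway_rm_anova(cell_means: np.ndarray) -> TwoWayRMAnova:
    """2x2 fully within-subject ANOVA.

    ``cell_means`` is subjects x 4 in the cell order (a0b0, a0b1, a1b0,
    a1b1). For a 2x2 within design each effect reduces to a one-sample
    t-test on its per-subject contrast: F(1, n-1) = t^2. Partial eta
    squared is SS_effect / (SS_effect + SS_error) computed from the
    contrast decomposition.
    """
    m = np.asarray(cell_means, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError("cell_means must be subjects x 4 (a0b0, a0b1, a1b0, a1b1)")
    n = m.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    a0b0, a0b1, a1b0, a1b1 = m.T

    def effect(contrast: np.ndarray) -> AnovaEffect:
        # contrast scaled so its mean equals the effect size per subject
        c_mean = contrast.mean()
        c_var = contrast.var(ddof=1)
        if c_var == 0:
            return AnovaEffect(F=np.inf if c_mean != 0 else 0.0, df=(1, n - 1),
                               p=0.0 if c_mean != 0 else 1.0, eta_sq_partial=1.0 if c_mean != 0 else 0.0)
        F = n * c_mean**2 / c_var
        p = float(stats.f.sf(F, 1, n - 1))
        # SS_effect = n * c_mean^2, SS_error = sum (c_i - c_mean)^2 (in contrast units)
        ss_eff = n * c_mean**2
        ss_err = (n - 1) * c_var
        return AnovaEffect(F=float(F), df=(1, n - 1), p=p,
                           eta_sq_partial=float(ss_eff / (ss_eff + ss_err)))

    ca = (a1b0 + a1b1 - a0b0 - a0b1) / 2.0
    cb = (a0b1 + a1b1 - a0b0 - a1b0) / 2.0
    cab = (a1b1 - a1b0 - a0b1 + a0b0) / 2.0
    return TwoWayRMAnova(factor_a=effect(ca), factor_b=effect(cb), interaction=effect(cab))


def rt_tuning(response_times, traj, n_bins: int = 9) -> TuningResult:
    """Inverted-U tuning of response time with belief.

    Identical machinery to the physiological baseline tuning: trials are
    binned by the predicted probability mu1hat and a*p*(1-p) + c is fit to
    bin means. Missing RTs are excluded.
    """
    return bernoulli_tuning(np.asarray(response_times, float), traj.mu1hat, n_bins=n_bins)


def accuracy(choices, outcomes) -> float:
    """Fraction of non-missing trials where the prediction matches the outcome."""
    c = np.asarray(choices, dtype=float)
    u = np.asarray(outcomes, dtype=float)
    ok = ~np.isnan(c)
    if not ok.any():
        raise ValueError("no non-missing choices")
    return float((c[ok] == u[ok]).mean())


def sensitivity_coupling(summaries) -> dict:
    """Cross-measure coupling report.

    ``summaries`` is a DataFrame-like with per-subject columns:
    ``stress_unc_beta``, ``pupil_unc_beta``, ``scr_unc_beta``, ``accuracy``,
    ``theta``, ``pss``, ``rating_mean``, ``rating_var``. NaNs mark subjects
    missing a modality. Correlations are Pearson except theta-PSS, which is
    gated by the KS normality check.
    """
    import pandas as pd

    df = pd.DataFrame(summaries)
    if len(df) < 10:
        raise ValueError("need at least 10 subjects")
    report: dict = {}

    def corr(a: str, b: str, method: str = "pearson"):
        r, p = correlate(df[a].to_numpy(), df[b].to_numpy(), method)
        n_eff = int((~(df[a].isna() | df[b].isna())).sum())
        return {"r": r, "p": p, "n": n_eff, "method": method}

    report["stress_vs_pupil"] = corr("stress_unc_beta", "pupil_unc_beta")
    report["stress_vs_scr"] = corr("stress_unc_beta", "scr_unc_beta")
    report["accuracy_vs_stress_beta"] = corr("accuracy", "stress_unc_beta")
    report["accuracy_vs_pupil_beta"] = corr("accuracy", "pupil_unc_beta")

    theta = df["theta"].to_numpy()
    method = normality_gate(theta[~np.isnan(theta)])
    report["theta_vs_pss"] = corr("theta", "pss", method)

    # gross-measure controls: raw rating summaries should not predict accuracy
    report["accuracy_vs_rating_mean"] = corr("accuracy", "rating_mean")
    report["accuracy_vs_rating_var"] = corr("accuracy", "rating_var")
    return report
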