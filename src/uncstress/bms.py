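"""Random-effects Bayesian model selection.

Given per-subject log model evidences, estimates the population distribution
over models as a Dirichlet posterior via the standard variational iteration
(Stephan et al.-style group BMS): model identity is a subject-level latent
with a Dirichlet prior over population frequencies. Reports expected model
frequencies r_k and exceedance probabilities phi_k (the posterior probability
that model k is the most frequent in the population).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats


@dataclass
class BMSResult:
    models: list[str]
    alpha: np.ndarray  # Dirichlet posterior parameters
    frequencies: np.ndarray  # expected model frequencies r_k
    exceedance: np.ndarray  # exceedance probabilities phi_k
    assignments: np.ndarray  # subjects x models posterior model probabilities
    n_iterations: int
    converged: bool

    def winner(self) -> str:
        return self.models[int(np.argmax(self.exceedance))]


def _exceedance(alpha: np.ndarray, mc_samples: int, seed: int) -> np.ndarray:
    k = len(alpha)
    if k == 2:
        # P(x1 > x2) = P(x1 > 1/2) with x1 ~ Beta(a1, a2), exact.
        p1 = float(stats.beta.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    counts = np.zeros(k)
    remaining = int(mc_samples)
    chunk = 200_000
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return counts / mc_samples


def rfx_bms(
    log_evidence: np.ndarray,
    models: list[str] | None = None,
    alpha0: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    mc_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects BMS over a subjects x models log-evidence matrix.

    Iterates: g_nk proportional to exp(log-evidence_nk + psi(alpha_k) -
    psi(sum alpha)); alpha_k = alpha0 + sum_n g_nk; until the change in alpha
    falls below `tol`. -inf evidences are permitted (model never selected for
    that subject).
    """
    ev = np.asarray(log_evidence, dtype=float)
    if ev.ndim != 2 or ev.shape[1] < 2 or ev.shape[0] < 1:
        raise ValueError("log_evidence must be subjects x models with >=2 models")
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    n, k = ev.shape
    if models is None:
        models = [f"model_{i}" for i in range(k)]
    ev = np.where(np.isfinite(ev), ev, -1e12)

    alpha = np.full(k, alpha0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_u = ev + special.digamma(alpha) - special.digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged:
        warnings.warn(f"rfx_bms did not converge in {max_iter} iterations")

    freq = alpha / alpha.sum()
    phi = _exceedance(alpha, mc_samples, seed)
    return BMSResult(
        models=list(models),
        alpha=alpha,
        frequencies=freq,
        exceedance=phi,
        assignments=g,
        n_iterations=it,
        converged=converged,
    )
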