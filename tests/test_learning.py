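"""Learning filters, choice likelihood and MAP/Laplace fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from uncstress.learning import (
    BeliefTrajectory,
    HGFParams,
    ResponseParams,
    RWParams,
    SuttonK1Params,
    choice_loglik,
    fit_model,
    hgf_filter,
    laplace_evidence,
    recode_outcomes,
    rw_filter,
    sutton_k1_filter,
    trajectory_for_subject,
)


class TestHGF:
    def test_first_trial_prediction_is_maximally_uncertain(self):
        t = hgf_filter([1, 0, 1], HGFParams(mu2_0=0.0))
        assert t.mu1hat[0] == 0.5
        assert t.sigma1hat[0] == 0.25

    def test_consistent_outcomes_drive_belief_toward_certainty(self):
        t = hgf_filter(np.ones(100), HGFParams(omega=-2.0, theta=0.5))
        assert t.valid
        assert np.all(np.diff(t.mu1hat[1:]) >= -1e-12)
        assert t.mu1hat[-1] > 0.9

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        omega=st.floats(-6.0, 0.0),
        theta=st.floats(0.01, 0.9),
    )
    def test_sigma1hat_is_bernoulli_variance_of_mu1hat(self, seed, omega, theta):
        u = np.random.default_rng(seed).integers(0, 2, 200)
        t = hgf_filter(u, HGFParams(omega=omega, theta=theta))
        ok = ~np.isnan(t.mu1hat)
        if t.valid:
            assert ok.all()
        assert np.all(t.sigma1hat[ok] <= 0.25 + 1e-15)
        assert np.allclose(t.sigma1hat[ok], t.mu1hat[ok] * (1 - t.mu1hat[ok]))
        # beliefs stay in the unit interval (floats may saturate at the
        # boundary for extreme log-odds)
        assert np.all((t.mu1hat[ok] >= 0) & (t.mu1hat[ok] <= 1))

    def test_small_theta_approaches_constant_learning_rate(self):
        # with a vanishing metavolatility step the volatility level freezes,
        # so the filter reduces to fixed-volatility learning that a matched
        # constant-rate Rescorla-Wagner tracks closely
        rng = np.random.default_rng(3)
        u = (rng.random(1000) < 0.7).astype(float)
        t = hgf_filter(u, HGFParams(omega=-2.0, theta=1e-8, sigma3_0=1e-8))
        assert t.valid
        assert abs(t.mu3[-1] - t.mu3[0]) < 1e-4  # volatility belief frozen
        best = min(
            np.mean(np.abs(
                rw_filter(u, np.zeros(1000, int), RWParams(alpha=a)).mu1hat[500:]
                - t.mu1hat[500:]
            ))
            for a in np.linspace(0.01, 0.6, 60)
        )
        assert best < 0.03

    def test_non_binary_outcomes_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            hgf_filter([0.5, 1.0], HGFParams())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hgf_filter([1, 0], HGFParams(theta=2.0))


class TestRW:
    def test_hand_recursion_two_shocks(self):
        # v0=0.5, alpha=0.5, outcomes [1,1] on one stimulus:
        # post-update beliefs 0.75 then 0.875
        t = rw_filter([1, 1], [0, 0], RWParams(alpha=0.5, v0=0.5))
        post = t.mu1hat + 0.5 * t.delta1
        assert np.allclose(post, [0.75, 0.875])

    def test_alpha_zero_freezes_belief(self):
        t = rw_filter([1, 0, 1, 1], [0, 0, 0, 0], RWParams(alpha=0.0, v0=0.3))
        assert np.allclose(t.mu1hat, 0.3)

    def test_alpha_one_tracks_previous_outcome(self):
        u = [1, 0, 1, 1, 0]
        t = rw_filter(u, [0] * 5, RWParams(alpha=1.0, v0=0.5))
        assert np.allclose(t.mu1hat[1:], u[:-1])

    def test_symmetric_coupling_transfers_across_stimuli(self):
        # a shock after stimulus A raises p(snake|A), so the prediction for
        # the next trial showing B must fall below v0
        t = rw_filter([1, 0], [0, 1], RWParams(alpha=0.5, v0=0.5))
        assert t.mu1hat[1] == pytest.approx(0.25)

    def test_independent_cues_do_not_transfer(self):
        t = rw_filter([1, 0], [0, 1], RWParams(alpha=0.5, v0=0.5, variant="independent_cues"))
        assert t.mu1hat[1] == pytest.approx(0.5)

    def test_dual_alpha_selects_rate_by_outcome(self):
        t = rw_filter([1, 0], [0, 0], RWParams(variant="dual_alpha",
                                               alpha_shock=0.8, alpha_noshock=0.1, v0=0.5))
        assert t.mu1hat[1] == pytest.approx(0.5 + 0.8 * 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            rw_filter([1, 0], [0], RWParams())


class TestSuttonK1:
    def test_zero_trace_leaves_gain_unchanged_on_first_trial(self):
        p = SuttonK1Params(h0=0.0, beta0=-1.0, mu_gain=0.5)
        t = sutton_k1_filter([1, 1], [0, 0], p)
        # first update uses alpha = exp(beta0) exactly
        assert t.mu1hat[1] == pytest.approx(0.5 + np.exp(-1.0) * 0.5)

    def test_vanishing_meta_rate_reduces_to_rescorla_wagner(self):
        rng = np.random.default_rng(0)
        u = (rng.random(300) < 0.7).astype(float)
        s = rng.integers(0, 2, 300)
        t_k1 = sutton_k1_filter(u, s, SuttonK1Params(mu_gain=1e-12, beta0=np.log(0.2)))
        t_rw = rw_filter(u, s, RWParams(alpha=0.2))
        assert np.allclose(t_k1.mu1hat, t_rw.mu1hat, atol=1e-8)

    def test_alternating_outcomes_lower_learning_rate_than_consistent(self):
        n = 50
        alt = np.tile([1.0, 0.0], n // 2)
        const = np.ones(n)
        stim = np.zeros(n, int)
        p = SuttonK1Params(mu_gain=0.3, beta0=np.log(0.3))

        def final_alpha(u):
            t = sutton_k1_filter(u, stim, p)
            # recover the running gain by replaying the recursion
            beta, h, v = p.beta0, p.h0, p.v0
            for k in range(n):
                d = u[k] - v
                beta += p.mu_gain * d * h
                a = min(1.0, np.exp(beta))
                v += a * d
                h = (h + a * d) * max(0.0, 1 - a)
            return min(1.0, np.exp(beta))

        assert final_alpha(alt) < final_alpha(const)


class TestChoiceLikelihood:
    def test_uninformative_beliefs_give_chance_likelihood(self):
        t = BeliefTrajectory(mu1hat=np.full(10, 0.5), sigma1hat=np.full(10, 0.25),
                             delta1=np.zeros(10))
        for zeta in (0.5, 1.0, 3.0):
            ll = choice_loglik(t, np.ones(10), ResponseParams(zeta=zeta))
            assert ll == pytest.approx(10 * np.log(0.5))

    def test_zeta_one_is_probability_matching(self):
        mu = np.array([0.2, 0.8, 0.6])
        t = BeliefTrajectory(mu1hat=mu, sigma1hat=mu * (1 - mu), delta1=np.zeros(3))
        ll = choice_loglik(t, [1.0, 1.0, 0.0], ResponseParams(zeta=1.0))
        assert ll == pytest.approx(np.log(0.2) + np.log(0.8) + np.log(0.4))

    def test_zeta_two_sharpening(self):
        mu = np.array([0.8])
        t = BeliefTrajectory(mu1hat=mu, sigma1hat=mu * (1 - mu), delta1=np.zeros(1))
        ll = choice_loglik(t, [1.0], ResponseParams(zeta=2.0))
        assert ll == pytest.approx(np.log(0.64 / (0.64 + 0.04)))

    def test_missing_choices_are_skipped(self):
        mu = np.array([0.7, 0.7])
        t = BeliefTrajectory(mu1hat=mu, sigma1hat=mu * (1 - mu), delta1=np.zeros(2))
        assert choice_loglik(t, [1.0, np.nan]) == pytest.approx(np.log(0.7))

    def test_invalid_trajectory_is_minus_infinity(self):
        t = BeliefTrajectory(mu1hat=np.array([0.5]), sigma1hat=np.array([0.25]),
                             delta1=np.zeros(1), valid=False)
        assert choice_loglik(t, [1.0]) == -np.inf


class TestFitting:
    def test_laplace_evidence_matches_gaussian_closed_form(self):
        # y ~ N(theta, s2) iid, prior theta ~ N(m0, t2): the marginal
        # likelihood is available in closed form and the posterior is
        # Gaussian, so the Laplace approximation is exact.
        rng = np.random.default_rng(1)
        s2, t2, m0 = 1.3, 2.0, 0.4
        y = rng.normal(1.0, np.sqrt(s2), 25)
        n = len(y)

        def nlj(x):
            th = x[0]
            return -(
                stats.norm.logpdf(y, th, np.sqrt(s2)).sum()
                + stats.norm.logpdf(th, m0, np.sqrt(t2))
            )

        x_map = optimize.minimize(nlj, [0.0]).x
        log_ev, ok = laplace_evidence(nlj, x_map)
        # closed form: y ~ N(m0 * 1, s2 I + t2 J)
        cov = s2 * np.eye(n) + t2 * np.ones((n, n))
        exact = stats.multivariate_normal.logpdf(y, mean=np.full(n, m0), cov=cov)
        assert ok
        assert log_ev == pytest.approx(exact, abs=1e-6)

    def test_random_choices_bounded_by_chance_likelihood(self, default_schedule):
        s = default_schedule
        c = (np.random.default_rng(0).random(320) < 0.5).astype(float)
        for model in ("rw", "hgf"):
            f = fit_model(c, s.outcome, s.stimulus, model, n_restarts=2, seed=0)
            traj = trajectory_for_subject(model, f.params_native, s.outcome, s.stimulus)
            ll = choice_loglik(traj, c)
            assert ll <= 320 * np.log(0.5) + 10.0

    def test_fit_recovers_rw_learning_rate(self, default_schedule):
        s = default_schedule
        rng = np.random.default_rng(5)
        traj = rw_filter(s.outcome, s.stimulus, RWParams(alpha=0.25))
        c = (rng.random(320) < traj.mu1hat).astype(float)
        f = fit_model(c, s.outcome, s.stimulus, "rw", n_restarts=3, seed=1)
        assert f.converged
        assert abs(f.params_native["alpha"] - 0.25) < 0.15

    def test_outcomes_update_beliefs_on_missed_trials(self, default_schedule):
        s = default_schedule
        c = np.ones(320)
        c[::3] = np.nan
        f = fit_model(c, s.outcome, s.stimulus, "rw", n_restarts=2, seed=0)
        assert np.isfinite(f.log_evidence)
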