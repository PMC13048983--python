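"""FFBS sampler: forward filter vs exhaustive enumeration, backward-sampling
law, surrogate objective, Gibbs determinism and parameter recovery."""

import numpy as np
import pytest

import blinkhmm as bh
from blinkhmm.gibbs import backward_weights
from blinkhmm.model import OFF, ON
from .conftest import enumerate_path_posterior, exact_marginals


class TestForwardFilter:
    def test_uninformative_emissions_give_prior_marginals(self, small_params):
        # identical components: emissions cancel under normalization and the
        # filter reduces to the chain marginals pi, A pi, A^2 pi, ...
        p = bh.ModelParams(
            mu=np.array([0.5, 0.5]), lam=np.array([2.0, 2.0]),
            A=small_params.A, pi=small_params.pi,
        )
        x = np.random.default_rng(0).normal(size=6)
        F = bh.forward_filter(x, p)
        marg = p.pi.copy()
        for n in range(6):
            assert np.allclose(F.f[n], marg, atol=1e-12)
            marg = p.A @ marg

    def test_matches_exhaustive_path_sum(self, small_params):
        # total unnormalized forward mass = sum of the joint density over all
        # 2^N hidden paths (brute-force enumeration oracle)
        from itertools import product
        from .conftest import log_path_density

        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        F = bh.forward_filter(x, small_params)
        logps = [log_path_density(p, x, small_params)
                 for p in product(range(2), repeat=6)]
        brute = np.logaddexp.reduce(logps)
        assert F.log_marginal_likelihood == pytest.approx(brute, rel=1e-10)

    def test_rows_normalized(self, small_params):
        x = np.random.default_rng(2).normal(size=50)
        F = bh.forward_filter(x, small_params)
        assert np.allclose(F.f.sum(axis=1), 1.0, atol=1e-12)

    def test_identity_chain_accumulates_evidence(self):
        # A = I: the filter is the running likelihood ratio, which moves
        # monotonically toward the state favored by the data
        p = bh.ModelParams(
            mu=np.array([1.0, -1.0]), lam=np.array([1.0, 1.0]),
            A=np.eye(2), pi=np.array([0.5, 0.5]),
        )
        x = np.full(20, 1.0)  # every bin favors ON
        F = bh.forward_filter(x, p)
        assert np.all(np.diff(F.f[:, ON]) >= 0)
        assert F.f[-1, ON] > 0.999


class TestBackwardSample:
    def test_weights_normalized(self, small_params):
        x = np.random.default_rng(3).normal(size=10)
        F = bh.forward_filter(x, small_params)
        for n in range(9):
            for ell in range(2):
                eta = backward_weights(F.f[n], small_params.A, ell)
                assert eta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identity_chain_gives_constant_path(self):
        p = bh.ModelParams(
            mu=np.array([1.0, -1.0]), lam=np.array([1.0, 1.0]),
            A=np.eye(2), pi=np.array([0.5, 0.5]),
        )
        x = np.full(15, 1.0)
        F = bh.forward_filter(x, p)
        S = bh.backward_sample(F, p.A, np.random.default_rng(4))
        assert np.all(S.labels == S.labels[0])

    def test_marginals_match_enumeration(self, small_params):
        # per-bin marginals of 20k FFBS draws vs exhaustive enumeration
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        F = bh.forward_filter(x, small_params)
        truth = exact_marginals(x, small_params)
        counts = np.zeros((6, 2))
        n_draws = 20_000
        for _ in range(n_draws):
            S = bh.backward_sample(F, small_params.A, rng)
            counts[np.arange(6), S.labels] += 1
        tv = 0.5 * np.abs(counts / n_draws - truth).sum(axis=1)
        assert np.all(tv < 0.02)


class TestSurrogate:
    def test_baseline_constant(self):
        assert bh.BASELINE_NATS == pytest.approx(-1.4189, abs=5e-5)

    def test_single_state_no_transition_cost(self):
        p = bh.ModelParams(
            mu=np.array([0.0, 5.0]), lam=np.array([1.0, 1.0]),
            A=np.eye(2), pi=np.array([1.0, 0.0]),
        )
        S = bh.StateSequence(labels=np.zeros(30, dtype=np.int64))
        x = np.random.default_rng(6).normal(size=30)
        terms = bh.surrogate_loglik(x, S, p)
        assert terms.transition == 0.0
        assert terms.L == pytest.approx(terms.emission + terms.initial)

    def test_approximation_close_on_long_stationary_data(self):
        # exact per-sweep L vs the stationary-occupancy approximation
        sc = bh.default_scenario(duration=5.0, seed=8)
        states, trace = bh.simulate_molecule(sc)
        x, _, sd = bh.standardize(trace)
        mu = (np.array([sc.mu_on, sc.mu_off]) - trace.counts.mean()) / sd
        lam = sd**2 / np.array([sc.mu_on, sc.mu_off])
        p = bh.ModelParams(mu=mu, lam=lam, A=sc.transition_matrix(),
                           pi=sc.stationary_pi())
        terms = bh.surrogate_loglik(x, states, p)
        approx = bh.surrogate_approx(states.occupancy(), lam, p.A)
        assert abs(terms.L - approx) < 0.05

    def test_forbidden_transition_reports_minus_inf(self):
        p = bh.ModelParams(
            mu=np.array([1.0, -1.0]), lam=np.array([1.0, 1.0]),
            A=np.eye(2), pi=np.array([0.5, 0.5]),
        )
        S = bh.StateSequence(labels=np.array([ON, OFF, OFF]))
        terms = bh.surrogate_loglik(np.zeros(3), S, p)
        assert terms.transition == -np.inf


class TestGibbsFit:
    def test_bitwise_deterministic(self):
        sc = bh.default_scenario(duration=0.25, seed=3)
        _, trace = bh.simulate_molecule(sc)
        hp = bh.Hyperparams(n_iter=60, burn_in=20)
        f1 = bh.gibbs_fit(trace, hp, rng=9)
        f2 = bh.gibbs_fit(trace, hp, rng=9)
        assert np.array_equal(f1.mu_chain, f2.mu_chain)
        assert np.array_equal(f1.labels_chain, f2.labels_chain)
        assert np.array_equal(f1.objective, f2.objective)

    def test_recovers_generating_parameters(self, reference_fit):
        sc, states, trace, fit = reference_fit
        s = fit.summary
        assert s.mu_counts[ON] == pytest.approx(sc.mu_on, rel=0.10)
        assert s.A_bar[ON, ON] == pytest.approx(
            1 - sc.delta / sc.tau_on, abs=0.01
        )
        assert s.mu_counts[ON] > s.mu_counts[OFF]

    def test_occupancy_near_stationary(self, reference_fit):
        sc, states, trace, fit = reference_fit
        expected = sc.tau_on / (sc.tau_on + sc.tau_off)
        assert fit.summary.n_on_mean / fit.N == pytest.approx(expected, abs=0.05)

    def test_objective_converges_quickly(self, reference_fit):
        *_, fit = reference_fit
        assert bh.sweeps_to_converge(fit.objective_trace, tol=0.01) <= 30

    def test_zero_spread_trace_refused(self):
        trace = bh.PhotonTrace(counts=np.full(100, 7), delta=5e-4)
        with pytest.raises(bh.ValidationError, match="spread"):
            bh.gibbs_fit(trace, bh.Hyperparams(n_iter=10, burn_in=1))


class TestPosteriorSummary:
    def test_frozen_chain_means_equal_value(self, reference_fit):
        *_, fit = reference_fit
        one = bh.posterior_summary(fit, burn_in=fit.n_iter - 1)
        assert np.allclose(one.mu_bar, fit.mu_chain[-1])
        assert np.allclose(one.A_bar, fit.A_chain[-1])

    def test_normalization_identities(self, reference_fit):
        *_, fit = reference_fit
        s = fit.summary
        assert s.w.sum() == pytest.approx(1.0)
        assert s.n_on_mean + s.n_off_mean == pytest.approx(fit.N)
        assert np.all((s.state_marginals >= 0) & (s.state_marginals <= 1))
        assert np.allclose(s.A_bar.sum(axis=0), 1.0)
        assert s.pi_bar.sum() == pytest.approx(1.0)

    def test_bad_burn_in_rejected(self, reference_fit):
        *_, fit = reference_fit
        with pytest.raises(bh.ValidationError):
            bh.posterior_summary(fit, burn_in=fit.n_iter)


class TestGibbsInvariance:
    def test_full_sweep_preserves_exact_joint_posterior(self):
        """One complete Gibbs sweep applied to an exact joint-posterior draw
        must return an exact joint-posterior draw (stationarity).

        On a tiny trace the exact posterior over hidden paths with the
        parameters integrated out is available in closed form (conjugate
        marginals, computed in the oracle below); we draw (S, theta) exactly,
        apply one full sweep S -> (mu, lam) -> pi -> A -> S, and check the
        per-bin state marginals are unchanged within Monte-Carlo error.
        """
        from itertools import product
        from scipy.special import gammaln
        from blinkhmm.model import emission_posterior_params, transition_counts

        hp = bh.Hyperparams()
        rng = np.random.default_rng(11)
        x = rng.normal(size=5) * 1.5
        N = x.size

        def collapsed_log_joint(labels):
            S = bh.StateSequence(labels=np.asarray(labels))
            up = emission_posterior_params(S, x, hp)
            lp = -0.5 * N * np.log(2 * np.pi)
            for k in range(2):
                lp += 0.5 * (np.log(hp.nu) - np.log(up.nu_hat[k]))
                lp += gammaln(up.a_hat[k]) - gammaln(hp.a)
                lp += hp.a * np.log(hp.b) - up.a_hat[k] * np.log(up.b_hat[k])
            lp += np.log(hp.alpha[labels[0]]) - np.log(hp.alpha.sum())
            C = transition_counts(S)
            for ell in range(2):
                tot = hp.beta[:, ell].sum()
                lp += gammaln(tot) - gammaln(tot + C[:, ell].sum())
                for k in range(2):
                    lp += gammaln(hp.beta[k, ell] + C[k, ell]) \
                        - gammaln(hp.beta[k, ell])
            return lp

        paths = [np.array(p) for p in product(range(2), repeat=N)]
        logp = np.array([collapsed_log_joint(p) for p in paths])
        probs = np.exp(logp - logp.max())
        probs /= probs.sum()
        truth = np.zeros((N, 2))
        for path, p in zip(paths, probs):
            truth[np.arange(N), path] += p

        counts = np.zeros((N, 2))
        n_rep = 20_000
        for _ in range(n_rep):
            S0 = paths[rng.choice(len(paths), p=probs)]      # exact S | I
            S0 = bh.StateSequence(labels=S0.copy())
            # one full sweep: theta | S, then S | theta (FFBS)
            mu, lam, _ = bh.sample_emission_posterior(S0, x, hp, rng)
            pi, _ = bh.sample_initial_posterior(int(S0.labels[0]), hp, rng)
            A, _ = bh.sample_transition_posterior(S0, hp, False, rng)
            params = bh.ModelParams(mu=mu, lam=lam, A=A, pi=pi)
            S1 = bh.backward_sample(bh.forward_filter(x, params), A, rng)
            counts[np.arange(N), S1.labels] += 1
        tv = 0.5 * np.abs(counts / n_rep - truth).sum(axis=1)
        assert np.all(tv < 0.02)
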