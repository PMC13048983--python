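"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately brute-force (exhaustive path enumeration,
direct density evaluation through scipy.stats) so they share no code with the
implementation paths they check.
"""

from itertools import product

import numpy as np
import pytest
from hypothesis import settings
from scipy.stats import dirichlet, gamma, norm

import blinkhmm as bh

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_fit():
    """One full fit of a default-scenario molecule, shared across tests."""
    scenario = bh.default_scenario(seed=7)
    states, trace = bh.simulate_molecule(scenario)
    fit = bh.gibbs_fit(trace, bh.Hyperparams(), rng=7)
    return scenario, states, trace, fit


# ------------------------------------------------------------------ oracles

def log_path_density(path, x, params):
    """Log joint p(I_{1:N}, S=path | params) by direct multiplication."""
    lp = np.log(params.pi[path[0]]) + norm.logpdf(
        x[0], params.mu[path[0]], 1.0 / np.sqrt(params.lam[path[0]])
    )
    for n in range(1, len(x)):
        lp += np.log(params.A[path[n], path[n - 1]])
        lp += norm.logpdf(
            x[n], params.mu[path[n]], 1.0 / np.sqrt(params.lam[path[n]])
        )
    return lp


def enumerate_path_posterior(x, params):
    """Exact posterior over all K^N hidden paths.  Returns (paths, probs)."""
    K = params.K
    paths = list(product(range(K), repeat=len(x)))
    logp = np.array([log_path_density(p, x, params) for p in paths])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    return paths, probs


def exact_marginals(x, params):
    """Per-bin posterior state marginals from exhaustive enumeration."""
    paths, probs = enumerate_path_posterior(x, params)
    N, K = len(x), params.K
    marg = np.zeros((N, K))
    for path, p in zip(paths, probs):
        for n, k in enumerate(path):
            marg[n, k] += p
    return marg


def log_joint(x, labels, mu, lam, A, pi, hp):
    """Complete-data log joint density of the model: likelihood times all priors."""
    lp = 0.0
    for n, k in enumerate(labels):
        lp += norm.logpdf(x[n], mu[k], 1.0 / np.sqrt(lam[k]))
    lp += np.log(pi[labels[0]])
    for n in range(1, len(labels)):
        lp += np.log(A[labels[n], labels[n - 1]])
    for k in range(len(mu)):
        lp += norm.logpdf(mu[k], hp.m, 1.0 / np.sqrt(hp.nu * lam[k]))
        lp += gamma.logpdf(lam[k], hp.a, scale=1.0 / hp.b)
    lp += dirichlet.logpdf(pi, hp.alpha)
    for ell in range(A.shape[1]):
        lp += dirichlet.logpdf(A[:, ell], hp.beta[:, ell])
    return lp


@pytest.fixture
def small_params():
    """Fixed, well-mixing K=2 parameters for enumeration comparisons."""
    return bh.ModelParams(
        mu=np.array([1.0, -1.0]),
        lam=np.array([1.2, 0.8]),
        A=np.array([[0.7, 0.4], [0.3, 0.6]]),
        pi=np.array([0.6, 0.4]),
    )
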