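"""Model types and closed-form conjugate posterior updates.

The observation model is a K-state Gaussian-emission hidden Markov model for a
standardized photon-count series I = (I_1..I_N): each hidden state k emits
counts from N(mu_k, lam_k^{-1}), the hidden chain has a column-stochastic
transition matrix A (A[k, l] = P(state k at n | state l at n-1)) and initial
distribution pi.  Priors are conjugate throughout -- Gauss-Gamma on each
(mu_k, lam_k), Dirichlet on pi and on every column of A -- so all parameter
blocks of the Gibbs sampler have exact closed-form full conditionals, which
this module implements.

State index 0 is the ON (bright) state and index 1 the OFF (dark) state once
labels have been ordered; the raw sampler is label-exchangeable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

ON = 0
OFF = 1

_LOG_2PI = float(np.log(2.0 * np.pi))


class ValidationError(ValueError):
    """Invalid model input (non-stochastic matrix, bad shapes, ...)."""


class DegenerateDataError(RuntimeError):
    """Posterior update collided with degenerate data (e.g. zero spread)."""


def _check_stochastic_columns(M: np.ndarray, name: str, tol: float = 1e-12) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {M.shape}")
    if np.any(M < -tol):
        raise ValidationError(f"{name} has negative entries")
    colsums = M.sum(axis=0)
    bad = np.where(np.abs(colsums - 1.0) > 1e-9)[0]
    if bad.size:
        raise ValidationError(
            f"column {bad[0]} of {name} sums to {colsums[bad[0]]!r}, expected 1"
        )


def _check_simplex(v: np.ndarray, name: str) -> None:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be a vector")
    if np.any(v < 0):
        raise ValidationError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{name} sums to {v.sum()!r}, expected 1")


@dataclass
class PhotonTrace:
    """Observed photon-count trajectory: one integer count per time bin."""

    counts: np.ndarray
    delta: float
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValidationError("counts must be a nonempty 1-d sequence")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        if not self.delta > 0:
            raise ValidationError("delta must be positive")

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def duration(self) -> float:
        return self.counts.size * self.delta


@dataclass
class StateSequence:
    """Hidden state labels, one per bin, with one-hot semantics.

    ``labels[n]`` is the index of the single active state at bin n
    (0 = ON, 1 = OFF for the two-state blinking analysis).
    """

    labels: np.ndarray
    K: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("labels must be a nonempty 1-d sequence")
        if self.labels.min() < 0 or self.labels.max() >= self.K:
            raise ValidationError(f"labels must lie in 0..{self.K - 1}")

    def __len__(self) -> int:
        return int(self.labels.size)

    def one_hot(self) -> np.ndarray:
        """(N, K) one-hot matrix s with s[n, k] = 1 iff labels[n] == k."""
        s = np.zeros((self.labels.size, self.K))
        s[np.arange(self.labels.size), self.labels] = 1.0
        return s

    def occupancy(self) -> np.ndarray:
        """Per-state occupancy frequencies w (sums to 1)."""
        return np.bincount(self.labels, minlength=self.K) / self.labels.size


@dataclass
class ModelParams:
    """Emission means/precisions, transition matrix and initial distribution."""

    mu: np.ndarray
    lam: np.ndarray
    A: np.ndarray
    pi: np.ndarray
    standardized: bool = True

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.lam <= 0):
            raise ValidationError("precisions lam must be strictly positive")
        _check_stochastic_columns(self.A, "A")
        _check_simplex(self.pi, "pi")

    @property
    def K(self) -> int:
        return int(self.mu.size)

    def to_json(self, delta: float | None = None) -> str:
        payload = {
            "mu": self.mu.tolist(),
            "lambda": self.lam.tolist(),
            "A": self.A.tolist(),
            "pi": self.pi.tolist(),
            "standardized": bool(self.standardized),
        }
        if delta is not None:
            payload["delta_s"] = float(delta)
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        d = json.loads(text)
        return cls(
            mu=d["mu"], lam=d["lambda"], A=d["A"], pi=d["pi"],
            standardized=d.get("standardized", True),
        )


@dataclass
class Hyperparams:
    """Prior hyperparameters and sampler settings.

    Defaults are the reference simulation conditions: Gauss-Gamma
    (nu, m, a, b) = (1, 0, 1, 1), flat Dirichlet alpha = (1, 1) on pi,
    all-ones Dirichlet concentration on the transition columns, with a
    sticky warm-start concentration (diagonal 20 N) used for the first
    ``warm_sweeps`` sweeps, and 1000 total Gibbs sweeps.
    """

    nu: float = 1.0
    m: float = 0.0
    a: float = 1.0
    b: float = 1.0
    alpha: np.ndarray = field(default_factory=lambda: np.ones(2))
    beta: np.ndarray = field(default_factory=lambda: np.ones((2, 2)))
    beta_warm: np.ndarray | None = None
    warm_sweeps: int = 10
    n_iter: int = 1000
    burn_in: int = 100

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.nu <= 0 or self.a <= 0 or self.b <= 0:
            raise ValidationError("nu, a, b must be strictly positive")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValidationError("alpha and beta must be strictly positive")
        if self.beta_warm is not None:
            self.beta_warm = np.asarray(self.beta_warm, dtype=float)
            if np.any(self.beta_warm <= 0):
                raise ValidationError("beta_warm must be strictly positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValidationError("burn_in must satisfy 0 <= burn_in < n_iter")

    @property
    def K(self) -> int:
        return int(self.alpha.size)

    def warm_beta(self, N: int) -> np.ndarray:
        """Sticky warm-start Dirichlet concentration: diagonal 20 N, off-diagonal 1."""
        if self.beta_warm is not None:
            return self.beta_warm
        B = np.ones((self.K, self.K))
        np.fill_diagonal(B, 20.0 * N)
        return B


@dataclass
class ConjugateUpdate:
    """Updated (posterior) hyperparameters from one conjugate block update."""

    nu_hat: np.ndarray | None = None
    m_hat: np.ndarray | None = None
    a_hat: np.ndarray | None = None
    b_hat: np.ndarray | None = None
    beta_hat: np.ndarray | None = None
    alpha_hat: np.ndarray | None = None


def emission_log_density(x, mu_k: float, lam_k: float):
    """Gaussian emission log-density: (1/2) ln(lam/2pi) - (lam/2)(x - mu)^2."""
    if not lam_k > 0:
        raise ValidationError("precision lam_k must be strictly positive")
    x = np.asarray(x, dtype=float)
    return 0.5 * (np.log(lam_k) - _LOG_2PI) - 0.5 * lam_k * (x - mu_k) ** 2


def emission_sufficient_stats(S: StateSequence, x: np.ndarray):
    """Per-state (count, sum, sum of squares) of assigned observations."""
    x = np.asarray(x, dtype=float)
    if x.size != len(S):
        raise ValidationError("state sequence and trace must have equal length")
    n_k = np.bincount(S.labels, minlength=S.K).astype(float)
    sum_k = np.bincount(S.labels, weights=x, minlength=S.K)
    sumsq_k = np.bincount(S.labels, weights=x * x, minlength=S.K)
    return n_k, sum_k, sumsq_k


def emission_posterior_params(
    S: StateSequence, x: np.ndarray, hp: Hyperparams
) -> ConjugateUpdate:
    """Gauss-Gamma posterior hyperparameters (nu_hat, m_hat, a_hat, b_hat)."""
    n_k, sum_k, sumsq_k = emission_sufficient_stats(S, x)
    nu_hat = n_k + hp.nu
    m_hat = (sum_k + hp.nu * hp.m) / nu_hat
    a_hat = 0.5 * n_k + hp.a
    b_hat = 0.5 * (sumsq_k + hp.nu * hp.m**2 - nu_hat * m_hat**2) + hp.b
    return ConjugateUpdate(nu_hat=nu_hat, m_hat=m_hat, a_hat=a_hat, b_hat=b_hat)


def sample_emission_posterior(
    S: StateSequence, x: np.ndarray, hp: Hyperparams, rng: np.random.Generator
):
    """Draw (mu, lam) from the Gauss-Gamma full conditional.

    lam_k ~ Gamma(shape=a_hat_k, rate=b_hat_k), then
    mu_k | lam_k ~ N(m_hat_k, (nu_hat_k lam_k)^{-1}).
    Returns ``(mu, lam, update)`` with the updated hyperparameters.
    """
    up = emission_posterior_params(S, x, hp)
    if np.any(up.b_hat <= 0):
        k = int(np.argmax(up.b_hat <= 0))
        raise DegenerateDataError(
            f"posterior rate b_hat[{k}] = {up.b_hat[k]!r} <= 0; a constant-valued "
            "state segment collided with the prior"
        )
    lam = rng.gamma(shape=up.a_hat, scale=1.0 / up.b_hat)
    mu = rng.normal(loc=up.m_hat, scale=1.0 / np.sqrt(up.nu_hat * lam))
    return mu, lam, up


def transition_counts(S: StateSequence) -> np.ndarray:
    """C[k, l] = number of observed transitions from state l to state k."""
    lab = S.labels
    flat = np.bincount(lab[1:] * S.K + lab[:-1], minlength=S.K * S.K)
    return flat.reshape(S.K, S.K).astype(float)


def transition_posterior_params(
    S: StateSequence, hp: Hyperparams, warm: bool = False
) -> ConjugateUpdate:
    beta = hp.warm_beta(len(S)) if warm else hp.beta
    return ConjugateUpdate(beta_hat=transition_counts(S) + beta)


def sample_transition_posterior(
    S: StateSequence, hp: Hyperparams, warm: bool, rng: np.random.Generator
):
    """Draw A from its Dirichlet full conditional, column by column.

    Column l of A (destination probabilities out of state l) is an independent
    Dirichlet with concentration ``beta_hat[:, l]`` (transition counts into
    each state from l, plus the prior).  Returns ``(A, update)``.
    """
    if len(S) < 2:
        raise ValidationError("need N >= 2 to update the transition matrix")
    up = transition_posterior_params(S, hp, warm=warm)
    K = S.K
    A = np.empty((K, K))
    for ell in range(K):
        A[:, ell] = rng.dirichlet(up.beta_hat[:, ell])
    return A, up


def sample_initial_posterior(s1: int, hp: Hyperparams, rng: np.random.Generator):
    """Draw pi ~ Dirichlet(alpha + one_hot(s1)).  Returns ``(pi, update)``."""
    if not 0 <= s1 < hp.K:
        raise ValidationError(f"s1 must lie in 0..{hp.K - 1}")
    alpha_hat = hp.alpha.copy()
    alpha_hat[s1] += 1.0
    pi = rng.dirichlet(alpha_hat)
    return pi, ConjugateUpdate(alpha_hat=alpha_hat)


def init_params(
    hp: Hyperparams, x: np.ndarray, rng: np.random.Generator
) -> ModelParams:
    """Initial parameter draw for the Gibbs chain.

    lam, pi and A come from their priors (A uses the sticky warm-start
    concentration so the chain starts in a slowly-switching regime); mu is
    anchored at the 80th (ON) and 20th (OFF) percentiles of the standardized
    trace to break the label symmetry of the mixture.
    """
    x = np.asarray(x, dtype=float)
    K = hp.K
    lam = rng.gamma(shape=hp.a, scale=1.0 / hp.b, size=K)
    # bright state first; for K > 2 spread anchors evenly between the extremes
    qs = np.linspace(80.0, 20.0, K)
    mu = np.percentile(x, qs)
    pi = rng.dirichlet(hp.alpha)
    warm = hp.warm_beta(x.size)
    A = np.empty((K, K))
    for ell in range(K):
        A[:, ell] = rng.dirichlet(warm[:, ell])
    return ModelParams(mu=mu, lam=lam, A=A, pi=pi, standardized=True)
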