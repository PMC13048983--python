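"""Synthetic blinking-trajectory generator.

Emulates the statistical structure of single-molecule fluorescence blinking
data: a two-state (ON/OFF) Markov chain with exponential dwell times, photon
counts accumulated per fixed time bin with Poisson (or rounded Gaussian)
noise, and optionally the underlying photon arrival-time stream at detector
resolution.  The default scenario reproduces the conditions of the DNA-ATTO655
blinking study this package targets: mean dwells 17.6 ms (ON) / 7.8 ms (OFF),
~20 detected photons per 0.5 ms bin in the ON state, and a small nonzero OFF
background.

Discrete-time dwells of the simulated chain are geometric with mean
Delta / (1 - A_kk); the mapping A_kk = 1 - Delta / tau_k is the first-order
discretization of exponential dwells with mean tau_k, and is the generative
inverse of the relaxation-time readout tau_k = Delta / (1 - A_kk) used in the
downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import state_chain_kernel
from .model import ON, OFF, PhotonTrace, StateSequence, ValidationError

#: stated timing resolution of the photon-counting electronics (s)
DETECTOR_TICK = 80e-9


@dataclass
class Scenario:
    """Generative conditions for one synthetic molecule.

    tau_on / tau_off are mean dwell times in seconds (tau_off may be inf for
    a permanently-ON record); mu_on / mu_off are mean counts per bin; delta is
    the bin width and duration the trace length, both in seconds.
    """

    tau_on: float = 17.6e-3
    tau_off: float = 7.8e-3
    mu_on: float = 20.0
    mu_off: float = 1.0
    noise_model: str = "poisson"
    gaussian_sd_on: float = 0.0
    gaussian_sd_off: float = 0.0
    delta: float = 0.5e-3
    duration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("poisson", "gaussian"):
            raise ValidationError(
                f"noise_model must be 'poisson' or 'gaussian', got {self.noise_model!r}"
            )
        if not (self.tau_on > self.delta and self.tau_off > self.delta):
            raise ValidationError("mean dwells must exceed the bin width delta")
        if math.isinf(self.tau_on) and math.isinf(self.tau_off):
            raise ValidationError("at most one dwell mean may be infinite")
        if not self.mu_on > self.mu_off:
            raise ValidationError("mu_on must exceed mu_off")
        if self.mu_off < 0:
            raise ValidationError("mean counts must be nonnegative")
        if self.delta <= 0 or self.duration <= 0:
            raise ValidationError("delta and duration must be positive")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.delta))

    def transition_matrix(self) -> np.ndarray:
        """Column-stochastic A with A_kk = 1 - delta / tau_k."""
        p_off = self.delta / self.tau_on if math.isfinite(self.tau_on) else 0.0
        p_on = self.delta / self.tau_off if math.isfinite(self.tau_off) else 0.0
        A = np.empty((2, 2))
        A[ON, ON], A[OFF, ON] = 1.0 - p_off, p_off
        A[ON, OFF], A[OFF, OFF] = p_on, 1.0 - p_on
        return A

    def stationary_pi(self) -> np.ndarray:
        """Stationary occupancy: pi_ON = tau_on / (tau_on + tau_off).

        An infinite dwell mean makes that state absorbing and it carries all
        the stationary mass.
        """
        if math.isinf(self.tau_on):
            return np.array([1.0, 0.0])
        if math.isinf(self.tau_off):
            return np.array([0.0, 1.0])
        p = self.tau_on / (self.tau_on + self.tau_off)
        return np.array([p, 1.0 - p])

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class ArrivalRecord:
    """Photon arrival times (s), strictly increasing, quantized to a tick."""

    times: np.ndarray
    resolution: float = DETECTOR_TICK
    duration: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (
            self.times[0] < 0 or self.times[-1] >= self.duration
        ):
            raise ValidationError("arrival times must lie in [0, duration)")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("arrival times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


def default_scenario(**overrides) -> Scenario:
    """Reference blinking conditions: tau_on = 17.6 ms, tau_off = 7.8 ms,
    mu_on = 20 counts per 0.5 ms bin, Poisson noise, 5 s trace.

    The OFF-state mean count is not constrained by the source measurements;
    the default of 1 count/bin is a placeholder standing in for the nonzero
    background seen in real traces.
    """
    return replace(Scenario(), **overrides)


def simulate_state_chain(
    A: np.ndarray,
    pi: np.ndarray,
    n_bins: int,
    seed: int | np.random.Generator = 0,
) -> StateSequence:
    """Simulate a hidden Markov label chain of length ``n_bins``.

    ``A`` must be column-stochastic (columns sum to 1): A[k, l] is the
    probability of moving to state k from state l.
    """
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("A must be square")
    colsums = A.sum(axis=0)
    bad = np.where(np.abs(colsums - 1.0) > 1e-12)[0]
    if bad.size:
        raise ValidationError(
            f"column {bad[0]} of A sums to {colsums[bad[0]]!r}, expected 1"
        )
    if abs(pi.sum() - 1.0) > 1e-12 or np.any(pi < 0):
        raise ValidationError("pi must be a probability vector summing to 1")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n_bins)
    labels = np.empty(n_bins, dtype=np.int64)
    state_chain_kernel(A, pi, u, labels)
    return StateSequence(labels=labels, K=pi.size)


def simulate_trace(
    states: StateSequence,
    scenario: Scenario,
    rng: np.random.Generator | None = None,
) -> PhotonTrace:
    """Draw per-bin photon counts given a hidden state chain.

    Poisson noise draws counts from Poisson(mu_state); Gaussian noise draws
    from N(mu_state, sd_state^2), rounds to the nearest integer and clips at
    zero so the output is always valid count data.
    """
    if len(states) != scenario.n_bins:
        raise ValidationError(
            f"state chain length {len(states)} does not match "
            f"duration/delta = {scenario.n_bins} bins"
        )
    rng = rng if rng is not None else scenario.rng()
    mu = np.array([scenario.mu_on, scenario.mu_off])[states.labels]
    if scenario.noise_model == "poisson":
        counts = rng.poisson(mu)
    else:
        sd = np.array([scenario.gaussian_sd_on, scenario.gaussian_sd_off])
        counts = np.rint(rng.normal(mu, sd[states.labels]))
        counts = np.clip(counts, 0, None).astype(np.int64)
    return PhotonTrace(counts=counts, delta=scenario.delta)


def simulate_molecule(
    scenario: Scenario, rng: np.random.Generator | None = None
):
    """Convenience: chain + counts for one molecule.  Returns (states, trace)."""
    rng = rng if rng is not None else scenario.rng()
    states = simulate_state_chain(
        scenario.transition_matrix(), scenario.stationary_pi(),
        scenario.n_bins, rng,
    )
    trace = simulate_trace(states, scenario, rng)
    return states, trace


def simulate_arrivals(
    scenario: Scenario,
    rng: np.random.Generator | None = None,
    resolution: float = DETECTOR_TICK,
) -> ArrivalRecord:
    """Simulate the photon arrival-time stream of a blinking molecule.

    The emission is a rate-switching Poisson process: state dwell times are
    exponential with means tau_on / tau_off, and within a dwell photons
    arrive homogeneously at rate mu_state / delta.  Arrival times are
    quantized down to the detector tick; coincident ticks are collapsed to
    one event (a detector registers at most one photon per tick).
    """
    rng = rng if rng is not None else scenario.rng()
    rates = (scenario.mu_on / scenario.delta, scenario.mu_off / scenario.delta)
    means = (scenario.tau_on, scenario.tau_off)
    T = scenario.duration

    state = ON if rng.random() < scenario.stationary_pi()[ON] else OFF
    t = 0.0
    chunks = []
    while t < T:
        tau = means[state]
        dwell = rng.exponential(tau) if math.isfinite(tau) else T - t
        end = min(t + dwell, T)
        rate = rates[state]
        if rate > 0 and end > t:
            n = rng.poisson(rate * (end - t))
            if n:
                chunks.append(np.sort(rng.uniform(t, end, size=n)))
        t = end
        state = OFF if state == ON else ON

    if chunks:
        times = np.concatenate(chunks)
        if resolution > 0:
            times = np.unique(np.floor(times / resolution) * resolution)
        times = times[times < T]
    else:
        times = np.empty(0)
    return ArrivalRecord(times=times, resolution=resolution, duration=T)
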