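"""Trajectory-level tools: standardization, photon-count histograms, the
two-Gaussian model histogram, rebinning across bin widths, a quantitative
bimodality classification, and the mean-variance (Poisson) diagnostic.

The photon-count histogram h(n) is the central reliability diagnostic of the
Gaussian-emission HMM: a bimodal h(n) means the ON and OFF emission levels
are separable and state inference is stable; a unimodal h(n) signals the
identifiability limit where inferred state sequences become noisy.  Because
the histogram shape depends on the bin width Delta, ``rebin`` reconstructs
traces at coarser Delta (exactly, from counts, or from raw arrival times),
conserving the total photon number up to a dropped trailing partial window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OFF, ON, PhotonTrace, ValidationError
from .simulate import ArrivalRecord

#: constant emission baseline of the approximate surrogate objective,
#: -(1 + ln 2 pi)/2 nats/sample, for a standardized (unit-variance) trace
BASELINE_NATS = -0.5 * (1.0 + np.log(2.0 * np.pi))


@dataclass
class CountHistogram:
    """Occurrence counts h(n) of the per-bin photon count n."""

    support: np.ndarray          # n = 0 .. n_max
    h: np.ndarray                # occurrence counts, same length
    delta: float

    @property
    def n_events(self) -> int:
        """Total number of photon-counting events N_eve = sum_n h(n)."""
        return int(self.h.sum())

    @property
    def total_photons(self) -> int:
        return int((self.support * self.h).sum())


@dataclass
class ModelHistogram:
    """Two-Gaussian model of the photon-count histogram.

    h_model(n) = N_eve [ w_ON N(n | mu_ON, 1/lam_ON) + w_OFF N(n | mu_OFF, 1/lam_OFF) ]
    with the weights given by the mean ON/OFF occupancies of the inferred
    hidden sequence.
    """

    support: np.ndarray
    h_model: np.ndarray
    w_on: float
    w_off: float
    mu_on: float
    mu_off: float
    lam_on: float
    lam_off: float
    n_events: int

    @property
    def sigma_on(self) -> float:
        return 1.0 / np.sqrt(self.lam_on)

    @property
    def sigma_off(self) -> float:
        return 1.0 / np.sqrt(self.lam_off)


def standardize(trace: PhotonTrace | np.ndarray):
    """Standardize counts to zero mean, unit (population) variance.

    Returns ``(x, mean, sd)``.  The inverse map for fitted parameters is
    mu_raw = mu * sd + mean and sigma^2_raw = sd^2 / lam.
    """
    counts = trace.counts if isinstance(trace, PhotonTrace) else np.asarray(trace)
    counts = counts.astype(float)
    mean = counts.mean()
    sd = counts.std()          # population sd: "unit variance" of the series
    if sd == 0:
        raise ValidationError(
            "trace has zero spread; standardization (and fitting) is undefined"
        )
    return (counts - mean) / sd, float(mean), float(sd)


def destandardize_params(mu_std, lam_std, mean: float, sd: float):
    """Map standardized (mu, lam) back to counts/bin: mu*sd+mean, var = sd^2/lam."""
    mu = np.asarray(mu_std) * sd + mean
    var = sd**2 / np.asarray(lam_std)
    return mu, var


def count_histogram(trace: PhotonTrace) -> CountHistogram:
    """Exact tally h(n) of integer per-bin photon counts."""
    counts = np.asarray(trace.counts).astype(np.int64)
    h = np.bincount(counts)
    return CountHistogram(support=np.arange(h.size), h=h, delta=trace.delta)


def model_histogram(
    summary, hist: CountHistogram, support: np.ndarray | None = None
) -> ModelHistogram:
    """Evaluate the two-Gaussian model histogram from a fit summary.

    ``summary`` must expose de-standardized emission parameters
    (``mu_counts``, ``var_counts`` indexed ON, OFF) and occupancy weights
    ``w`` (per-bin ON/OFF frequencies of the inferred hidden sequence).
    """
    w_on, w_off = float(summary.w[ON]), float(summary.w[OFF])
    if abs(w_on + w_off - 1.0) > 1e-9:
        raise ValidationError(f"weights sum to {w_on + w_off!r}, expected 1")
    mu = np.asarray(summary.mu_counts, dtype=float)
    var = np.asarray(summary.var_counts, dtype=float)
    lam = 1.0 / var
    n = np.asarray(support if support is not None else hist.support, dtype=float)
    dens = (
        w_on * np.sqrt(lam[ON] / (2 * np.pi)) * np.exp(-0.5 * lam[ON] * (n - mu[ON]) ** 2)
        + w_off * np.sqrt(lam[OFF] / (2 * np.pi)) * np.exp(-0.5 * lam[OFF] * (n - mu[OFF]) ** 2)
    )
    return ModelHistogram(
        support=n,
        h_model=hist.n_events * dens,
        w_on=w_on,
        w_off=w_off,
        mu_on=float(mu[ON]),
        mu_off=float(mu[OFF]),
        lam_on=float(lam[ON]),
        lam_off=float(lam[OFF]),
        n_events=hist.n_events,
    )


def rebin(source, new_delta: float, delta: float | None = None) -> PhotonTrace:
    """Reconstruct a photon-count trace at a coarser bin width.

    From a :class:`PhotonTrace` (or a counts array plus ``delta``),
    ``new_delta`` must be an integer multiple of the original bin width and
    consecutive windows are summed.  From an :class:`ArrivalRecord` any
    ``new_delta > 0`` is allowed and photons are tallied directly.  In both
    cases a trailing partial window is dropped, so total photons are conserved
    up to the dropped remainder.
    """
    if new_delta <= 0:
        raise ValidationError("new_delta must be positive")
    if isinstance(source, ArrivalRecord):
        n_bins = int(np.floor(source.duration / new_delta + 1e-9))
        if n_bins < 1:
            raise ValidationError("record shorter than one bin of new_delta")
        idx = np.floor(source.times / new_delta).astype(np.int64)
        counts = np.bincount(idx[idx < n_bins], minlength=n_bins)
        return PhotonTrace(counts=counts, delta=new_delta)

    if isinstance(source, PhotonTrace):
        counts, delta = np.asarray(source.counts), source.delta
    else:
        if delta is None:
            raise ValidationError("delta required when rebinning a bare counts array")
        counts = np.asarray(source)
    factor = new_delta / delta
    if abs(factor - round(factor)) > 1e-9:
        raise ValidationError(
            f"new_delta = {new_delta} is not an integer multiple of delta = {delta}; "
            "rebin from the photon arrival record instead"
        )
    factor = int(round(factor))
    n_full = counts.size // factor
    if n_full < 1:
        raise ValidationError(
            f"record of {counts.size} bins is shorter than one bin of "
            f"new_delta = {new_delta}"
        )
    rebinned = counts[: n_full * factor].reshape(n_full, factor).sum(axis=1)
    return PhotonTrace(counts=rebinned, delta=new_delta)


def separation_score(mu_on, mu_off, sigma_on, sigma_off) -> float:
    """Component separation d = (mu_ON - mu_OFF) / (sigma_ON + sigma_OFF)."""
    return float((mu_on - mu_off) / (sigma_on + sigma_off))


def bimodality_report(mh: ModelHistogram):
    """Classify the fitted histogram shape from the separation score.

    d >= 1 -> 'bimodal' (boundary inclusive), 0.5 <= d < 1 -> 'shoulder',
    d < 0.5 -> 'unimodal'.  Returns ``(classification, d)``.
    """
    d = separation_score(mh.mu_on, mh.mu_off, mh.sigma_on, mh.sigma_off)
    if d >= 1.0:
        label = "bimodal"
    elif d >= 0.5:
        label = "shoulder"
    else:
        label = "unimodal"
    return label, d


def qc_flag(classification: str, mean_objective: float):
    """Trajectory quality-control rule.

    A dataset is flagged (not dropped) when the fitted histogram is unimodal
    or the post-burn-in mean surrogate objective falls below the standardized
    emission baseline ``BASELINE_NATS``.  Returns ``(flagged, reasons)``.
    """
    reasons = []
    if classification == "unimodal":
        reasons.append("unimodal photon-count histogram")
    if mean_objective < BASELINE_NATS:
        reasons.append(
            f"mean objective {mean_objective:.4f} below baseline {BASELINE_NATS:.4f}"
        )
    return bool(reasons), reasons


def mean_variance_table(summaries, molecule_ids=None) -> pd.DataFrame:
    """Per-molecule, per-state table of inferred (mu, sigma^2) in counts/bin.

    The ratio column sigma^2 / mu measures deviation from Poisson photon
    statistics (ratio 1); rows with ratio outside [0.5, 2] or mu <= 0 are
    flagged, never dropped.
    """
    rows = []
    for i, s in enumerate(summaries):
        mol = molecule_ids[i] if molecule_ids is not None else getattr(
            s, "molecule_id", str(i)
        )
        for state, name in ((ON, "ON"), (OFF, "OFF")):
            mu = float(np.asarray(s.mu_counts)[state])
            var = float(np.asarray(s.var_counts)[state])
            ratio = var / mu if mu > 0 else np.nan
            flagged = mu <= 0 or not (0.5 <= ratio <= 2.0)
            rows.append(
                {"molecule_id": mol, "state": name, "mu": mu, "var": var,
                 "ratio": ratio, "flag": bool(flagged)}
            )
    return pd.DataFrame(rows, columns=["molecule_id", "state", "mu", "var", "ratio", "flag"])
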