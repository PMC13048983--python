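# blinkhmm

Bayesian hidden Markov analysis of single-molecule fluorescence blinking.

Under continuous excitation a surface-tethered fluorophore (e.g. ATTO655
conjugated to a DNA duplex) alternates between an emitting ON state and a
dark OFF state created by photoinduced charge separation.  The photon-count
trajectory — detected photons accumulated in fixed time bins Δ (typically
0.5 ms) — is a noisy two-state telegraph signal, and the quantities of
interest are the dwell-time distributions of the two states: the OFF-dwell
scale measures the lifetime of the charge-separated state, the ON-dwell
scale the stability of the emitting state.  `blinkhmm` is for experimentalists
and modelers who need to turn such trajectories into reliable ON/OFF dwell
statistics when shot noise and background make simple thresholding
unreliable.

## Model

The counts I = (I₁…I_N), standardized to zero mean and unit variance, follow
a K = 2 state Gaussian-emission HMM

- emission: Iₙ | sₙ = k ~ 𝒩(μ_k, λ_k⁻¹)  (Gaussian approximation to Poisson
  counting at ~20 photons/bin),
- hidden chain: s₁ ~ Cat(π), sₙ | sₙ₋₁ = ℓ ~ Cat(A·ℓ) with column-stochastic
  A (A_{kℓ} = P(k at n | ℓ at n−1)),
- conjugate priors: Gauss-Gamma 𝒩𝒢(μ_k, λ_k | m, ν, a, b) on each emission
  pair, Dirichlet on π and on each column of A.

Inference is blocked Gibbs sampling.  Each sweep draws the **entire** hidden
path S from its exact conditional by forward-filtered backward sampling
(FFBS): a normalized forward recursion
f_{kn} ∝ 𝒩(Iₙ|μ_k, λ_k⁻¹) Σ_ℓ A_{kℓ} f_{ℓ,n−1}, then backward categorical
draws with weights η_{kn} ∝ f_{kn} A_{ℓk} (ℓ the sampled state at n+1).  The
parameter blocks then follow from their closed-form conditionals
(Gauss-Gamma and Dirichlet updates).  A sticky transition prior (diagonal
concentration 20 N) stabilizes the first 10 sweeps.  A per-sweep surrogate
objective ℒ (nats/sample) monitors convergence against the constant
emission baseline −(1 + ln 2π)/2 = −1.4189.

From the fitted chains the package computes dwell-time densities
p(τ_k) = n_k/(N_e Δτ), exponential decay constants from
p(τ) = (1/s) e^{−τ/s} (MLE or histogram least squares), the independent
transition-matrix readout τ_k = Δ/(1 − Ā_kk), photon-count histogram
diagnostics h(n) vs the two-Gaussian model h_model(n), a quantitative
bimodality score d = (μ_ON − μ_OFF)/(σ_ON + σ_OFF), and the mean–variance
(Poisson σ² ≈ μ) table across molecules.

Because typical experimental trajectories of this kind are not publicly
deposited, the package ships a first-class synthetic generator
(`blinkhmm.simulate`) reproducing the reference study conditions: mean
dwells 17.6 ms (ON) / 7.8 ms (OFF), ~20 Poisson counts per 0.5 ms ON bin,
near-zero OFF background, optional photon arrival streams at 80 ns detector
resolution.

## Worked example

```python
import blinkhmm as bh

scenario = bh.default_scenario(duration=5.0, seed=42)   # 10,000 bins of 0.5 ms
states, trace = bh.simulate_molecule(scenario)
fit = bh.gibbs_fit(trace, bh.Hyperparams(), rng=42)     # 1000 sweeps, burn-in 100
s = fit.summary

d_on, d_off = bh.extract_dwells(s.state_marginals, trace.delta)
fit_on, fit_off = bh.fit_exponential(d_on), bh.fit_exponential(d_off)
tau_on, tau_off = bh.relaxation_from_transition(s.A_bar, trace.delta)
```

This prints (formatting as in `examples` of the docstrings):

```text
mu_ON  = 20.02 counts/bin   sigma^2_ON  = 20.70
mu_OFF = 1.00 counts/bin   sigma^2_OFF = 1.05
A_ON,ON = 0.9692   A_OFF,OFF = 0.9402
s_ON  = 16.27 +/- 1.14 ms  (N_e = 203)
s_OFF = 8.32 +/- 0.58 ms  (N_e = 204)
tau_ON = 16.23 ms   tau_OFF = 8.36 ms
histogram: bimodal (separation d = 3.41),  mean L = -0.3001 nats/sample
```

Reading the output: the emission means recover the generating brightness
(20 and 1 counts/bin) with near-Poisson variances (σ² ≈ μ); the exponential
dwell fits (16.3 / 8.3 ms from one 5 s trace, standard errors ~1 ms) and the
transition-matrix readout agree with each other and with the generating
dwell means (17.6 / 7.8 ms) within the sampling error of ~200 dwell events;
the bimodal histogram (d ≥ 1) and ℒ above the −1.4189 baseline mark the fit
as reliable.

A command-line interface wraps the same pipeline:

```bash
blinkhmm simulate --n-molecules 5 --duration 5.0 --seed 1 --outdir sim
blinkhmm report --input sim/mol000.csv --input sim/mol001.csv \
    --input sim/mol002.csv --seed 1 --outdir analysis
```

## Layout

- `blinkhmm.model` — types, emission density, conjugate posterior updates
- `blinkhmm.gibbs` — forward filter, backward sampler, the Gibbs loop,
  surrogate objective, posterior summaries
- `blinkhmm.dwell` — dwell extraction, blinking plots, exponential and
  transition-matrix relaxation estimates
- `blinkhmm.trace` — standardization, histograms, rebinning, bimodality,
  mean–variance diagnostics
- `blinkhmm.simulate` — synthetic chains, traces and photon arrival streams
- `blinkhmm.io` / `blinkhmm.cli` — file formats, run configs, pipeline, CLI

See `docs/methods.md` for the full model description, parameter defaults,
numerical choices and known limitations.
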