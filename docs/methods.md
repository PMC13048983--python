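# Methods

## Model

A photon-count trajectory is a sequence I = (I₁…I_N) of nonnegative integer
counts, one per time bin of width Δ (seconds).  Before fitting, the counts
are standardized to zero mean and unit variance using the population
standard deviation of the realized series; all emission parameters are
inferred on that scale and de-standardized (μ_raw = μ·sd + mean,
σ²_raw = sd²/λ) for reporting in counts/bin.

The generative model is a K-state hidden Markov model with Gaussian
emissions.  The hidden state sₙ at bin n is categorical (one-hot semantics;
internally an integer label, with index 0 = ON and 1 = OFF after ordering).
Emission: Iₙ | sₙ = k ~ 𝒩(μ_k, λ_k⁻¹), where λ_k is the precision
(inverse variance).  The Gaussian form is the central-limit approximation to
Poisson photon counting, adequate when the ON count per bin is ~10 or more;
it is the reason bin widths that are too small (counts piled near zero)
degrade inference.  The hidden chain has initial distribution π and a
column-stochastic transition matrix A: A[k, ℓ] = P(state k at n | state ℓ
at n−1), so columns are the conditional distributions and must sum to 1.
Dirichlet priors are therefore applied per column of A; this orientation is
forced by the transition kernel's role as a conditional distribution, and
the posterior update β̂_{kℓ} = Σₙ s_{kn} s_{ℓ,n−1} + β_{kℓ} counts
transitions *into* k *out of* ℓ, grouping naturally by column.

Priors are fully conjugate:

- (μ_k, λ_k) ~ Gauss-Gamma 𝒩𝒢(m, ν, a, b): λ_k ~ Gamma(shape a, rate b),
  μ_k | λ_k ~ 𝒩(m, (νλ_k)⁻¹).  The Gamma is parameterized shape–rate
  (density ∝ λ^{a−1} e^{−bλ}).
- π ~ Dirichlet(α); each column of A ~ Dirichlet(β column).

## Sampler

One blocked Gibbs sweep draws, in order:

1. **S | θ, I** by forward-filtered backward sampling.  The forward pass
   computes per-step-normalized weights
   f_{kn} ∝ 𝒩(Iₙ|μ_k, λ_k⁻¹) Σ_ℓ A_{kℓ} f_{ℓ,n−1} (initialization
   f_{k1} ∝ π_k 𝒩(I₁|·)), storing each step's log normalizer so the
   unnormalized forward probability — and hence the marginal likelihood —
   stays recoverable.  Without per-step normalization the recursion
   underflows for N ≳ 10³; normalization leaves the backward draw unchanged
   because the sampling weights η_{kn} ∝ f_{kn} A_{ℓk} are scale-invariant
   in f.  Per-step emission log-densities are max-shifted before
   exponentiation.  The backward pass samples s_N from the final filter
   row, then s_n | s_{n+1} = ℓ from η.  The backward message b(sₙ) is never
   materialized: the conditional p(sₙ | sₙ₊₁, I) depends only on f and A.
2. **(μ, λ) | S, I** from the Gauss-Gamma conditional: ν̂_k = n_k + ν,
   m̂_k = (Σ s_{kn} Iₙ + νm)/ν̂_k, â_k = n_k/2 + a,
   b̂_k = ½(Σ s_{kn} Iₙ² + νm² − ν̂_k m̂_k²) + b, with λ_k drawn first and
   μ_k | λ_k second.  In exact arithmetic b̂_k − b is a sum of squares, so
   b̂_k > 0 always; a guard raises a degeneracy error if catastrophic
   cancellation ever produces b̂_k ≤ 0.
3. **π | S** from Dirichlet(α + one-hot(s₁)).
4. **A | S** from per-column Dirichlets with concentration β̂.  For the
   first `warm_sweeps` sweeps the concentration is the sticky warm-start
   matrix (below); afterwards the flat all-ones prior.

The per-sweep surrogate objective (nats/sample)
ℒ = (1/N)[Σ emission log-densities + ln π_{s₁} + Σ ln A transitions] is
recorded with its three components for convergence monitoring, never for
stopping.  Its stationary approximation
ℒ ≈ ½ Σ_k w_k ln λ_k − ½(1 + ln 2π) + Σ_ℓ w_ℓ Σ_k A_{kℓ} ln A_{kℓ}
(w_k the state occupancies) carries the constant emission baseline
−(1 + ln 2π)/2 = −1.4189 for a unit-variance trace, a useful reference
line: fits whose post-burn-in mean ℒ sits below it are flagged by QC.

### Initialization and label handling

λ⁽⁰⁾, π⁽⁰⁾ and A⁽⁰⁾ are drawn from their priors (A from the warm-start
concentration).  μ⁽⁰⁾ is anchored at the 80th (ON) and 20th (OFF)
percentiles of the standardized trace rather than drawn from the prior:
with m = 0 for both components a prior draw makes the mixture exchangeable
and symmetry breaking slow.  The sampler itself runs unconstrained (the
posterior is label-exchangeable); when a sweep is recorded, components are
ordered so that μ_ON > μ_OFF — the ON state is by definition the bright
one — and the stored label sequence is permuted to match.  This ordering
never feeds back into the sampler state.  Oscillation of the ordering after
burn-in (more than two switches) triggers a warning, as it indicates the
two components are not resolved.

### Defaults

| parameter | default | meaning |
|---|---|---|
| (ν, m, a, b) | (1, 0, 1, 1) | Gauss-Gamma prior on each (μ_k, λ_k), standardized units |
| α | (1, 1) | flat Dirichlet on π |
| β | all ones | flat Dirichlet on each column of A |
| warm β | diag 20 N, off-diag 1 | sticky start; switched off after 10 sweeps |
| n_iter | 1000 | Gibbs sweeps (fixed; convergence monitored, not enforced) |
| burn_in | 100 | sweeps discarded from posterior averages (configurable) |
| Δτ | 1 ms | dwell-histogram grid spacing |
| Δ | 0.5 ms | time-bin width of the reference conditions |

The burn-in of 100/1000 is a package choice: the objective typically
stabilizes within 20–30 sweeps, but the sticky warm start can take a few
hundred sweeps to relax on *unresolvable* data, and 100 sweeps costs little.

## Dwell statistics

Maximal runs of constant state become dwells of duration (run bins)×Δ.
When the input is a per-bin posterior ON frequency rather than a hard
sequence, it is binarized at 0.5 with exact ties resolved to OFF
(conservative against false ON events).  Boundary runs (first and last,
truncated by the observation window) are included by default; a censor
policy drops them.  The duration histogram uses half-open bins
[τ_{k−1}, τ_k) on the grid τ_k = kΔτ and is normalized so
Σ p(τ_k)Δτ = 1.  The exponential decay constant s of
p(τ) = (1/s)e^{−τ/s} is estimated by MLE — the sample mean, which is the
unique maximum-likelihood estimator for an exponential density, with
standard error s/√N_e — or by least squares of the closed form against the
histogram density; MLE is the default and both are reported by the
pipeline.  The independent readout from the chain itself is
τ_k = Δ/(1 − Ā_kk) with Ā the posterior-mean transition matrix; a unit
diagonal yields an infinite dwell reported as a flagged sentinel.  Dwells
of 1–2 bins are systematically under-detected by any binned analysis;
durations are reliable only above ≈ 3Δ.

## Histogram diagnostics

The photon-count histogram h(n) is compared with the two-Gaussian model
h_model(n) = N_eve [w_ON 𝒩(n|μ_ON, λ_ON⁻¹) + w_OFF 𝒩(n|μ_OFF, λ_OFF⁻¹)],
with weights w = ⟨N_state⟩/N from the inferred hidden sequence.  Shape is
classified by the separation score d = (μ_ON − μ_OFF)/(σ_ON + σ_OFF):
bimodal for d ≥ 1 (boundary inclusive), shoulder for 0.5 ≤ d < 1, unimodal
below — a reproducible stand-in for the visual judgement the field
traditionally applies.  Rebinning to coarser Δ (exactly from counts by an
integer factor, or from raw arrival times at any Δ, dropping a trailing
partial window so total photons are conserved up to the remainder) shifts
the histogram to larger counts and can create bimodality at the cost of
erasing dwells shorter than the new Δ.  The QC rule flags (never drops) a
dataset whose fitted histogram is unimodal or whose post-burn-in mean ℒ
falls below −1.4189.

## Synthetic data

The generator emulates the reference measurement conditions: a two-state
Markov chain with A_kk = 1 − Δ/τ_k (the first-order discretization of
exponential dwells, and exactly the generative inverse of the
τ = Δ/(1 − A_kk) readout; discrete-time dwells are geometric with mean
τ_k/Δ bins), stationary initial occupancy τ_on/(τ_on + τ_off), and per-bin
counts that are Poisson(μ_state) or rounded, zero-clipped Gaussians.
Defaults: τ_on = 17.6 ms, τ_off = 7.8 ms, μ_ON = 20 counts per Δ = 0.5 ms
bin, 5 s traces.  μ_OFF = 1 count/bin is a placeholder — the real OFF
background level is not constrained by the source measurements — chosen
nonzero so the OFF state never has exactly zero variance.  Photon arrival
streams are rate-switching Poisson processes (exponential dwells, uniform
arrivals within a dwell at rate μ/Δ), quantized down to the 80 ns detector
tick with coincident ticks collapsed; one dwell mean may be infinite to
emulate a single-state record.

What the generator does **not** emulate: triplet shelving, photobleaching,
power-law blinking, focal drift, background non-stationarity, or detector
afterpulsing.  Passing tests on this generator therefore demonstrate
correctness of the inference machinery under the model's own assumptions
(plus Poisson instead of Gaussian noise), not robustness to every artifact
of real traces.

## Numerical choices

- Population (not sample) standard deviation in standardization.
- Forward filter normalized per step, log normalizers stored; zero total
  weight (possible only with structural zeros in A or π) raises an error
  naming the bin.
- Degenerate traces (zero spread) are refused at fit time.
- Rebinning drops the trailing partial window rather than rescaling it, so
  all bins stay identically distributed.
- Consensus state sequence: per-bin majority across post-burn-in sweeps,
  exact 50% ties to OFF.
- All randomness flows through a single numpy Generator; the jitted kernels
  consume pre-drawn uniforms, so runs are bitwise reproducible per seed.

## Problem sizes

The test suite fits 5 s traces (N = 10⁴ bins) with 1000 sweeps — about a
second per molecule with the compiled kernels — and uses 20-replicate
ensembles for recovery checks; exhaustive-enumeration oracles run at
N ≤ 8.  The acceptance script uses a 12-molecule × 6 s ensemble, which
pools ≈ 2,800 dwell events per state, comparable to a realistic pooled
single-molecule dataset.

## Known limitations

- **Prior shrinkage of the OFF precision.**  With counts standardized to
  unit variance, a dim OFF state has tiny variance on the standardized
  scale (≈ 0.011 under the defaults), i.e. λ_OFF ≈ 90.  The Gamma(1, 1)
  prior rate is then not negligible against the data term ½Σ s I² ≈ 17 of
  b̂, and the posterior mean of λ_OFF sits several posterior SDs below the
  generating value (the OFF variance is over-estimated by ~5–10%).  This
  is a property of the default prior at these scales, not of the sampler:
  the exact conjugate posterior computed with the true labels shows the
  same offset.  μ, A, occupancies and dwell statistics are unaffected.  If
  an unbiased OFF variance matters, use a weaker precision prior
  (smaller b) or a prior scaled to the standardized OFF variance.
- The Gaussian emission model mismatches Poisson counts at low means; with
  μ_OFF ~ 1 the OFF histogram is visibly skew and the model histogram
  deviates from h(n) there even for a perfect fit.
- At the identifiability limit (μ_ON ≈ μ_OFF) the sampled state sequences
  approach independent per-bin switching; the mean sampled dwell then
  approaches 1/(2w(1−w)) ≥ 2 bins and dwell statistics carry no
  information.  The QC flag marks this regime.
- Dwells shorter than ≈ 3Δ are under-detected; decay constants comparable
  to Δ cannot be recovered by a binned analysis regardless of sampler
  quality.
- K > 2 is structurally supported (all types are K-generic) but no model
  selection over K is provided, and the ON/OFF labelling logic assumes the
  brightest-versus-rest distinction that only K = 2 makes canonical.
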