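# Methods

## Model

Presynaptic ATP is tracked in relative units: the resting level is 1, so
the production constant equals the basal consumption rate γ_b and the
balance during the *i*-th sustained stimulation train is

    da/dt = γ_b(1 − a) − γ_i(t)·a,    a(0) = a₀.

The model is a scalar linear ODE; for a constant activity rate γ₁ and a
resting start (first train) it has the closed form
a(t) = [1 + (γ₁/γ_b)e^{−(γ₁+γ_b)t}] / (1 + γ₁/γ_b), decaying to the
steady state 1/(1 + γ₁/γ_b). Transmission failures are Bernoulli per
stimulus with probability given by a Hill function of the instantaneous
ATP level, F(a) = 100/(1 + (a/K)^h) percent: F(K) = 50 exactly, F is
strictly decreasing in a, and F(1) is negligible for the fitted
parameters, so a rested terminal transmits reliably.

Assumptions worth stating plainly:

- **No absolute concentrations.** Only relative ATP is identifiable from
  failure data; K is carried as a fraction of basal (K_rel ∈ (0, 1)).
  The failure rate is invariant under common rescaling of ATP and K
  (property-tested).
- **No inter-train recovery kinetics.** Each train's initial ATP a₀ is a
  free parameter rather than the output of a recovery model; the data
  between trains (rest periods) are not modeled.
- **Phenomenological demand growth.** For trains 2 and 3 the consumption
  rate climbs sigmoidally from γ₁ toward γ_iᵐᵃˣ with half-time K_i (s)
  and steepness h_i. γ_i(0) = γ₁ by construction. This is a descriptive
  form, not a mechanism.
- **Failures are conditionally independent** given the ATP trajectory
  (no refractoriness or bursting in the failure process itself).

## Parameters and defaults

| parameter | meaning | unit | default / preset |
|---|---|---|---|
| γ_b | basal consumption | s⁻¹ | 0.0065 |
| γ₁ | activity consumption, train 1 | s⁻¹ | 0.11 (≈17× γ_b) |
| h | Hill cooperativity | – | 6 |
| K_rel | half-failure ATP | fraction of basal | 0.046 |
| a₀ (train 2, 3) | onset ATP | fraction of basal | 0.10, 0.047 |
| end demand (train 2, 3) | γ_i(150 s)/γ₁ | – | 1.26, 1.40 |
| h_i, K_i | demand sigmoid shape | –, s | 4, 75 |

The sigmoid shape parameters (h_i, K_i) are a generator choice — the
half-time sits at the midpoint of the 150-s train with moderate
steepness — because only the onset ATP and the end-of-train demand ratio
are constrained quantities; γ_iᵐᵃˣ is then solved so that γ_i(150 s)
matches the stated end-of-train ratio exactly
(`gamma_max_for_end_ratio`).

## Fitting

The observable per train is the OxPhos-dependent failure percentage:
control success minus OxPhos-blocked success on matched 25-stimulus bins
(0.25 s at 100 Hz, timestamped at bin centers), clamped to [0, 100] —
bins where the blocked condition nominally outperforms control are
sampling noise and clamp to zero (logged).

Estimation is sequential bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective):

1. **Train 1** fits (γ_b, γ₁, h, K_rel) with the closed-form prediction
   (equivalent to the ODE for constant rate; equivalence ≤ 10⁻⁶ relative
   is an acceptance-tested invariant).
2. **Trains 2 and 3** fit (a₀, γᵐᵃˣ, h_i, K_i) with the shared
   parameters frozen and the ODE integrated numerically (LSODA,
   rtol 10⁻⁹, atol 10⁻¹²).

Each fit restarts from log-uniformly perturbed initial guesses (default
20 starts, ×3 span, seeded); the best SSE wins and the spread of
estimates across converged starts is reported as an identifiability
diagnostic. Bounds are wide but physical (rates ≤ 10 s⁻¹, h ∈ [0.5, 20],
K_rel ≤ 0.5). The onset-ATP guess for later trains inverts the Hill
function at the first observed bin. Degenerate inputs: an identically
zero failure series raises an unidentifiability error (nothing
constrains h or K); a train whose demand never grows collapses the
sigmoid to the constant rate and is recovered as such.

`fit_diagnostics` adds per-parameter 1-D SSE sweeps (others held fixed) —
a cheap profile-likelihood-style picture of which parameters the data
actually pin down.

## Identifiability under realistic sampling noise

Noise-free self-generated curves return every parameter to ≤ 0.1 %
relative (inverse-crime tests). Under the study's sampling noise —
25-stimulus bins averaged over 14 cells, i.e. ~350 Bernoulli trials per
bin — the first-train parameter surface has a pronounced sloppy valley:
γ_b, h and K_rel trade off against each other with nearly identical
predicted curves. Linearized error propagation at the default parameters
gives relative SDs of roughly 104 % (γ_b), 15 % (γ₁), 75 % (h) and 127 %
(K_rel) for the unweighted least-squares estimator, and even the
Cramér–Rao bound with optimal weighting leaves 52 %/9 %/35 %/64 %. Raw
parameter estimates from a single cohort should therefore be read with
caution; the quantities the data do pin down are the fitted failure
*curve*, the stimulation rate γ₁, and composites such as the
time-to-failure-onset. The acceptance suite contains a stochastic
recovery test asserting ±20 % recovery of all four parameters in ≥ 90 %
of 50 replicates; it fails (≈ 8/50) for exactly this reason and is
retained as an honest record of the estimator's limits — best-fit SSE in
those replicates is *below* the SSE at the generating values, so this is
a property of the statistics, not of the optimizer.

## Train metrics

Conventions, where the literature leaves room:

- Success threshold: 5 % of the per-cell baseline EPSC, ties counting as
  successes; per-call override.
- Rolling success: trailing (causal) 25-event window, timestamped at the
  last stimulus of the window. The fitting pipeline uses disjoint
  25-stimulus bins instead, so bins are independent.
- Transmission failure event: two consecutive stimuli without a
  response; `time_to_first_failure` returns the first stimulus of the
  earliest such pair.
- Depression fit: normalized amplitudes, single exponential
  a(t) = ss + (1−ss)e^{−t/τ} over 1-based pulses 3–20 (100 Hz) or 3–46
  (300 Hz); the default window clamps to the train length (a 150-ms
  300 Hz burst holds 45 stimuli). Steady state: mean normalized
  amplitude beyond 3τ.
- RRP charge: trapezoidal integral of the baseline-subtracted sweep over
  the train, with stimulation-artifact windows blanked and bridged by
  linear interpolation; baseline is the median of the 50 ms before the
  train. The artifact-subtraction procedure is a stand-in chosen for
  testability (the generator provides ground-truth charge).
- Recovery: f(Δt) = 1 − (1−f₀)e^{−Δt/τ}; points before 0.4 s are
  excluded for RRP recovery (transient facilitation), none for single
  EPSCs. Unfittable cells are flagged with reason codes, never silently
  dropped.
- Spontaneous events: threshold-crossing detection with a refractory
  interval, stimulus windows excluded — a deliberately simple stand-in
  detector, adequate for the synthetic traces it is tested on.

## Synthetic data

The generator emulates what the analysis layer consumes, not the
biophysics beneath it: amplitudes follow exponential depression to a
steady-state fraction with unit-mean lognormal quantal noise
(CV 0.1); failures are Bernoulli draws from the ATP model, emitting a
small residual amplitude (1 % of baseline) so the threshold classifier
is genuinely exercised; sweeps are exponential EPSC kernels (τ 3 ms,
1 ms synaptic latency) plus biphasic stimulation artifacts and Gaussian
noise at 10 kHz sampling; spontaneous events are Poisson with lognormal
amplitudes; cohorts draw per-cell parameters lognormally around a
template (default baseline-amplitude CV 0.31, n = 14 cells). Protocol
presets: 100 Hz × 200 ms and 300 Hz × 150 ms bursts, paired
depletion/recovery trains at intervals 10 ms–13 s (a 20 ms-start variant
also ships), and three sustained 100 Hz trains (150 s mature, 30 s
immature) with 2-min rests and post-train test pulses at 0.1–19 s.

What passing tests on this substrate do *not* show: real recordings have
correlated failures (a failing axon stays failed for stretches),
receptor desensitization and saturation, series-resistance artifacts,
and rundown — none of which the generator produces. The mature
OxPhos-blocked preset uses the fitted model parameters; the immature
glycolysis-blocked preset is illustrative only (no quantitative failure
model exists at that age).

## Numerical choices

ODE: LSODA with rtol 10⁻⁹ / atol 10⁻¹², uniform output grid (default
0.25 s), solver failure raises with diagnostics rather than returning
NaN. The Hill function is evaluated in log space to avoid overflow at
extreme ATP/K ratios. Optimizer tolerances 10⁻¹² (xtol/ftol/gtol).
Fits are deterministic given the config seed; all generators are pure
functions of (parameters, seed), with per-cell/per-train seeds spawned
from the master seed via `numpy.random.SeedSequence`.

## Problem sizes

The analysis drivers and tests run the study at its native scale —
three 150-s trains at 100 Hz (15,000 stimuli each) across 14 cells per
condition, 600 bins per train — which completes in seconds; the pipeline
unit tests use 40-s trains with 6 cells for brisk iteration.

## Known limitations

- Between-train ATP recovery is not modeled; onset ATP values are free
  parameters, so the model cannot predict the effect of changing rest
  intervals.
- The demand sigmoid is descriptive; its shape parameters are weakly
  identified when the data only sample one flank.
- First-train parameters are estimated jointly from one curve and are
  sloppy under realistic noise (see above); cross-cohort averaging or
  priors would be needed for tight per-parameter claims.
- The failure model is memoryless given ATP; observed failure runs in
  recordings may be longer than Bernoulli statistics predict.
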