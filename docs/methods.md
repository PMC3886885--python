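# Methods

## Model

The task is a center-out reach to a circular target of radius `n0` at unit
distance in direction θ, with the cursor rotated by γ (counter-clockwise)
relative to the hand. The network has two layers. The input layer is a
population of `N` neurons with Von Mises tuning

    u_i(θ) = Λ exp(ρ (cos(θ − θ_i) − 1)),

preferred directions evenly spaced on the circle. `ρ` is the tuning
concentration (dimensionless; ρ = 0 is flat tuning, the half-bandwidth
solves `exp(ρ(cos x − 1)) = (1 + e^{−2ρ})/2` and shrinks with ρ). The peak
`Λ` is not free: it is set so the squared population norm `‖u(θ)‖²` equals
`U` (default 1) for every θ. Holding the norm fixed makes the effective
per-rewarded-trial step, and hence the single-target learning time,
independent of the tuning width; this invariance is verified by a
two-sample KS test across ρ ∈ {0.5, 2, 8}. With discrete N the norm is
θ-dependent only at O(e^{−N}); the residual is exposed as
`TuningField.normalization_residual()`.

The output layer holds the planar hand endpoint `y = W u(θ) + ξ`, with
`W ∈ R^{2×N}` and isotropic Gaussian noise ξ (SD σ per component — σ is the
scale of motor variability, the model's only source of exploration). The
cursor is `c = R_γ y`. Squared errors: noisy `E = |c − v(θ)|²`, noiseless
`Ẽ = |R_γ W u − v|²`. The binary reward is `1{E ≤ n0²}` (non-strict at the
boundary; the difference has measure zero under the noise). Two graded
families are provided: a logistic in the squared error,
`σ_T(E) = 1/(1 + exp((E − n0²)/T))`, which is 1/2 on the target rim and
recovers the binary reward as the smoothing `T → 0`, and a Bernoulli draw
with success probability `σ_T(E)`.

Plasticity is reward-gated and Hebbian in (noise × input):

    W ← W + η R ξ u(θ)ᵀ.

The normalized rate `η̃ = η‖u‖²` is the natural parameter: a rewarded trial
whose noise exactly cancels the residual displacement scales the noiseless
displacement by `(1 − η̃)` (verified to 1e−8 against the network update).

The initial map `W0` solves `W0 u(θ) = v(θ)` for all θ (zero noiseless
error before the rotation). It is built as the least-squares solution on a
720-point θ-grid with singular values below 1e−8 of the maximum truncated —
those directions correspond to Fourier modes of the tuning curve whose
coefficients are at rounding level and carry no signal. The analytic form,
rows `(cos θ_i, sin θ_i)/(N f1)` with `f1 = Λ e^{−ρ} I₁(ρ)` the first
Fourier coefficient of the tuning curve, is kept as a cross-check; the two
agree to ~5e−11 at ρ = 1, N = 360. Flat tuning (ρ = 0) has `f1 = 0` and is
rejected: the input then carries no directional information.

## Analytics

All closed forms below are exact in the small-target limit `n0 → 0`, where
a reward pins the noise realization; they are validated against Monte-Carlo
or network-level oracles in the test suite.

* **Reward probability.** The cursor–target distance is Rice distributed
  (noncentrality √Ẽ, scale σ), so `P = 1 − Q₁(√Ẽ/σ, n0/σ)` with Q₁ the
  Marcum Q-function; evaluated through the scipy Rice CDF and cross-checked
  by adaptive quadrature of the density (agreement 1e−8). P is decreasing
  in Ẽ, and non-monotonic in σ whenever Ẽ > n0²: some noise is needed to
  reach a distant target at all, too much scatters the endpoint. The first
  reward is geometric with parameter P(Ẽ₀).
* **Trajectory and thresholds.** Across rewarded trials
  `Ẽ_k = (1 − η̃)^{2k} Ẽ₀`: convergence iff η̃ < 2. With finite n0 the
  reward only constrains the cursor to within n0 of the center; the
  adversarial recursion `|d| ← |1 − η̃||d| + η̃ n0` has fixed point `n0`
  for η̃ ≤ 1, `η̃ n0/(2 − η̃)` for 1 < η̃ < 2, and no finite fixed point
  beyond 2. Hence noiseless performance is exactly 1 iff η̃ ≤ 1. The bound
  is computed by iterating the recursion, not by the closed form, and the
  closed form is asserted in tests. At η̃ = 1 the stationary noiseless
  error is uniform on [0, n0²]; we verify this empirically (KS on
  subsamples thinned by 500 trials to break the serial correlation of the
  chain) and treat the uniformity as an empirical property, not a theorem
  of this package.
* **Generalization and interference.** The overlap
  `Γ(Δθ) = u(θ)·u(θ+Δθ)/‖u‖²` has the large-N form
  `I₀(2ρ cos(Δθ/2))/I₀(2ρ)` (discrete sum matches to 1e−6 at N = 360).
  After full single-target adaptation the test-direction error obeys
  `G(Δθ) = 1 − Ẽ_after/Ẽ_before = Γ(2 cos Δθ − Γ)`: perfect at Δθ = 0,
  negative (worse than baseline) when `cos Δθ < Γ/2`. The first rewarded
  trial for one of two targets changes the other's noiseless error by the
  factor `1 − I₁` with `I₁ = η̃Γ(2 cos Δθ − η̃Γ)`; positive I₁ is
  constructive interference, negative destructive, and `I₁ ≡ G` at η̃ = 1.
  `critical_angle` locates an interior extremum of I₁ on (0, π) by
  bracketed root-finding on its numerical derivative and returns `None`
  when I₁ is monotone (broad tuning).

## Simulation engine

`run_adaptation` executes the per-trial loop (target selection → input
activity → noise draw → reach → reward → gated update → shaping step) for
one seeded realization; `run_ensemble` vectorizes the identical arithmetic
across realizations for ensemble statistics. Randomness comes from
counter-based streams (`SeedSequence(base, spawn_key=(i,))`), so
realizations are order-independent and replays are bit-identical. The
rotation is in force from trial 0, so the trial-0 error is the
already-rotated error. Runs whose noiseless error exceeds 1e6 terminate
early and are flagged divergent rather than raising; with the binary
reward a super-critical rate self-limits instead (rewards stop arriving
once the error is large and the map freezes), so the guard matters mainly
for flat graded rewards.

Shaping controllers:

* **Target size**: start at `n0_init`, shrink by `n0_step` (floor
  `n0_final`) whenever every monitored per-target reward EMA (timescale
  `ema_timescale` trials, default 100) has changed by less than
  `steady_tol` (default 0.02) over one timescale; the EMAs are then reset
  to zero. Monitoring is per target by default.
* **Rotation angle**: grow γ from 0 by `gamma_step` toward the task angle,
  either every `block_len` trials (default 25) or adaptively on the same
  EMA steady-state rule.

## Estimators

* **Final error**: median of the noisy error over the last 10% of the run
  (floor 10 trials; the window length is a package default, configurable).
* **Learning duration τ**: first trial from which the 50-trial
  median-filtered error stays below 1.05 × final error for a full window;
  never-crossing curves are censored at the run length. A never-*adapting*
  curve sits on its initial plateau and satisfies the settle criterion
  trivially at trial 0; the optional `baseline_drop` rule (final error must
  fall below half the initial plateau) censors these instead. A
  moving-average variant is provided as a cross-check and agrees within the
  filter window on smooth curves.
* **Per-target completion (ensembles)**: a target counts as learned at the
  first presentation from which its median-filtered *noiseless* error stays
  within the target (≤ n0²) for a full window. This criterion is used for
  delayed-, ordered- and entire-task statistics because the settle
  criterion applied per target is dominated by the width of the stationary
  noiseless-error distribution and can lag actual completion by thousands
  of trials; the settle criterion remains the default for single learning
  curves.
* **Performance / noiseless performance**: time-averaged indicators
  `1{E ≤ n0²}` and `1{Ẽ ≤ n0²}` after an excluded transient.
* **CC(t)**: Pearson correlation, across realizations, between the error on
  a trial presenting target A and the error on the immediately following
  trial presenting target B, centered per pair position across realizations
  (the natural reading of the estimator; per-realization centering is the
  alternative). Reported after a centered 51-point moving average that
  shrinks at the series boundaries (boundary positions average fewer
  points — documented, not masked); `cc_ext` is the signed extremum of the
  smoothed curve. Zero-variance positions are NaN and skipped.
* **Delayed learning**: per-realization sorted per-target completions
  (τ1, τ2), ratio τ2/τ1, against an independence null in which τ2 is the
  maximum of two draws from the matched single-target completion
  distribution. Censored realizations are excluded from ratios and counted.
* **Ordered learning**: a realization is close-to-far ordered when
  completion times are non-decreasing in angular distance from the
  first-completed target, with symmetric-distance ties exchangeable. The
  chance level is computed by exact enumeration of the (m−1)! completion
  orders (1/30 for m = 6).

## Study conditions

The simulations behind the qualitative results use `N = 60`, γ = 30°,
η̃ = 0.5 and U = 1 unless stated. The tuning normalization makes learning
times independent of N and ρ, so the input-layer size only sets the angular
resolution of the map. Noise and target radius are chosen per regime from
the reward-probability analysis so that first-reward waiting times are
10²–10⁴ trials: σ = 0.18 ("low noise", strong destructive delay of a
second opposite target) vs σ = 0.5 ("high noise", near-simultaneous
learning) at n0 = 0.15; σ = 0.15, n0 = 0.2 for the multi-target and
ordered-learning ensembles; σ = 0.2, n0 = 0.05, η̃ = 0.1 for the
small-target generalization measurement. Ensembles use 50–200 realizations
and 10⁴–10⁵ trials per run; these sizes give standard errors comfortably
below the effect sizes being asserted.

## What the synthetic data does and does not emulate

The generator produces the model's own world: endpoint reaches with
isotropic Gaussian exploration noise, stationary tuning, a linear
sensorimotor map, and an exactly circular reward region. It does not
emulate trajectory-level movement generation, muscle dynamics, signal-
dependent or temporally correlated motor noise, use-dependent drift,
retention/forgetting between sessions, or explicit/strategic re-aiming —
so passing tests demonstrate the internal consistency of the model and its
analytics, not that human adaptation follows the same curves.

## Numerical choices

Radians internally, degrees at the CLI and in configs. The Rice CDF is
evaluated via scipy (noncentral χ²) with exponentially scaled Bessel
functions elsewhere, safe for ρ up to several hundred. The W0 pseudo-
inverse truncates at rcond = 1e−8 (see above). The convergence scan
classifies a rate as convergent/divergent by whether 500 rewarded
iterations shrink the error below half its initial value or grow it above
twice (exact marginality occurs only at η̃ = 2, where the contraction
factor is exactly 1); the reported boundary is the midpoint between the
last convergent and first divergent grid rate. The worst-case fixed point
iterates to relative tolerance 1e−12. Degenerate inputs are defined
explicitly: σ = 0 reward probability is the indicator `1{Ẽ ≤ n0²}`;
ρ = 0 gives half-bandwidth π, overlap 1, and no valid W0; γ = 0 makes the
generalization ratio undefined and is flagged rather than returning a
number.

## Known limitations

The two-layer linear model cannot express trajectory curvature or speed
profiles; all statements are endpoint statements. The closed forms are
small-target-limit results — at finite n0 they hold to O(n0²/Ẽ), which is
why the contraction-recovery test filters to Ẽ > 25 n0². The CC smoothing
window and the duration-filter window are reporting choices that shift
estimates by up to half a window. The uniform stationary distribution at
η̃ = 1 is verified empirically at one parameter point, not proved.
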