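# Methods

## Model

The package implements an open-population (Jolly–Seber-type) spatial
capture–recapture model for count detections of identified individuals.

**Observation.** Individual `i` alive in primary period `t` with activity
center `s[i,t]` is detected at trap `j` on each of the `K[j,t]` active
trap-days independently with probability
`p = 1 − exp(−λ₀ g)`, `g = exp(−d²/(2σ_p²))`, `d = ‖x_j − s[i,t]‖`, i.e.
a complementary log-log (Poisson-hazard) link on a half-normal encounter
rate; counts are Binomial(K[j,t], p). Dead or not-yet-recruited
individuals produce zero counts with probability one. `λ₀` and `σ_p` are
shared across periods by default (a per-period λ is accepted in
configuration but not used by the benchmark experiments).

**Population process.** The data are augmented to `M` potential
individuals. `z[i,1] ~ Bern(γ₁)`; for `t ≥ 2`,
`z[i,t] ~ Bern(φ^Δt · z[i,t−1] + γ_t · α[i,t])`, where `α[i,t]` indicates
the individual has never been alive before `t`. The `γ_t` are
*conditional entrance probabilities* — conditional on the number of
augmented individuals still available — so they are intrinsically
time-specific and tied to `M` and to `area(S)`; they are reported but not
compared across configurations. Per-capita recruitment `R_t/N_{t−1}` and
abundance `N_t = Σ z[i,t]` are derived quantities. Unequal primary-period
spacing enters only through `φ^Δt`, so the reported `φ` is always
per-unit-interval (annual when `Δt` is in years).

**Movement.** Between periods, activity centers are (a) constant, (b)
independent uniform redraws over `S`, or (c) a Gaussian random walk with
per-axis SD `σ_s`, truncated to the rectangle `S`. On a rectangle the
truncated bivariate normal factorizes, and the normalizing mass (product
of two 1-D truncated-normal masses) is computed exactly from the normal
CDF; this matters for valid Metropolis ratios near the boundary and makes
the movement density integrate to one over `S` (verified by quadrature in
the tests). A generation-only variant (`markovian_jump`) relocates the
center uniformly with probability `p_jump` instead of stepping, emulating
occasional long-distance moves; its parameters (`p_jump = 0.1`, uniform
relocation kernel) are package choices for the misspecification
experiments, as only the qualitative behaviour is documented for this
scenario.

## Inference

Metropolis-within-Gibbs, implemented in numba:

* **Alive trajectories.** Valid life histories are intervals: enter at
  `e`, last alive at `l` (`e ≤ l`), plus "never". Each individual's whole
  trajectory is redrawn from its exact conditional by enumerating the
  `T(T+1)/2 + 1` states (entry forced at or before the first detection,
  death at or after the last). This joint update is exact and mixes far
  better than single-site Gibbs when recaptures are sparse.
* **φ and γ_t.** Conjugate Beta draws from the transition sufficient
  statistics under Uniform(0,1) priors. With unequal intervals `φ^Δt`
  breaks conjugacy and a random-walk MH step on `φ` is used instead.
* **Activity centers.** Random-walk MH per individual (constant model:
  one block for the shared center) or per individual-period. Proposal
  steps scale with `1/√(1+n)` where `n` is the number of detections
  informing the center, equalizing acceptance between heavily-detected
  individuals (conditional SD ≈ σ_p/√n) and augmented ones; without this
  the well-detected centers barely move at any single global scale and
  their posteriors stay stuck near initialization, biasing detection
  parameters. Where the likelihood is flat (never-alive individuals, and
  off-periods under the independent model) the center is redrawn directly
  from its prior. Under the markovian model the acceptance ratio includes
  both adjacent step densities and the exact change in truncation mass.
* **Center paths and the alive state are decoupled.** The sampler defines
  every individual's center path over all periods (uniform in period 1,
  then the movement process), independent of `z`. Periods in which the
  individual is not alive contribute no likelihood, so the posterior of
  all identified parameters is unchanged, while the trajectory update
  stays a clean enumeration (no movement terms depend on `e, l`).
* **Detection parameters.** Log-scale random-walk MH for `λ₀` and `σ_p`
  under Uniform(0, 10) and Uniform(0, max side of S) priors, plus a joint
  "ridge" move that scales `λ₀` up while scaling `σ_p` down (holding
  `λ₀σ_p²` fixed). The two parameters are strongly negatively correlated;
  without the ridge move their chains need an order of magnitude more
  iterations. `λ₀` remains the slowest-mixing quantity. The detection
  block runs on alternate iterations and the row-likelihood cache is
  refreshed lazily once per iteration.
* **σ_s.** Log-scale random-walk MH against the full random-walk density
  including truncation masses, Uniform(0, max side) prior.
* **Adaptation.** Proposal scales adapt in batches of 50 iterations
  during burn-in only (frozen afterwards, preserving detailed balance).

Initialization: observed individuals start alive from first to last
detection with centers at their detection-weighted mean trap location;
augmented individuals start never-alive with uniform centers; parameters
start at dispersed random values (per chain). Chain `c` uses `seed + c`.
Observed individuals are sorted canonically by encounter history before
sampling, so relabelled input yields bit-identical posteriors.

**CJS variant.** Conditions on first capture: entry is fixed at the first
detection period, only the death time is sampled, and there is no
recruitment or augmentation — it estimates survival, detection and
movement but not abundance.

**Validation.** Two exact cross-checks bracket the sampler. On a tiny
instance (T=2, M=3, one trap, centers and detection fixed) the MCMC
posterior over all joint alive-trajectory configurations matches
brute-force enumeration (φ, γ_t integrated analytically via Beta
functions) to total-variation distance < 0.02. Complementarily, on an
instance whose alive state is pinned by the data, the posterior over
(center, λ₀, σ_p) from the sampler matches direct 4-D numeric
integration — this covers exactly the continuous updates the
enumeration check cannot see.

## Simulator

The generator reproduces a standard benchmark design: T = 5 periods,
M = 150 potential individuals, 40 alive in period 1 (exactly, not in
expectation — this fixes the initial condition without changing any
expectation), a 7 × 7 trap grid with unit spacing centered in a 10 × 10
state space (4σ_p buffer), K = 5 occasions per period, φ = 0.75,
λ₀ = 0.5, σ_p = 0.5, σ_s² = 0.25. Each year the entrance probability is
computed as (deaths since last year) / (never-yet-alive pool), clamped to
[0, 1] (the formula can go negative stochastically), so E[N_t] = 40
throughout. Unobserved individuals are stripped from the returned
encounter data but kept in the truth.

What the generator does *not* emulate: behavioural response to capture,
individual heterogeneity in detection or movement, transients/floaters,
inhomogeneous density, habitat structure, trap failures. Passing
recovery tests therefore demonstrates correctness of the estimator under
its own assumptions, not robustness to these real-data features (the
misspecification grid probes exactly one such violation: a wrong
between-year movement model).

## Simulation study

For each scenario the driver simulates replicate datasets (generating
buffer always 4σ_p), fits with the scenario's movement model and analysis
buffer (3, 4, or 5 σ_p), and accumulates per-parameter posterior means
and 95% central credible intervals. Metrics: average posterior mean,
relative bias `(mean − truth)/truth`, relative RMSE
`√(mean (est − truth)²)/truth` (the denominator convention chosen so the
constant-model survival rRMSE lands at the published ≈ 0.06 scale), and
coverage. Every metric carries a Monte-Carlo standard error so
reduced-replication runs stay interpretable. Density truth is
`target_N / area` of the *generating* state space (0.40 individuals per
unit²). Replicate seeds derive deterministically from the master seed via
`SeedSequence(master, spawn_key=(scenario, rep))`.

**Problem sizes.** The package's default experiment scale is 10–40
replicates per scenario with single chains of 6,000 iterations (1,500
burn-in, thin 3) — chosen because per-fit posterior means at this length
agree with 40,000-iteration runs to well within the across-replicate
spread.
Full-replication (100 datasets, multi-chain) runs use the same code with
larger `--reps` and `--iters`.

## Numerical choices and edge cases

* Row log-likelihoods omit binomial coefficients (constant in every
  ratio); `log(1−p) = −λ₀g` is exact under the cloglog link, so zero
  counts cost one `exp` per trap; traps with kernel exponent > 45
  contribute below double-precision resolution and are skipped.
* Probabilities are clamped away from 0/1 by 1e−12 before logs; a
  proposal that makes a detected count impossible gets log-likelihood
  −1e300 and is rejected.
* `γ_t` with an empty recruitment pool is 0 with a warning (simulator);
  the sampler flags posteriors where `N_t` piles within one of `M`
  ("increase M").
* Ties in the canonical individual ordering are identical rows, so the
  order among them is irrelevant.
* Zero-effort traps are retained and contribute nothing; a period with no
  active traps anywhere is rejected at validation.

## Known limitations

* Rectangular state spaces only — no habitat masks or polygon domains.
* Circular (isotropic) home ranges; no detection covariates; no
  behavioural or occasion effects.
* `γ_t` estimates are `M`- and `S`-dependent by construction and should
  not be compared across state spaces.
* The CJS variant ignores individuals' pre-first-capture history, so it
  cannot estimate recruitment or abundance.
* Under sparse recaptures the `σ_s` posterior is weakly identified and
  mixes slowly (flagged via Gelman–Rubin when multiple chains are run);
  an informative prior or a fixed `σ_s` is the practical remedy, not
  implemented here beyond the configurable prior bound.
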