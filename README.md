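# openscr

Open-population spatial capture–recapture (SCR) modelling: simulation,
Bayesian MCMC estimation, and sensitivity analysis of survival and density
estimates to the state-space definition and the between-period movement
model.

## The problem

Camera-trap and similar surveys detect individually identifiable animals at
known trap locations over multiple primary periods (e.g. years). Open SCR
models estimate survival, recruitment, abundance and density while
accounting for imperfect, distance-dependent detection. Each individual
carries a latent *activity center* `s` in a state space `S` (a buffered
rectangle around the traps); counts at trap `j` follow

    y[i,j,t] | z[i,t]=1  ~  Binomial(K[j,t], p(d))
    p(d) = 1 − exp(−λ₀ · exp(−d² / 2σ_p²))

where `d` is the trap–center distance and `K[j,t]` the days trap `j` was
active. Alive states follow a Jolly–Seber process with data augmentation to
size `M`:

    z[i,t] ~ Bernoulli(φ^Δt · z[i,t−1] + γ_t · α[i,t])

with per-interval survival `φ`, conditional entrance probabilities `γ_t`,
and recruitment availability `α`. Abundance is the derived sum
`N_t = Σᵢ z[i,t]`, density `D_t = N_t / area(S)`. Between primary periods
activity centers are **constant**, redrawn **independent**ly uniform on
`S`, or follow a **markovian** Gaussian random walk (per-axis SD `σ_s`)
truncated to `S`. Because `S` also bounds where animals can move, survival
and density estimates can depend on how big you draw it — that sensitivity
is what the `study` module quantifies.

Audience: quantitative ecologists and biostatisticians running multi-year
capture–recapture studies, and methodologists stress-testing open SCR
model specifications.

## Worked example

```python
from openscr import (SimulationConfig, simulate_scenario,
                     OpenSCRJollySeber)

sim = simulate_scenario(SimulationConfig(movement_model="constant",
                                         seed=2024))
print(sim.data.n_observed, sim.N)            # 46 observed; true N per year

est = OpenSCRJollySeber(movement_model="constant", buffer=2.0, M=150,
                        n_chains=2, n_iter=8000, n_burnin=2000, seed=1)
est.fit(sim.data, sim.traps)
print(round(est.phi_mean_, 3), est.N_mean_.round(1))
print(est.summary_.loc[["phi", "lambda0", "sigma_p"]].round(3))
```

Output:

```
46 [40. 39. 36. 37. 34.]
0.788 [40.6 36.2 41.2 42.2 39.3]
          mean     sd   q2.5  median  q97.5
phi      0.788  0.044  0.697   0.790  0.868
lambda0  0.470  0.041  0.391   0.469  0.553
sigma_p  0.524  0.017  0.493   0.523  0.558
```

The generator used survival 0.75, λ₀ = 0.5 and σ_p = 0.5 with 40 animals
on a 10 × 10 state space; a single replicate recovers them within
posterior uncertainty, and the abundance series tracks the true `N_t`.
`est.rhat_` holds Gelman–Rubin diagnostics, `est.posterior_` the full
chains.

The same workflow is scriptable from the shell:

```sh
openscr simulate --seed 1 --out-dir data/
openscr fit --traps data/traps.csv --detections data/detections.csv \
            --t 5 --movement markovian --buffer-mult 4 --out-dir fit/
openscr study --reps 20 --iters 6000 --burnin 1500 --chains 1 \
              --out-dir study/
```

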