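# spatemort

Bayesian spatiotemporal forecasting of small-area mortality and life
expectancy.

Health and pension planning needs forecasts of age-specific death rates and
life expectancy not just nationally but for every district of a country.
`spatemort` implements a family of Bayesian hierarchical models for exactly
this problem — district × age group × year death counts smoothed over age,
time, birth cohort and space — together with the demographic machinery to
turn forecast rates into life expectancy, and a holdout protocol to choose
among competing models.  It is aimed at demographers, epidemiologists and
statisticians who want a self-contained, testable implementation of this
model family, with a synthetic-data generator that makes every component
recoverable.

## The models

Deaths in district *s*, age group *a*, year *t* are Poisson,

```
D[s,a,t] ~ Poisson( N[s,a,t] * exp(eta[s,a,t]) )
```

with five competing structures for the log rate `eta`:

1. `alpha0 + alpha_a + (beta0 + beta_a)·t̃ + gamma_t + u_s + v_s` — smooth
   age-specific levels (`alpha_a`, RW2 prior) and trends (`beta_a`, RW2), a
   linear national trend plus a non-linear period random walk (`gamma_t`,
   RW1), and a Besag–York–Mollié spatial term (intrinsic-CAR `u_s` plus
   exchangeable `v_s` on a district adjacency graph);
2. model 1 with a sign-preserving exponent on the centred time covariate,
   `t̃ → sign(t̃)|t̃|^theta`, for faster- or slower-than-linear trends;
3. model 1 plus a birth-cohort random walk `phi_c` (cohort = year − age,
   in five-year bands);
4. model 3 with smooth age-specific weights `w_a ∈ [0,1]` on the cohort
   term;
5. a Lee–Carter structure `a_a + b_a·k_t` (period index `k_t` a random walk
   with drift, classical `Σb = 1`, `Σk = 0` identification) plus the same
   spatial term.

Fitting is by Hamiltonian Monte Carlo with closed-form gradients, a dense
Fisher-information mass matrix and Brooks–Gelman–Rubin convergence
diagnostics.  Forecasts are posterior predictive: deterministic components
extrapolate by their formulas, random-walk components are forward-simulated
per draw.  Life expectancy comes from abridged life tables with a
Kannisto–Thatcher logistic extension of the open 85+ age group to 100+,
Arriaga decomposition of life-expectancy change by age, and
population-weighted national aggregation; inequality summaries include the
1st–99th percentile spread of district life expectancies and deprivation
quintiles.

## Worked example

```python
from spatemort import (SimulationConfig, simulate_study, MortalityForecaster,
                       life_expectancy_from_rates, national_rate)
import numpy as np

# a synthetic study: 12 districts on a 3x4 grid, 19 age groups, 20 years
cfg = SimulationConfig(seed=11)
data, truth, graph = simulate_study(cfg, model_id=3)

est = MortalityForecaster(model_id=3, chains=2, draws=500, warmup=500, seed=3)
est.fit(data, graph=graph)
print(f"max PSRF: {est.max_psrf_:.3f}")

fc = est.forecast(horizon=10)                    # rates to 10 years ahead
pop = data.population[:, :, -1]                  # district x age weights
nat = (fc.rates * pop[None, :, :, None]).sum(axis=1) \
      / pop.sum(axis=0)[None, :, None]           # national rates per draw
e0 = life_expectancy_from_rates(np.moveaxis(nat, 1, -1), data.age_scheme)
q = np.quantile(e0[:, -1], [0.025, 0.5, 0.975])
print(f"national e0 in {data.years[-1] + 10}: "
      f"{q[1]:.1f} (95% CrI {q[0]:.1f}-{q[2]:.1f}) years")
```

Output:

```
max PSRF: 1.024
national e0 in 2022: 80.6 (95% CrI 79.8-81.4) years
```

The maximum potential scale reduction factor near 1 says the two chains
agree.  Life expectancy at birth in this synthetic study is ~76 years in
the last data year; a decade of the generator's ~2%-per-year mortality
decline carries the forecast to 80.6 years, with a credible interval that
widens with the forecast horizon (posterior uncertainty plus the
forward-simulated period random walk).

A command-line pipeline wraps the same stages:

```bash
spatemort simulate --seed 5 --out study/
spatemort compare --data study/data.csv --adjacency study/adjacency.txt \
    --models 1,3 --cutoff-year 2006 --out validation/
```

`compare` fits each model on the years up to the cutoff, forecasts the
withheld years, scores forecast error / absolute error / 90% interval
coverage for life expectancy and death rates, and emits the model with the
smallest median absolute life-expectancy error.

## Layout

- `src/spatemort/` — the library: `simulate` (synthetic studies), `models`
  (the five structures, likelihood, priors), `inference` (HMC fitting,
  diagnostics), `forecasting`, `lifetable`, `validation`, `estimator`
  (scikit-learn-style wrapper), `cli`.
- `docs/methods.md` — modelling and implementation notes.
- `tests/` — unit, property and end-to-end acceptance tests.
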