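# Methods

This note records the modelling choices, identification conventions,
numerical decisions and known limitations of `spatemort`, in the order the
pipeline uses them.

## Data model

The unit of analysis is a district × age group × year cell of one sex.
Deaths are Poisson given person-years of exposure and a log rate:

    D[s,a,t] ~ Poisson( N[s,a,t] * exp(eta[s,a,t]) ).

The Poisson form is the natural likelihood for count data of this kind; it
ignores overdispersion beyond what the hierarchical effects absorb, which
is the usual assumption for all-cause mortality at these cell sizes.  Age
groups are abridged (0, 1–4, then five-year groups to 80–84, and open
85+); the open group's midpoint is fixed at 90 years and the cohort of a
cell is `year − midpoint(age group)`, binned into five-year bands —
midpoint binning is the standard age-period-cohort (APC) convention for
abridged data.

## The five model structures

Model 1 decomposes the log rate into smooth age-specific levels and
trends, a non-linear period term, and a spatial level:

    eta = alpha0 + alpha_a + (beta0 + beta_a)·t~ + gamma_t + u_s + v_s

`t~` is the calendar year centred at the mid-period year, so the intercept
is the mid-period national level and random-walk forecasts anchor at the
data's end.  Model 2 replaces `t~` by `sign(t~)|t~|^theta` (trends faster
or slower than linear); model 3 adds a cohort term `phi_c`; model 4
weights the cohort term by smooth age-specific weights `w_a ∈ [0,1]`
(cohort effects can matter more at some ages, e.g. cumulative life-course
exposures at older ages); model 5 is a Lee–Carter structure
`a_a + b_a·k_t` plus the same spatial level, with the classical
identification `Σ b_a = 1`, `Σ k_t = 0` and a random walk with drift on
`k_t`.

### Priors

* Age blocks (`alpha_a`, `beta_a`, and the Lee–Carter level) get
  second-order random-walk (RW2) priors: Gaussian second differences with
  block-specific innovation SDs.  RW2 produces the smooth age profiles
  mortality data show; first-order walks are offered as an option
  (`rw_order_age=1`).  The linear (ramp) direction is in the RW2 null
  space and carries its own Normal(0, 10) prior — log-mortality age
  profiles have slopes of order 10 on a unit-norm ramp, so a tighter prior
  would be unintentionally informative (we measured a visible intercept
  bias with a unit-scale prior).
* Period (`gamma_t`) and cohort (`phi_c`) blocks get RW1 priors (RW2
  optional for the period block).  First order is deliberately
  conservative for time: RW2 period terms extrapolate curvature, which is
  exactly the over-extrapolation risk the linear-plus-wiggle decomposition
  is meant to avoid.
* The spatial term is Besag–York–Mollié: an intrinsic-CAR component `u`
  (pairwise-difference Gaussian on the adjacency graph) plus exchangeable
  Gaussian noise `v`, each with its own scale.  The BYM structure applies
  to district *levels*; district trends are shared through the age-trend
  and period terms.
* All innovation SDs get half-normal hyperpriors with a single
  configurable scale (default 1 on the log-rate scale — weakly
  informative, since realistic innovation SDs are 0.001–0.3).  `theta` has
  a log-normal prior with median 1 (SD 0.25 on the log scale), so model 2
  is anchored at linearity.  `w_a` is a logistic transform of an RW1 block
  whose level has a Normal(0, 2) prior on the logit scale.

### Identification

Every deviation block is constrained to sum to zero.  Period and cohort
blocks are additionally constrained to have zero linear trend (their prior
is the RW density conditioned on that subspace).  This is the standard APC
identification: a linear drift in the period or cohort walk is exactly
aliased with `beta0`, so without the constraint the posterior contains
prior-only-identified ridges — `beta0` becomes meaningless and, worse, the
*forecast* depends on an arbitrary allocation of trend between components
that extrapolate differently (the linear term extrapolates indefinitely,
the walks are forward-simulated without drift).  The constraint can be
switched off (`trend_constrained=False`) for sensitivity analysis.

## Synthetic-data generator

The generator draws one realisation of every model component and
forward-simulates Poisson counts, so all parameters are recoverable by
construction.  Defaults describe a stylised low-mortality national
population:

* age effects: a fixed J-shaped baseline schedule (infant rate 6 per 1000
  falling to 0.1 per 1000 in late childhood and rising near-exponentially
  to 200 per 1000 at 85+; overall level `alpha0 = −5.65`), plus RW2
  deviations with innovation SD 0.02 — deviations stay within a few tenths
  of a log unit, since RW2 innovations integrate to ~`sigma·n^{3/2}` at
  the profile ends;
* trend: 2% annual decline (`beta0 = −0.02`), age-specific trend
  deviations with RW2 SD 0.0005 (≤ ±1.5 %/year across ages);
* period wiggles: RW1 SD 0.01; cohort wiggles: RW1 SD 0.03 (background
  generation-to-generation variation of a few percent);
* space: intrinsic-CAR SD 0.10 plus exchangeable SD 0.05 on a rook-adjacent
  grid (default 3×4 = 12 districts) — ~10% structured mortality
  differences between districts;
* populations: 1 500 person-years per district-year in the infant group,
  6 000 at 1–4, 7 500 in five-year groups, 4 000 at 80–84, 3 000 at 85+ —
  the order of magnitude of a real district's age bands;
* period and cohort draws are centred *and* detrended.  These effects are
  only defined up to linear terms (the drift belongs to the explicit
  trend), so the generator emits the identified part; leaving random drift
  in the truth makes "recovery" ill-posed, since no model can allocate an
  aliased drift correctly.

The default study (12 districts × 19 ages × 20 years) is sized so that a
full fit runs in ~10–15 s on one CPU and replicate-based checks finish in
minutes.  What the generator does *not* emulate: migration and population
dynamics, overdispersion beyond the model family, irregular geographies,
missing data, and real cohort shapes (its cohort effects are stationary
wiggles, not the sharp generation effects of, e.g., wartime births).
Passing tests on these data show the machinery is correct and calibrated
under the model family's own assumptions — not that the family is adequate
for any particular real population.

## Inference

The sampler is Hamiltonian Monte Carlo with analytic gradients.  Blocks
are parameterised by coefficients in orthonormal bases of their
constrained subspaces (unit Jacobian, so the sampled density is exactly
the model's likelihood-plus-prior); innovation SDs are sampled on the log
scale.  Three design points matter:

* **Dense Fisher mass matrix.**  Age, period, cohort and spatial blocks
  are strongly correlated through the likelihood (including weakly
  identified near-aliased directions such as cohort-quadratic vs
  age-trend).  A diagonal mass matrix cannot remove these correlations —
  we measured potential scale reduction factors of 5–100 with diagonal
  adaptation.  The mass matrix is therefore the expected information
  `J'·diag(mu)·J` at the starting point (J by central differences of the
  linear predictor) plus the prior Hessian; with this whitening the
  default fixture fit reaches max PSRF ≈ 1.01–1.05.
* **Marginalised BYM.**  Only the sum `u + v` is likelihood-identified;
  the split mixes pathologically if sampled.  The sampler carries the sum
  under its exact marginal Gaussian prior (eigenbasis of the graph
  Laplacian, per-component variance `sigma_u²/lambda + sigma_v²`), and the
  (u, v) split of each stored draw is recovered afterwards by exact
  conditional simulation — draws are from the correct joint posterior.
* **Adaptation.**  Dual-averaging step size towards 0.9 acceptance,
  jittered leapfrog count (1–32), divergence guard at an energy error of
  1000, data-driven start (empirical log rates with a +0.5 continuity
  correction for zero-death cells, jittered per chain).  Step-size
  adaptation occasionally locks onto a too-large step; a chain ending with
  acceptance < 0.6 or repeated divergences is rerun once, more
  conservatively, from the same seed stream.

Convergence is assessed by the (Brooks–)Gelman–Rubin potential scale
reduction factor on every stored scalar; the convergence gate is
max PSRF < 1.1 (configurable; a soft gate — the CLI signals failure with a
distinct exit code rather than discarding the fit).  Default sampling is
2 chains × (500 warmup + 500 kept) draws; the draw count is configurable
up to the 8 000-sample regime used for final inference.

Known small-sample property: at the default study size the posterior mean
of `alpha0` sits ~+0.005 (≈ 1 posterior SD, 0.09% of the value) above the
generating value.  The smoothness prior shrinks the sharp J-kink of the
age profile at the young, low-count ages (a few hundred expected deaths
per young age group in the whole study), and the sum-to-zero constraint
pushes the surplus into the intercept.  The effect disappears as counts
grow and does not affect cell-rate coverage, `beta0`, forecasts or life
expectancy at any detectable level.

## Forecasting

For each posterior draw: the linear (or exponentiated) trend and all age
and spatial effects extrapolate deterministically; the period walk, new
cohorts, and the Lee–Carter index are forward-simulated once with that
draw's innovation SD (one stochastic path per draw, the standard
posterior-predictive recipe).  The non-linear period term is
forward-simulated rather than frozen, so forecast intervals widen with
horizon as `sigma²·h` demands.  No damping is applied to the linear trend
— the model family has none.  Quantiles use linear interpolation of order
statistics everywhere.

## Life tables

Abridged life tables use `q = n·m/(1 + (n−a)·m)` with `a = 0.1` years in
the infant group and `n/2` elsewhere (the low-mortality standard); an
exponential-hazard convention (`q = 1 − e^{−nm}`, `L = d/m`) is available
and makes constant-hazard populations analytically exact.  The open group
has `q = 1`, `L = l/m`.

The open 85+ group is extended to 85–89, …, 95–99, 100+ with the
Kannisto–Thatcher logistic hazard `mu(x) = a·e^{bx}/(1 + a·e^{bx})`,
fitted by least squares on the logit scale over the groups starting at 70,
75, 80 and the 85+ midpoint (90).  The fitted shape is rescaled by a
single factor, solved by bisection, so that total deaths over total
person-years of the implied stationary cohort reproduce the input 85+
rate exactly; the stationary cohort uses the exponential within-interval
convention, which keeps the conservation identity exact for arbitrarily
high old-age rates (the midpoint convention's `q` exceeds 1 above
`m = 1/a`).  A non-increasing fit falls back, with a warning, to a flat
hazard equal to the 85+ rate (conservation then holds trivially).

Life expectancy is always computed per posterior draw and summarised
afterwards — credible intervals are on life expectancy itself, never on
rates that were first summarised.  Change in life expectancy is attributed
to age groups with the discrete (Arriaga) decomposition — a direct term
(person-years gained within the group) plus an indirect/interaction term
(extra survivors exposed later); contributions sum to the total change
exactly (telescoping identity), though individual terms are antisymmetric
under reversal only to second order.  National rates are
population-weighted means of district rates per age-year cell.  Inequality
summaries: the 1st–99th percentile spread of district life expectancies
per draw, and equal-count deprivation quintiles (population-weighted life
expectancy and min–max range per quintile); the deprivation index is an
input, never computed here.

## Holdout validation

The protocol fits on the early years, forecasts the withheld window and
scores: signed forecast error (bias), absolute error, and 90% interval
coverage, for life expectancy (per district-year) and national
age-specific rates.  Conventions: the central estimate is the posterior
median; error is forecast minus observed; a value on an interval bound
counts as covered; observed life expectancy runs through the same
life-table pipeline (including the old-age extension) on raw withheld
rates, with zero-death open-group cells given half a death; interval
coverage is assessed against posterior-predictive counts simulated with
the withheld exposures, so the comparison includes the sampling noise the
observations themselves carry.  Model selection minimises the median
absolute life-expectancy error, with ties broken by |mean error|, then by
model number.

The default split of the 20-year study is 14 training years and 6 withheld
years (the ~2:1 ratio of the full protocol, which trains on 21 of 32 years
where that much data exists).  The cohort-model selection experiment uses
a cohort innovation SD of 0.3 — adjacent five-year generations differing
by ~35% in mortality, the scale of the strongest documented generation
effects (male smoking cohorts reached all-cause rate ratios near 2).  At
background cohort variation (SD 0.03–0.1) the holdout contrast between the
cohort and no-cohort models is within the noise floor of a 12-district
study, and selection is essentially a coin flip; a criterion about
*detecting* cohort structure needs a condition where the structure is
decisively present.

## Limitations

* The sampler's mass matrix is fixed at the start; posteriors whose
  curvature changes drastically across the support (e.g. extremely sparse
  data) may still need the conservative-retry path or more warmup.
* The appendix-level details of the original model family (exact priors,
  whether district *trends* are spatially smoothed) are not public; the
  choices above are this package's own and are flagged where they are
  genuinely open.  An optional BYM block on district slopes is not
  implemented — district trend differences load on the shared smooth
  structure.
* All analyses are sex-specific by construction; the pipeline processes
  one sex per invocation and never models sexes jointly.
* Small-population disclosure handling (suppressing districts below a
  population threshold) is the user's responsibility.
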