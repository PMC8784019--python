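# fewlevels

A Monte Carlo simulation study of a common rule of thumb in ecological
statistics: *"don't use a random effect with fewer than five levels."*

When observations are grouped in blocks (field sites, individuals,
populations), the grouping factor can be modelled either as a **random
intercept** in a linear mixed-effects model (LMM, partial pooling) or as a
set of **dummy-coded fixed effects** in an ordinary linear model (LM, no
pooling). With few groups the between-group variance is hard to estimate —
but does that actually degrade the *fixed-effect* slope estimates
researchers usually care about? This package simulates unbalanced grouped
Gaussian data, fits both models to every dataset, and scores them head to
head on coverage probability, relative RMSE, bias, variance-component
recovery, and singular-fit frequency across a grid of sample sizes
(N = 30, 60, 120) and group counts (3, 5, 10). It is aimed at
quantitative ecologists and biostatisticians who want to stress-test
modelling guidelines on data that look like their own.

## The model

Data are generated from a random-intercept Gaussian model

```
y_i = β₀ + u_{j(i)} + β₁ x₁ᵢ + β₂ x₂ᵢ + εᵢ,
u_j ~ N(0, σ²ᵤ),   εᵢ ~ N(0, σ²ε),   x₁, x₂ ~ N(0, 0.5)
```

with defaults β₀ = 73, β₁ = 2 (strong slope), β₂ = 0.2 (weak slope),
σ²ᵤ = σ²ε = 1, and an *unbalanced* allocation: each of the g levels gets
one observation, the rest pick a level uniformly at random, and perfectly
balanced draws are rejected (in a balanced design the fixed-effect
estimators decouple from the random effects, which would make the
comparison vacuous).

Each dataset is fitted two ways:

- **LMM** — random intercept per group, estimated by REML. The two
  variance components are profiled down to the ratio θ = σᵤ/σε and the
  concentrated restricted deviance
  `log|V| + log|XᵀV⁻¹X| + (n−p)·log(rᵀV⁻¹r)`, with `V = I + θ² Z Zᵀ`, is
  minimised over θ ≥ 0. A fit with θ̂ below a tolerance (default 1e-4) is a
  **singular fit**. Slope CIs are Wald z-intervals.
- **LM** — OLS with an intercept, both predictors, and g−1 group dummies;
  slope CIs are t-intervals on n − g − 2 degrees of freedom.

Because partial pooling interpolates between full pooling (θ = 0, pooled
OLS) and no pooling (θ → ∞, exactly the dummy-coded LM), the two models
bracket the LMM's behaviour — both limits are verified in the test suite.

## Worked example

Fit both models to one simulated dataset from the largest scenario cell:

```python
from fewlevels import ScenarioConfig, gen_dataset, child_rng, fit_lm, fit_lmm

cfg = ScenarioConfig(n_obs=120, n_levels=10)
ds = gen_dataset(cfg, child_rng(1, 120, 10, 0))
print(fit_lmm(ds).summary())
```

```
Random-intercept linear mixed model (REML)
  theta (sd ratio): 0.896287
  group variance:    0.600441
  residual variance: 0.747439
  95% CIs: z-based Wald
  param         estimate          se      ci_low     ci_high
  intercept     73.16463     0.25911    72.65679    73.67247
  beta1          2.03445     0.12085     1.79758     2.27131
  beta2          0.33962     0.12255     0.09943     0.57981
```

The true values (73, 2, 0.2) all fall inside the intervals; the
random-intercept variance (true value 1) is under-estimated at 0.60 from
only 10 groups. The dummy-coded LM on the same data gives nearly identical
slopes (β̂₁ = 2.03631 vs 2.03445) — with ten groups the two treatments of
the blocking factor barely matter for the slopes.

The full study runs from the command line. A reduced run and its report:

```sh
fewlevels simulate --n-reps 2000 --seed 1 --out results/
fewlevels report --records results/replicates.csv --out results/tables/
```

`simulate` writes a tidy per-replicate CSV (one row per scenario ×
replicate × model × parameter, with estimate, CI, truth, and singularity
flag), summary CSVs, and a manifest with file checksums; `report` prints
the headline tables — coverage, relative RMSE, variance-component
recovery with 2.5/97.5% quantile intervals, singular-fit proportions, and
the singularity-stratified variants. At 2,000 replicates per cell the
patterns are: slope coverage near 0.95 for both models at N = 120, LMM
coverage dipping below the LM's at N = 30, singular fits rising steeply as
levels drop from 10 to 3 (e.g. ~10% at N = 30 with 3 levels vs ~0% at
N = 120 with 10), and relative RMSE driven by N, not by the number of
levels.

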