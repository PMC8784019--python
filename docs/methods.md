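# Methods

## Data-generating process

Each simulated dataset follows a Gaussian random-intercept model with two
observation-level predictors:

    y_i = β₀ + u_{j(i)} + β₁ x₁ᵢ + β₂ x₂ᵢ + εᵢ
    u_j ~ N(0, σ²ᵤ),  εᵢ ~ N(0, σ²ε),  x₁ᵢ, x₂ᵢ ~ N(0, σ²ₓ)

Defaults: β₀ = 73 (an arbitrary grand mean on the scale of, say, tree
height), β₁ = 2 and β₂ = 0.2 (one strong and one weak predictor, mimicking
a dominant driver and a subtle trophic effect), σ²ᵤ = σ²ε = 1 (equal
between-group and residual variance), σ²ₓ = 0.5 (predictors that look like
variables standardised to mean 0 and modest spread). With these values the
marginal response variance is σ²ᵤ + (β₁² + β₂²)σ²ₓ + σ²ε = 4.02, which the
generator tests verify by simulation.

**Unbalanced allocation.** Group labels are assigned by giving each of the
g levels one observation and drawing the remaining n − g labels uniformly
with replacement; an allocation whose counts come out exactly equal is
discarded and redrawn in full. Uniform assignment is the minimal model of
"levels chosen at random", and whole-allocation rejection is the simplest
unbiased way to condition on imbalance. Balanced designs are excluded
deliberately — there the fixed-effect estimators are independent of the
random effects, so the LM/LMM comparison would be empty — and when g does
not divide n the rejection loop provably runs exactly one attempt. The
precondition n > g guarantees termination (at n = g only the balanced
allocation exists).

**Seed policy.** One master seed; the stream for replicate r of scenario
(n, g) is `SeedSequence(master, spawn_key=(n, g, r))`. Any replicate is
reproducible in isolation and results are invariant to the order in which
cells execute, which the experiment tests assert.

## Estimators

**Dummy-coded LM (no pooling).** OLS on [1, x₁, x₂, g−1 treatment
dummies], solved by Cholesky on the normal equations after an SVD rank
check (relative tolerance 1e-10 on singular values; a rank-deficient
design raises an error naming the offending column). Residual variance is
RSS/(n − g − 2); slope CIs use t quantiles on those degrees of freedom.

**Random-intercept LMM (partial pooling), REML.** The two variances are
reduced to the ratio θ = σᵤ/σε. With V(θ) = I + θ²ZZᵀ, the concentrated
restricted deviance is

    d(θ) = log|V| + log|XᵀV⁻¹X| + (n − p) log(rᵀV⁻¹r),  p = 3,

where β̂(θ) is the GLS solution and r = y − Xβ̂(θ). Since Z indicates
group membership, Woodbury gives V⁻¹ = I − Z diag(θ²/(1 + θ²nⱼ)) Zᵀ, so
after one pass accumulating XᵀX, XᵀZ, Zᵀy, etc., each evaluation of d
costs O(gp²); this is what makes the 10,000-replicate grid tractable.
Correctness of the Woodbury form is tested against a dense evaluation
with explicit determinants and inverses (1e-8).

d(θ) is minimised over θ ≥ 0 by evaluating a coarse geometric grid
(0 and 24 points from 1e-3 to 32, grown geometrically if the minimum sits
at the top edge), then polishing the bracketing interval with bounded
Brent (xatol 1e-9). θ = 0 is always evaluated explicitly and wins ties,
so boundary optima are exact rather than merely small. The optimum is
verified in tests against a 1,000-point exhaustive grid and against the
lme4 and statsmodels implementations. At the optimum:
σ̂²ε = rᵀV⁻¹r/(n − p), σ̂²ᵤ = θ̂²σ̂²ε, fixed-effect covariance
σ̂²ε(XᵀV⁻¹X)⁻¹, Wald z CIs.

**Singular fits.** θ̂ < 1e-4 (ratio scale, configurable) is flagged
singular, mirroring the de facto convention of mixed-model software for
"variance estimated at or numerically near zero". The tolerance matters
little: boundary optima land at exactly 0 here.

**Interval policy.** How the original analysis computed its 95% CIs is not
documentable from published sources, so the policy is explicit
configuration recorded in run metadata: LM t-intervals (df = n − g − 2)
and LMM Wald z-intervals by default, either switchable to the other rule.
z-based LMM intervals ignore the uncertainty in the variance components,
which is exactly what produces the observed LMM under-coverage at N = 30.

**Pooling limits.** θ = 0 reproduces pooled OLS exactly; θ → ∞ reproduces
the dummy-coded LM slopes (computed independently via within-group
centering). Both identities are asserted in the tests and pin down the
sense in which the LMM interpolates between the two LMs.

## Metrics

All metrics operate on a tidy long-format records table (one row per
scenario × replicate × model × parameter).

- **Coverage**: fraction of replicates whose CI contains the truth;
  endpoints count as covered (a measure-zero choice fixed for
  determinism). Variance-component records carry no per-replicate CI and
  are excluded from coverage.
- **Relative RMSE**: RMSE divided by |truth|. The normalisation is this
  package's definition (chosen so the β = 2 and β = 0.2 panels are
  comparable); only qualitative orderings are claimed for it.
- **Quantile intervals**: 0.025/0.975 empirical quantiles by linear
  interpolation of order statistics (numpy's default; other definitions
  shift the interval endpoints slightly but change no conclusions).
- **Singular proportion**: fraction of LMM fits flagged singular.
- **Stratification**: summaries optionally split by singularity status.
  Empty strata are omitted; single-replicate strata are kept but flagged,
  since a lone 0/1 coverage outcome is not a mean. The stratified
  summaries reconcile exactly: unstratified coverage equals the
  stratum-size-weighted mean of stratum coverages (asserted to 1e-12).
- Non-converged fits are excluded from summaries and tallied in an
  `n_excluded` column. Under this generator they are essentially absent;
  failed replicates are recorded, never silently redrawn, which would
  bias the Monte Carlo distribution.

## Variance-component recovery: scale matters

A subtle point the study design surfaces: the REML estimate of σ²ᵤ is
close to mean-unbiased, and truncation of boundary solutions at zero can
only raise its mean — at 3 levels and N = 60 the Monte Carlo mean of
σ̂²ᵤ is ≈ 1.04 (confirmed identically by lme4 on the same datasets). The
"under-estimation with few levels" phenomenon is real but lives on the
**SD scale**, where mixed-model software reports its estimates: by
Jensen's inequality plus the point mass at zero, E[σ̂ᵤ] < 1 (≈ 0.90 at
that cell), and the deficit shrinks as levels grow. The acceptance suite
therefore checks spread recovery on the SD scale, while the records store
the variance-scale estimate; the distribution's 2.5/97.5% quantile
intervals are reported either way and widen sharply below five levels.

## Problem sizes and what the tests show

The acceptance suite runs the full 3 × 3 grid at 2,000 replicates per
cell (master seed 101, ~1 minute single-core); `scripts/acceptance.py`
runs the N = 120, 10-level cell at 2,500 replicates. At these sizes the
Monte Carlo standard error of a coverage estimate is ≈ 0.005, comfortably
inside the ±0.02 bands checked, and mean-recovery checks use 3 Monte
Carlo standard errors. The original 10,000-replicate grid is a CLI flag
away and changes none of the qualitative orderings.

The generator emulates the study conditions exactly — Gaussian response,
independent Gaussian predictors, a single random intercept, moderate
imbalance. Passing tests therefore say nothing about non-Gaussian
responses, random slopes, correlated predictors, severe imbalance, or
grouping factors confounded with covariates; those are out of scope by
design.

## Known limitations

- One random-effect term only; no crossed or nested structures, GLMM
  links, or profile/bootstrap CIs (the Wald/t policy is the only knob).
- Fixed-effect p-values are not computed; the comparison is CI-based.
- The experiment loop is sequential. Seed streams are pre-assigned per
  (scenario, replicate), so a parallel executor would produce identical
  results, but none is shipped: the full grid already fits in desk-scale
  single-core time.
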