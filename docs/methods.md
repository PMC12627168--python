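# Methods

## The proxy likelihood

The drift diffusion model describes a two-choice decision as a noisy
accumulator starting midway between two absorbing boundaries a distance α
apart, drifting at rate ν with unit diffusion coefficient; the response time
is the first-passage time plus a nondecision offset τ.  Evaluating the
Wiener first-passage density is expensive and awkward to embed in larger
models.  This package instead scores each design cell's data through three
summary statistics — the number of correct responses `T_ob` out of `N`
trials, and the mean `M_ob` and unbiased variance `V_ob` of the correct
response times — whose sampling distributions are tractable given the
cell's parameters:

* `T_ob ~ Binomial(R, N)` with `R = logistic(αν)`,
* `M_ob ~ Normal(M, V/N)`,
* `V_ob ~ Gamma((N-1)/2, 2V/(N-1))`, approximated for moderate-to-large N
  by `Normal(V, 2V²/(N-1))`,

where `(R, M, V)` are the closed-form EZ-diffusion predictions.  The
product of the three terms is the proxy likelihood.  Both variance laws are
implemented (`variance_law = "normal_approx" | "gamma_exact"`); the normal
form is the default because it is the headline formulation, and within two
sampling SDs of the prediction the two differ by less than 0.01 nats per
cell at N = 10⁴ (they differ materially only in the far tails or in tiny
cells).

Assumptions inherited from the three-parameter (simple) DDM: unbiased
starting point (α/2), no across-trial parameter variability, and
correct/error RT distributions that coincide — which is why correct-only RT
moments are used (an all-trials variant of `summarize` exists for
robustness checks).  The binomial term always uses the integer count, never
the rate.

### Maximum-likelihood identity

The closed-form inverse-EZ estimators maximise the proxy likelihood
asymptotically: the binomial term peaks when the predicted accuracy equals
the observed rate, and τ frees the mean term to peak exactly.  The exact
joint maximiser's predicted variance is `V_ob (N-1)/N` under the gamma law
(and ≈ `V_ob (1-3/(N-1))` under the normal law) because the mean term's
variance `V/N` also depends on V; the induced coordinate offset is O(1/N)
(about `ν/2N` in drift).  Tests assert agreement to 1e-4 per coordinate at
N = 10⁵, and separately document that the gap at N = 200 stays below 0.05.

A note on the drift estimator: the radicand
`L(R²L − RL + R − ½)/V_ob` (with `L = logit(R)`) equals ν⁴ under the
forward system, so the estimator takes its **fourth root**; the sign is
`sgn(R − ½)`.  The round-trip identity `inverse(forward(ν, α, τ)) =
(ν, α, τ)` holds to machine precision and is tested on a 10×4×3 grid and
as a property test.

### Support

The likelihood returns a `-inf` sentinel (never raises) for proposals with
`α ≤ 0` **or `τ < 0`**.  The τ constraint is the parameter's own physical
support, and it matters numerically: without it the likelihood has an
unbounded ridge (ν → 0, α → ∞ with αν fixed, τ → −∞ absorbing the implied
decision time) that decays only logarithmically, and samplers can wander
into it.  Accuracy rates of exactly 0 or 1 are handled in the *estimators*
(not the likelihood) by the standard `1/(2N)` edge correction.

## Hierarchical model and priors

Individual parameters are draws from normal parents; exactly one criterion
parameter (drift, boundary, or ndt) has its mean shifted by `β·x`.  The
parents are untruncated: at the individual level invalid draws are vetoed
by the likelihood's support sentinel during sampling, while the *simulator*
rejection-resamples below floors (α ≥ 0.01, τ ≥ 0) — two deliberately
different mechanisms for the same constraint, one for inference and one for
generation.

Default priors (all configurable through `PriorSpec`, chosen to span the
empirically plausible ranges for two-choice RT tasks):

| parameter | prior | rationale |
|---|---|---|
| μ_ν | Normal(0, 2²) | drift rates rarely exceed ±4 |
| μ_α | Normal(1.5, 1²) on (0.1, 5) | typical caution range |
| μ_τ | Normal(0.3, 0.25²) on (0, 1) | encoding+motor time < 1 s |
| σ_ν, σ_α, σ_τ | Uniform(0.01, 3) | weakly informative, bounded away from 0 |
| β | Normal(0, 1) | analytic density at 0 for Savage–Dickey |

In within-subject designs each participant contributes one summary cell per
condition; the criterion parameter is drawn independently per cell
(`Normal(μ + β x_cond, σ²)`) while the two non-criterion parameters are
drawn once per participant and shared across that participant's cells (the
same person brings the same caution and motor time to both conditions).

## Simulator

Trials are generated by Euler–Maruyama integration of the diffusion (start
α/2, increment mean ν·dt, SD √dt), absorbed at 0 or α; `rt = τ + steps·dt`.
The scheme is transparent and easily audited; its cost is the O(√dt)
first-passage bias, equivalent at leading order to widening each boundary
by 0.5826·√dt (the Brownian continuity-correction constant).
`discretization_tolerance` converts that widening into per-statistic bias
bounds via the forward equations, with a safety factor of 2.5 for
higher-order terms; simulator-versus-theory tests allow 3 Monte-Carlo SEs
plus this bound.  The default step is dt = 1e-4 s for single-unit
simulation; the study harnesses default to dt = 1e-3 s, which leaves the
covariate-effect (β) conclusions essentially untouched — the discretisation
acts like a small common inflation of every participant's boundary, which
cancels out of contrasts — while making 100-replicate studies affordable.
Hierarchical datasets simulate all participants' trials in one vectorised
batch; parent-draw rejections at the positivity floors are counted and
recorded in the output sidecar.

## Sampler

The posterior is explored by adaptive random-walk Metropolis-within-Gibbs:

* every individual parameter of one kind is proposed and accepted
  elementwise in a single vectorised sweep (exact, because units are
  conditionally independent given the population parameters);
* the seven population scalars get scalar random-walk updates, with the σ
  parameters updated on the log scale with the Jacobian correction;
* three additional *joint* move families handle the slow directions of a
  centred hierarchy: translating a mean together with all its individuals,
  rescaling a σ together with its residuals (the map's Jacobian exactly
  cancels the group-density change, leaving the log-σ term), and tilting β
  together with the criterion cells along the covariate.  Without these the
  μ/σ blocks mix at the narrow conditional scale and R̂ for μ_τ-type
  parameters stays above 1.5 at desk-scale run lengths; with them a
  standard-length run reaches R̂ < 1.01 on every parameter.

Proposal scales adapt toward 0.44 acceptance by stochastic approximation
during warmup only (step t^{-1/2}), so detailed balance holds for retained
draws; population-block proposals are initialised at their conditional
scales (σ/√P, 1/√2P on the log-σ scale, σ/√Sxx for β).  Chains start from
per-cell inverse-EZ estimates (edge-corrected; degenerate cells fall back
to prior medians; initial values are projected into the prior support and
the likelihood support).  Defaults are 4 chains × (2000 warmup + 5000
draws); the study harnesses use 2 × (500 + 1000), which is enough for
β-focused conclusions while σ-type parameters may retain R̂ ≈ 1.05–1.2 at
that length.

Diagnostics are split-R̂ and Geyer initial-monotone-sequence ESS, computed
natively and cross-checked against a reference implementation in the test
suite.  A simulation-based-calibration smoke test (data generated from the
proxy's own sampling laws, truth drawn from the analysis priors) verifies
rank uniformity at the 1% level.

## Studies

`run_recovery_cell` simulates replicate datasets at a given scenario
(criterion × design), refits, and aggregates bias, empirical SD and 95%
central credible-interval coverage of β; `run_grid` crosses P, T, scenarios
and β values with content-hash caching for resumability; replicate seeds
derive deterministically from (base seed, cell hash, replicate index).
`savage_dickey` estimates the posterior density of β at 0 by Gaussian KDE
over pooled draws (plug-in bandwidth), carries a moment-matched normal
estimate as a cross-check, and flags disagreements above 10%.

Desk-scale defaults: 100 replicates per focal cell, 40 for secondary cells;
the full 6-scenario × 25-(P,T) grid at 1000 replicates is expressible but
intended for cluster-scale runs.

## What the generator does and does not emulate

The synthetic data are a faithful hierarchical simple DDM: normal parent
heterogeneity, a single linear covariate effect, unbiased diffusion within
trial.  They do **not** contain contaminant RTs, across-trial parameter
variability, response bias, condition-dependent trial counts, or non-normal
individual differences — so passing recovery tests demonstrates internal
consistency of the method under its own assumptions, not robustness to the
violations real data bring.  Summary statistics use the total trial count N
in the sampling laws while the RT moments come from correct trials only;
for accuracies near the simulated operating range (≈ 0.8) this mild
variance understatement is absorbed into the posterior spread.

## Known limitations and observed behaviour

* **Nondecision-time location bias.**  With the defaults
  (μ_τ = 0.4, σ_τ = 0.05), posterior means of μ_τ sit slightly *above*
  truth (≈ +0.01 to +0.03, shrinking with T): constraining τ to its
  physical support truncates the long left tail of the per-cell
  nondecision-time likelihood at small T.  With a larger between-subject
  spread (σ_τ ≈ 0.15) the opposite, *under*-estimation pattern appears —
  the skewed tails then dominate the partial pooling.  The direction of
  this bias is therefore configuration-dependent; β on the ndt criterion
  remains unbiased (|bias| < 0.01 in the measured cells) either way, which
  is the quantity the method is designed for.
* Posterior SDs of σ-type parameters are only loosely pinned in small
  designs (P ≤ 20), and their chains are the slowest-mixing blocks.
* The proxy model treats the three statistics as independent; the true
  joint sampling distribution under the diffusion has mild dependence
  (accuracy with RT moments), unmodelled here.
* Meta-analytic input (summaries only) is supported, but no publication-bias
  or heterogeneity-of-design corrections are attempted.
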