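# Methods

## SIT household infestation model

Houses move between three stocks — susceptible (S), infested (I), treated
(T) — with total *N = S + I + T* constant:

    dS/dt = -(β/N) S I + γ I + α T
    dI/dt =  (β/N) S I - (γ + τ) I
    dT/dt =  τ I - α T

Transmission is frequency-dependent: the force of infestation (β/N)·I keeps
β's units (per month) independent of community size, and the signs are the
unique choice consistent with dN/dt = 0. Assumptions: stocks are
continuous (fractional houses are allowed — this is a mean-field ODE, not
an agent model), there is no demographic turnover, and rates are constant
in time.

Threshold behaviour follows from linearizing the I equation at the
infestation-free state: R₀ = β/(γ+τ). For R₀ > 1 and α > 0 the endemic
equilibrium is S* = N(γ+τ)/β, I* = (N−S*)/(1+τ/α), T* = τI*/α. With α = 0
the treated class is absorbing, so no positive equilibrium exists and
`endemic_equilibrium` reports absence; `simulate_sit` still integrates the
system and lets T absorb.

**Two-species coupling.** A house infested by one species raises the
neighbourhood's exposure to the other. We model this as a multiplicative
amplification of the force of infestation, (β_k/N)·I_k·(1 + κ_k·I_j/N),
per species k against partner j. This is the minimal form that vanishes
when the partner is absent and reduces exactly to independent systems at
κ = 0; it is a modelling choice, not a mechanistic claim — cross-species
interaction could equally be a compartment transfer, which the package
does not implement. κ defaults to 0.25 and is exposed in every config.

**Integration.** DOP853 (8th-order adaptive Runge–Kutta) with rtol 1e-11
and atol 1e-11·N, sampled on a uniform output grid (default dt 0.1 month,
horizon 24 months). The tight tolerance is deliberate: algebraically
equivalent formulations (a decoupled two-species run vs. two independent
runs) then agree to ~1e-8·N despite different adaptive step sequences,
so exact structural identities can be asserted numerically.

## Parameter inference

Survey aggregates map to rates by the simplest internally consistent
scheme: α = 1/mean control-effectiveness duration, γ = 1/mean
self-recovery duration, τ = fraction of infested households starting
control per month, and β is calibrated so the model's endemic prevalence
I*/N equals the surveyed prevalence (closed-form inversion
β = (γ+τ)/(1 − p(1+τ/α)), rejected as inconsistent when the implied
susceptible stock is non-positive). Zero prevalence falls back to a
below-threshold default R₀ = 0.5.

`fit_sit` minimises Σ_t (I_model(t) − I_obs(t))² over any free subset of
(β, γ, τ, α), on log-parameters so positivity holds by construction, with
a box on monthly rates of [1e-8, 50] (values outside are implausible and
make the ODE stiff). Only I is observed; S and T are latent, initialised
as S(0) = N − I_obs(0), T(0) = 0. The optimizer is Nelder–Mead (maxiter
500, relative objective tolerance 1e-10) whose accepted-iterate objective
path is monotone and recorded, followed by a bounded trust-region
least-squares polish for sharp local convergence; the whole procedure is
deterministic given the initial guess.

**Identifiability.** With I-only data, γ and τ are separated only through
the delayed T→S return: both drain I, but treatment re-exposes houses
after a 1/α lag. The likelihood surface has a near-flat γ/τ ridge. A
local Fisher-information analysis at the canonical truth (β=0.5, γ=0.1,
τ=0.2, α fixed, 24 monthly observations, 5% multiplicative noise) gives
standard errors of roughly 0.8, 7.3 and 1.7 on log β, log γ and log τ,
with pairwise correlations ≈ ±0.999. Noise-free series are therefore
recovered essentially exactly (the ridge has a unique bottom), but under
realistic observation noise individual γ and τ estimates are unreliable —
fits slide along the ridge, often to a boundary. The practical remedy the
package supports is fixing more parameters at survey-derived values via
`fixed=`; combinations such as β+τ with γ and α fixed are well
identified. This limitation is a property of the observation design, not
of the optimizer.

## Habitat suitability workflow

**Collinearity filter.** Pairwise Pearson |r| over non-masked cells;
while any pair exceeds the threshold (default 0.7), the member of the
worst pair with the larger mean |r| against all other retained layers is
dropped (ties: lexicographically later name), deterministically. Constant
layers are dropped with a warning.

**Learner.** A penalized logistic regression (L2, C = 1, lbfgs) on
standardized linear + quadratic covariate features, contrasting presence
cells against background cells sampled uniformly from non-masked,
non-presence cells (default 10× the presence count). Balanced class
weights make the output probability correspond to a 50% presence prior,
so scores use the full [0, 1] range regardless of the
background-to-presence ratio and fixed thresholds are meaningful. This is
a deliberately simple, pluggable stand-in for a full maximum-entropy
learner: it captures unimodal (quadratic) responses but not interactions,
hinges or the MaxEnt regularization path. `SuitabilityModel` is an opaque
scorer, so a different learner can be slotted in behind the same
train/predict interface.

**Validation.** The rank AUC is computed by exact pair counting
(presence > background counts 1, ties count ½) via sorted search —
identical to brute-force enumeration, threshold-independent. The
sub-sample ensemble repeats a 70/30 presence split three times (all
defaults overridable), trains on each 70%, computes a test AUC on the
held-out 30% against a fresh background sample, and averages the
replicate rasters cellwise. The jackknife retrains with each variable
alone and with each variable omitted, sharing one split and one
background pair across variables so the AUCs are comparable.

**Classification and overlap.** Scores are classified into five
equal-interval bands ([0,0.2) very low … [0.8,1] very high; breakpoints
are a convention, exposed nowhere because the band edges are definitional).
Binarization uses score ≥ threshold with default 0.4 ("moderate or
better"), exposed as a flag. Co-suitability of two species is the cellwise
conjunction of their binary maps, summarised by the Jaccard index
|U∩V|/|U∪V| over valid cells; an empty union is an error, not 0.

## Synthetic data

All inputs are generated with known ground truth; a single global seed
fans out to named components through
`SeedSequence(seed, spawn_key=(component,))`, so each generator is
independently reproducible.

- **Surveys**: 4 counties × 100 households by default, mirroring a
  400-respondent interview design. Infestation per species is Bernoulli
  at the endemic prevalence implied by per-county true rates (a coastal
  high-infestation county dominated by one species, a capital with
  coexistence, two inland counties dominated by the other species at low
  intensity; shared γ=0.1, τ=0.2, α=0.25, per-county β between 0.33 and
  0.70). Durations are exponential with means 1/α and 1/γ; summaries are
  exact aggregates of the records.
- **Prevalence series**: I_obs(t) = I_model(t)·exp(ε_t),
  ε_t ~ N(0, σ) with σ = 0.05 by default — multiplicative, mean-zero in
  log, exact at σ = 0.
- **Environmental stacks**: per layer, white Gaussian noise smoothed by a
  moving-average kernel (width = autocorrelation length, default 5 cells,
  wrap-around edges), standardized to mean 0/variance 1; layers are
  mutually independent. Default 100×100 grid, 5 layers named temp,
  humidity, pop_density, elevation, landcover.
- **Planted truth**: suitability = logistic(intercept + Σ w_l·layer_l).
  Default weights 2.5/1.0/1.0 on temp/humidity/pop_density (species a) and
  1.0/2.5/1.0 (species b); zero weights elsewhere. The intercept defaults
  to −4.0, making the suitable niche rare (~11% of the landscape). The
  rarity matters: occurrences are sampled proportionally to suitability,
  and if half the landscape were suitable, presence and background scores
  would overlap so heavily that no model could exceed AUC ≈ 0.75; a rare
  niche is both the realistic regime for a species distribution and the
  one in which AUC is informative (Bayes-optimal ≈ 0.88 at these
  defaults).
- **Occurrences**: 200 cells drawn with probability proportional to true
  suitability, points at cell centers. Smooth size-biased sampling, not
  thresholded presence/absence.

What the generator does **not** emulate: real geography or climate
(layers are isotropic stationary noise, real covariates have trends,
ranges and cross-correlations), spatial sampling bias in occurrences,
survey non-response or misreporting, and any temporal change in the
environment. Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted structure — not predictive skill
on real African distribution data.

## Problem sizes and numerical choices

Default study sizes — 100×100 grids, 200 presences, 2000 background,
3 replicates, 20-seed Monte-Carlo repetitions, 240-month dynamics runs —
keep every stage to seconds on one CPU while leaving Monte-Carlo
standard errors well inside the asserted margins. Degenerate inputs fail
loudly: zero-variance layers are dropped with a warning (filter) or
rejected (learner, fewer than two distinct presence covariate vectors),
all-zero suitability cannot be sampled, empty train/test splits and empty
Jaccard unions are errors. Occurrence points on nodata cells or outside
the grid are rejected at snap time with a logged count.

## Pipeline

`run_pipeline` executes selected stages in fixed dependency order
(synth → simulate/fit and synth → filter-vars → train → overlap), writes
all artifacts (CSV tables, ASCII-grid rasters, JSON reports) plus a
manifest containing the full config, a config hash, the seed and every
stage metric. Metrics live only in the manifest; logs are for humans.
Rerunning the same config reproduces identical metrics. Requesting a
stage whose upstream artifact is missing raises an error naming the stage
to run first.
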