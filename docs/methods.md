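# Methods

## Setting and estimands

Consider a randomized (or suitably adjusted observational) study sample of
size N partitioned into G mutually exclusive subgroups v_1, …, v_G defined by
baseline covariates, with binary treatment A and outcome Y. Write

* τ_g = E[Y(1) − Y(0) | X ∈ v_g, S = 1] — the subgroup sample ATE,
* p_g = P(X ∈ v_g | S = 1) — the subgroup's sample representation,
* β = p′τ — the sample ATE (SATE).

When only β̂ is reported, its mean squared error as an estimate of a
*subgroup's* effect is

    R(τ_g, β̂) = σ²_β̂ + ((e_g − p)′τ)² = σ²_β̂ + (τ_g − β)²,

variance plus the squared gap between the subgroup effect and the weighted
average. Averaging over a prior π on τ (only the second moment
M = E[ττ′] = Σ_τ + μ_τμ_τ′ is needed) gives the Bayes risk; the package's
inequity measure is the difference in Bayes risk between two subgroups,

    Δ_ij(θ̂_i, θ̂_j) = E_τ[R(τ_i, θ̂_i) − R(τ_j, θ̂_j)].

Under an exchangeable prior — invariant to permuting subgroup labels, with
φ² = var(τ_i − τ_j) for i ≠ j — this collapses, for the shared SATE estimate,
to Δ_ij = φ²(p_j − p_i): the less-represented subgroup carries the larger
average risk, linearly in both the representation gap and the heterogeneity
variance. For unbiased subgroup-specific estimators the inequity is instead
σ_i² − σ_j², the variance gap, which again disadvantages small subgroups.
Both formulas are implemented (`inequity_sate`, `inequity_exchangeable`,
`inequity_unbiased`) together with the pointwise risk (`risk_sate`).

## Representation-adjusted ATEs

The representation-adjusted ATE (RATE) for subgroup g is the ATE in a
pseudo-sample whose subgroup composition q_g = (q_g1, …, q_gG) has been
chosen to estimate τ_g well: η_g = Σ_k q_gk τ_k, estimated by η̃ = Q τ̂ for a
row-stochastic weight matrix Q and any vector of unbiased subgroup estimates
τ̂ with covariance Σ. Two constructions:

* **Optimal weights** (`optimal_weights`) minimize each subgroup's Bayes risk
  separately under the exchangeable prior:

      q_g = (1 − 1′Ωe_g)(1′Ω1)⁻¹ Ω1 + Ωe_g,   Ω = φ²(2Σ + φ²I)⁻¹.

* **Shared weights** (`shared_weights`) constrain every pseudo-sample to one
  composition, q_g = w e_g + (1 − w)(1 − e_g)/(G − 1), and minimize the
  subgroup-averaged Bayes risk, giving w = 1/(1 + γ) with

      γ = (σ̄²(G − 1) − V₁) / (φ²G/2 + V₂/(G − 1) − V₁),

  σ̄² the mean estimator variance, V₁ = G⁻¹Σ_g e_g′Σ(1 − e_g),
  V₂ = G⁻¹Σ_g (1 − e_g)′Σ(1 − e_g).

Inference uses Σ_η̃ = QΣQ′ with normal-quantile Wald intervals (the exact 95%
quantile 1.959964 is used throughout, including when standard errors are
recovered from published CIs as width/(2z)). Σ is the estimated covariance
plugged in as fixed; its own sampling uncertainty is not propagated.

In the uncorrelated case the optimal construction equals the posterior means
of a normal hierarchical model with fixed hypervariance φ²/2 and a flat
hypermean prior (`hierarchical_shrinkage_oracle`); the test suite verifies
this identity to 1e−10 on randomized instances, which guards the matrix
algebra with an independent scalar derivation.

## The heterogeneity hyperparameter φ

φ = SD(τ_i − τ_j) is specified by the analyst, not estimated: φ = 0 pools
completely (all rows of Q collapse to a common weighting), φ → ∞ stratifies
(Q → I), intermediate values trade bias for variance. `popoviciu_phi_bound`
elicits an upper bound φ ≤ c/2 from a substantive bound c on how much any two
subgroup effects can differ (Popoviciu's variance inequality).
`phi_sensitivity` tabulates a fit over a φ grid; self-weights are
nondecreasing in φ.

## Numerical choices and degenerate cases

* φ = 0 in the optimal construction is a 0/0 form; it is evaluated through
  its analytic limit, the GLS pooling row Σ⁻¹1/(1′Σ⁻¹1) repeated G times
  (inverse-variance weights when Σ is diagonal). This requires nonsingular Σ.
* (2Σ + φ²I) is symmetric positive definite for φ > 0, and is inverted with
  an SPD solve; no regularization is added.
* With correlated estimators the optimal rows can contain entries outside
  [0, 1]. They are returned unclipped — clipping would break the optimality
  derivation — with a prominent warning, and still sum to one ("generalized
  weights").
* γ ≥ 0 and a positive γ denominator are guaranteed for any positive
  semidefinite Σ (off-diagonal mass cannot exceed σ̄²(G − 1)); the clamp of a
  negative γ to identity weights, and the regularity error for a nonpositive
  denominator, are defensive paths reachable only with degenerate inputs.
* Representation vectors whose entries sum to within 0.01 of 1 (published
  rounded percentages) are renormalized with a logged warning; larger
  deviations are errors.
* A single subgroup (G = 1) makes every inequity identically zero; the
  functions warn and return 0 rather than erroring.
* The covariance of the outcome-model (g-computation) estimator has no closed
  form for generic arm models; a nonparametric bootstrap over records
  (default B = 1000, seeded) is used, holding the fitted arm models fixed —
  it reflects the averaging step only, not model-refitting variability.

## Synthetic-trial generator

`simulate_trial` emulates a two-arm randomized trial with fixed subgroup
counts: n_total = 300 split by largest-remainder rounding of the
representation vector (75/15/10% for three groups → 225/45/30; 67/15/10/5/3%
for five groups → 201/45/30/15/9), a random within-subgroup permutation of
treatment with arms as equal as possible (for odd counts the extra record
lands in either arm with probability ½), and outcomes

    Y = 1 + β_G A + 2·1{G ∈ {1, 3}} + X₁ + 2.5 X₂ + ε,

X₁ ~ N(1, 1), X₂ ~ Bernoulli(0.3), ε ~ N(0, 1), all independent. Subgroup
effects are i.i.d. draws from one of three families — standard normal;
a bimodal mixture 0.8·N(0.5, 1) + 0.2·N(−3, 0.5); Gamma(3, 3) — affinely
rescaled about the family mean so that var(τ_g) = φ²/2 and hence
SD(τ_i − τ_j) = φ (default target φ = 1). The mixture's second parameters are
read as variances (raw mixture variance 2.86); a spec switch gives the SD
reading. Randomness flows from one master seed through `SeedSequence` spawns
per effect draw and per trial, so results are bit-reproducible and individual
replicates can be regenerated in isolation.

What the generator does *not* emulate: covariate-dependent treatment effects
within subgroups, non-normal or heteroscedastic outcome noise, missingness,
and non-random sampling into the study. Passing tests therefore demonstrate
correctness of the estimators under a clean randomized design, not robustness
to those real-data features.

## Estimator-comparison harness

`run_simulation` crosses effect draws with simulated trials (defaults
500 × 500; the packaged tests use 50 × 100, which reproduces the qualitative
orderings in a few tens of seconds on one CPU) and reports per-subgroup RMSE
against the drawn effects, one RMSE per effect draw, summarized by quartiles;
`cumulative_percentile_trace` tracks running 25th/50th/75th percentiles to
confirm stabilization. All estimators are applied to the same trials (paired
comparison). The default registry: stratified difference-in-means (Welch
variances); the treatment-by-subgroup interaction regression; a shrinkage
comparator (`hierarchical_shrinkage_oracle` at a fixed prior variance — a
closed-form stand-in for a random-effects model, with the heterogeneity
variance specified rather than estimated); optimal-weights adjustment at
φ ∈ {0.75, 1, 1.5} (under-, correctly-, and over-specified); and
shared-weights adjustment at φ = 1. The representation-adjusted estimators
reuse the interaction-model estimates and covariance.

By default the interaction comparator is the saturated treatment-by-subgroup
model *without* X₁/X₂ adjustment, so all comparators share one precision
scale and the comparison isolates the effect of the representation
adjustment itself; adjusting for the covariates (available via
`SimulationConfig(adjust_covariates=True)`) cuts the residual variance from
3.31 to 1.0, which shrinks every standard error and with it both the benefit
of borrowing strength and the penalty of the shared constraint.

## Known limitations

* Difference-scale effects only; ratio scales would require adjusting
  potential-outcome means separately.
* Full exchangeability of subgroup effects; no partial-exchangeability
  structure.
* Within-sample generalization only: τ̂ may be replaced by target-population
  subgroup estimates, but no transport machinery is provided.
* φ is a fixed input; nothing in the package estimates it from the data.
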