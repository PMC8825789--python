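# Methods

## The model

Food-group intake from repeated 24-h dietary recalls is semicontinuous: a
large spike at zero (no consumption that day) and a right-skewed positive
part. For a participant *i* on recall day *j*, with design row
*x*<sub>ij</sub> = (1, meat, sex, meat×sex) where meat is the day's total
meat consumption in g/2,000 kcal and sex is coded 0 = female / 1 = male,
the package fits the correlated two-part ("mixed distribution")
mixed-effects model

- **probability part** — logit P(Y<sub>ij</sub> > 0 | u<sub>1i</sub>) =
  x′<sub>ij</sub>β₁ + u<sub>1i</sub>,
- **amount part** — log Y<sub>ij</sub> | Y<sub>ij</sub> > 0, u<sub>2i</sub>
  ~ N(x′<sub>ij</sub>β₂ + u<sub>2i</sub>, σ<sub>e</sub>²),

with person-level random effects (u₁, u₂) jointly normal with SDs
(σ<sub>u1</sub>, σ<sub>u2</sub>) and covariance σ<sub>u12</sub>. The
covariance links how *often* a person consumes with how *much* they consume
per occasion; σ<sub>e</sub>² is the within-person day-to-day variance of
log amount. The marginal likelihood integrates (u₁, u₂) out per person.

The **uncorrelated variant** fixes σ<sub>u12</sub> = 0. It is selected when
the data cannot identify the correlation: only participants with
*discordant* days (consumed on one recall, not the other) inform it, so
`select_variant` falls back to the uncorrelated model when the discordant
fraction is at or below a floor (default 2%, configurable), or when the
correlated fit fails to converge to a positive-definite Hessian. Food
groups where *no* day (or every day) shows consumption degenerate further:
the affected part carries no information, `fit` raises a `SeparationError`,
and the pipeline refits the single active part (`parts="amount"` or
`parts="probability"`) instead of aborting the batch.

## Likelihood evaluation and estimation

The 2-D random-effect integral is evaluated by Gauss–Hermite quadrature
after Cholesky-standardizing (u₁, u₂), 15 nodes per dimension by default.
Two rules are used, intentionally:

- **Optimization** uses the *prior-standardized* (non-adaptive) rule. It is
  deterministic, smooth in the parameters, and admits exact analytic
  gradients (posterior node weights per person, chain-ruled through the
  Cholesky factor), which L-BFGS-B needs to converge quickly and
  reproducibly.
- **Likelihood evaluation** (`person_loglik`, `dataset_loglik`) defaults to
  *adaptive* quadrature: a few vectorized Newton steps locate each person's
  posterior mode of the standardized effects, the rule is recentred and
  rescaled by the local curvature, and 15 nodes then agree with brute-force
  grid integration to below 1e-6 even when the integrand sits far from the
  prior mode. (The non-adaptive rule is accurate to roughly 1e-3 in such
  cases — adequate inside the optimizer, where only differences matter, but
  not as a reference value.)

Estimation maximizes the summed person log-likelihoods on an unconstrained
scale: log σ for the three SDs and atanh ρ for the correlation, with box
constraints log σ ∈ [−8, 4], atanh ρ ∈ [−4, 4] for numerical safety.
Because the meat covariate lives on a ~100 g scale, the exposure design
columns are standardized internally during optimization and the estimates
and covariance mapped back exactly afterwards; without this the optimizer
is badly conditioned. Starting values come from the factorized
(zero-variance) model — a logistic GLM for β₁ and OLS on log grams among
consumers for β₂ and σ<sub>e</sub> — with random-effect variances started
at 0.5 and ρ at 0.

The parameter covariance is the inverse observed information (central-
difference Hessian of the negative log-likelihood at the optimum),
reported on the unconstrained scale (used by the bootstrap) and propagated
to the natural scale (σ's and σ<sub>u12</sub>) by the delta method. The
`converged` flag requires both optimizer success and a positive-definite
Hessian; a fit that is not converged is returned with diagnostics, never
silently accepted.

## Prediction

Population meat quartiles are empirical quartiles of the person-level mean
energy-standardized exposure over the *total* population (all ages pooled),
using the (n+1)p order-statistic rule with linear interpolation — on the
integers 1..100 the cutpoints are 25.25/50.5/75.75. The model plays no role
in defining quartiles. A day-level quartile basis is available by config.

The predicted intake at a covariate profile (a quartile's mean exposure, a
sex) is Monte-Carlo: draw 10,000 random-effect pairs from the fitted
covariance (jointly for the correlated variant, independently for the
uncorrelated one), form per draw

- probability = odds/(1+odds) with log odds = x′β̂₁ + u₁,
- amount = exp(x′β̂₂ + u₂ + ½σ̂<sub>e</sub>²)  (log-normal mean
  back-transformation),

and average the per-draw *products*. Averaging products rather than
multiplying averaged components is what lets the random-effect correlation
show up in the predicted intake (with ρ > 0, intake exceeds
probability × amount of the means). The Monte-Carlo standard error of the
intake is reported. One master seed drives everything through named
substreams hashed from (seed, age group, food group, …), so adding a
profile or food group never perturbs other results; the draws are shared
across the eight profiles of one food group (common random numbers), which
smooths quartile contrasts.

`true_marginal_intake` computes the same three quantities by deterministic
trapezoid integration over the standardized random-effect plane with
step-halving to 1e-8 — the independent target that the Monte-Carlo
predictor and the estimation chain are tested against.

The association summary is the relative difference
(intake at Q4 mean − intake at Q1 mean) / observed mean intake of the
age-sex group; probabilities convert to expected consumption days per week
as 7p.

## Confidence intervals

Parametric bootstrap: 1,000 parameter vectors are drawn from
N(θ̂, Cov̂(θ̂)) *on the unconstrained scale*, where the normal approximation
is defensible and every draw maps back to valid parameters (positive
variances, |ρ| < 1). Draws are additionally clipped to the optimizer's box
constraints before mapping back: with weakly identified fits the covariance
can be enormous in the variance directions, and unclipped draws overflow;
clipping keeps every replicate evaluable, and the resulting intervals are
honestly wide. Each replicate reruns the full Monte-Carlo prediction with
fresh random-effect draws; the 2.5/97.5 empirical percentiles (same
order-statistic rule as the quartiles) form the 95% interval. Replicates
yielding non-finite intakes are dropped, with an error if more than 1%
are.

## Synthetic data

The generator draws from exactly the model the analysis assumes, with known
truth, emulating the structure of a national food-consumption survey:
four age groups (1–8, 9–18, 19–50, 51–79 years), ~equal sex split, exactly
two recall days per participant, per-participant meat exposure drawn
log-normally with age-group means/SDs of 65±53, 89±70, 92±75 and 98±74
g/2,000 kcal, and day-level energy drawn log-normally around 1,405, 2,124,
2,277 and 2,056 kcal. The six default food-group truths span the regimes
such surveys exhibit — episodic groups whose consumption probability falls
steeply with meat exposure (fish, nuts), staples that rise with it
(potatoes, vegetables), and a near-daily group (~99% day-level probability)
that exercises the uncorrelated fallback. Exposure is held constant across
a participant's days by default so that analytic truth values are
well-defined (a day-varying option adds log-normal day noise); energy is
generated independently of food-group amounts.

What the generator does *not* emulate: real surveys have item-level
reporting mapped through a food-composition database, correlated intakes
across food groups, survey weights, misreporting, and day-level exposure
measured with error. Passing tests therefore demonstrate that the
estimation/prediction/bootstrap chain is correct *under the model's own
assumptions*, not that the model is correct for any real survey.

## Numerical choices and problem sizes

- Quadrature: 15 nodes/dimension default (configurable); the test-suite
  simulation studies use 7–9 nodes where speed matters, which changes
  estimates by far less than a standard error at those sample sizes.
- Optimizer: L-BFGS-B, ftol 1e-12, projected-gradient tol 1e-6, max 500
  iterations.
- σ<sub>e</sub> is floored at 1e-6 to guard the likelihood against
  degenerate residual variance.
- Amount-part exponents are clipped at 300 before exponentiation (with a
  warning outside the bootstrap) so products and their variances stay
  finite.
- Validation studies: parameter recovery uses 50 replicates of 1,000
  participants × 2 days; bootstrap coverage uses 200 replicates of 500
  participants with 200 bootstrap draws of 2,000 prediction draws each;
  the acceptance script runs 250 participants per age group with 4,000
  prediction draws and 200 bootstrap replicates.

## Known limitations

- One food group at a time; no cross-food-group correlation.
- Covariates fixed to (meat, sex, meat×sex); no additional confounders.
- Mean predicted intake only — no usual-intake distribution percentiles.
- The parametric bootstrap perturbs parameters, not data; it does not
  capture misspecification of the random-effect distribution.
- With two recall days, the consumption probability of rarely consumed
  groups is weakly identified; tiny strata can legitimately fail the
  correlated fit and fall back (flagged in the manifest).
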