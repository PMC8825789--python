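# twopart-intake

Correlated two-part mixed-effects modelling of episodically consumed food
groups from repeated 24-h dietary recalls.

## The problem

Day-level food-group intake from recall surveys is semicontinuous — many
zeros (no consumption that day) and a skewed positive part — and people who
consume a food *more often* may also consume *more of it* per occasion.
With two recall days per participant, naive averaging attenuates exactly
the frequency/amount structure a dietary-pattern analysis is after. This
package is for nutritional epidemiologists who want to separate the
**probability** of day-level consumption from the **amount** among
consumers, relate both to a continuous exposure (here: total meat
consumption in g/2,000 kcal), and propagate estimation uncertainty into
population-level predicted intakes.

## The model

For participant *i*, recall day *j*, food-group intake Y<sub>ij</sub> and
design row x<sub>ij</sub> = (1, meat, sex, meat×sex):

```
logit P(Y_ij > 0 | u_1i)            = x_ij' β₁ + u_1i
log Y_ij | Y_ij > 0, u_2i           ~ N(x_ij' β₂ + u_2i, σ_e²)
(u_1i, u_2i)                        ~ N₂(0, [[σ_u1², σ_u12], [σ_u12, σ_u2²]])
```

The person-level random effects u₁ and u₂ are correlated, linking
consumption frequency to per-occasion amount; σ<sub>e</sub>² is the
within-person day-to-day variance. The marginal likelihood (random effects
integrated out by Gauss–Hermite quadrature) is maximized per food group and
age group; when near-universal or near-absent consumption leaves the
correlation unidentified, an uncorrelated variant (σ<sub>u12</sub> = 0) is
selected automatically.

Predicted intake at a covariate profile is Monte-Carlo: 10,000 random-
effect draws, per draw probability = odds/(1+odds) and amount =
exp(x′β̂₂ + u₂ + ½σ̂<sub>e</sub>²), intake = mean of the per-draw
probability×amount products. 95% intervals come from a parametric
bootstrap (1,000 parameter redraws from the estimate covariance).
Profiles are the four population meat-quartile means by sex; the headline
association summary is (intake at Q4 − intake at Q1) / group mean intake.

Since national recall microdata are available only on request, the package
ships a synthetic-data generator that draws from exactly this generative
model with known truth (four age groups, two recall days, realistic meat
exposure and energy scales), so the whole chain is testable end to end.
See `docs/methods.md` for the full account.

## Worked example

```python
import twopart_intake as tpi

study = tpi.generate_study(tpi.PopulationConfig(n_participants=250, seed=7))
spec, labels = tpi.build_meat_quartiles(study.data)

cheese = study.data[(study.data.age_group == "51-79")
                    & (study.data.food_group == "cheese")]
fit = tpi.fit(cheese, variant="auto")

q1 = tpi.CovariateProfile(spec.quartile_means[0], sex=1)
q4 = tpi.CovariateProfile(spec.quartile_means[3], sex=1)
p1 = tpi.predict_intake(fit, q1, n_draws=10_000, seed=1)
p4 = tpi.predict_intake(fit, q4, n_draws=10_000, seed=1)
iv = tpi.bootstrap_ci(fit, q1, n_boot=1000, n_draws=10_000, seed=2)
```

which prints (via the obvious f-strings):

```
quartile means (g/2,000 kcal): [29.6, 55.1, 88.3, 171.9]
variant=correlated  converged=True  rho=0.20  sigma_u1=1.33  sigma_e=0.50
Q1: probability=0.637  amount=35.6  intake=23.8
Q4: probability=0.405  amount=35.7  intake=15.6
Q1 95% CI: [17.4, 32.1]
group mean = 21.4; relative difference (Q4-Q1)/mean = -0.38
Q1 weekly cheese days: 4.46
```

Read: men aged 51–79 at the lowest meat-quartile mean (29.6 g/2,000 kcal)
consume cheese on ~64% of days (≈ 4.5 days/week), ~36 g/2,000 kcal per
consuming day, for a predicted intake of 23.8 g/2,000 kcal (95% CI
17.4–32.1); at the highest meat quartile predicted intake drops to 15.6.
The negative relative difference (−0.38) says cheese consumption is higher
where meat consumption is low. The generator's analytic truth at the Q1
profile is (0.558, 38.0, 23.0) — inside the interval.

A command-line interface wraps the same steps:

```sh
twopart-intake simulate --n-participants 250 --seed 7 --out recalls.csv
twopart-intake fit --data recalls.csv --food-group cheese --out fit.json
twopart-intake predict --fit fit.json --exposure 29.6 --sex 1
twopart-intake ci --fit fit.json --exposure 29.6 --sex 1 --boot 1000
twopart-intake run --config config.yaml     # full fit→predict→CI pipeline
```

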