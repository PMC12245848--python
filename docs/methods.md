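# Methods

This note documents the models implemented in `hmburden`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Valuation (`hmburden.valuation`)

The benefit transfer scales the US value of a statistical life (VSL) by the
ratio of gross national incomes per capita (PPP) raised to an income
elasticity. Parameters (`VslParams`):

| parameter | default | unit | rationale |
|---|---|---|---|
| `vsl_us` | 11.23e6 | 2021 US$ | the 2015 HHS estimate ($9.4M, 2015 US$) inflated to 2021 prices |
| `gnipc_us` | 66,080 | intl$ per capita | US GNI per capita, PPP, 2019 (the transfer reference year) |
| `elasticity_hic` / `elasticity_non_hic` | 1.0 / 1.5 | — | the standard benefit-transfer convention: unit elasticity in high-income settings, 1.5 elsewhere. The 1.5 value is applied to all of UMIC, LMIC and LIC; the low/middle-income convention does not distinguish them |
| `floor_multiple` | 20 | × GNIpc | minimum VSL where the power transfer would otherwise produce implausibly low values |
| `discount_rate` | 0.03 | per year | standard health-economic discounting of future money |
| `base_year` | 2021 | — | all burden is expressed in 2021 international dollars |

The VSLY divides the (floored) VSL by the remaining period life expectancy
at the population median age — *without* discounting; the 3% rate applies
only when money moves across calendar years. Keeping the two rules in
separate operations (`vsly_from_vsl` vs `discount_to_base`/`cpi_adjust`)
prevents double discounting. In `build_vsly_table` the transfer ratio uses
each country-year's own GNIpc over the fixed US reference GNIpc, so the
VSLY evolves with national income — this is what makes valuation a driver
of burden change in the decomposition. Income classification is frozen at
the panel's final classification year (2021), including for projections.

Note the transfer is discontinuous at the HIC boundary when the two
elasticities differ; this is a property of the method, not a bug.

## Burden accounting (`hmburden.burden`)

One DALY = one VSLY. Monetization propagates the DALY uncertainty interval
multiplicatively and treats the VSLY as fixed; the ±20% VSLY variation
belongs exclusively to the bootstrap, so the two uncertainty channels are
never double-counted. Quintile maps use inclusive linear-interpolation
percentiles at 20/40/60/80 with ties resolved to the lower bin in stable
input order; fewer than five distinct values is a degenerate input and an
error rather than a silent 1-bin map.

## Shapley decomposition (`hmburden.decomposition`)

The burden identity `C = Σ_a P·s_a·r_a·V` maps the four named drivers onto
factors: population growth = P, aging = s, epidemiological change = r,
valuation = V. This is the canonical three-factor demographic
decomposition of a rate-times-population quantity, extended by the
valuation factor; it reproduces the grouped report structure
(VSLY + DALYs = 100%; DALYs = growth + aging + epidemiology). Shapley
contributions are computed exactly by the subset-weighted formula (2^4
cost evaluations); the permutation-enumeration form is kept as an
independent oracle and the two are cross-checked on random instances in the
tests. Percentages are signed; aggregation sums absolute country
contributions and re-derives global percentages from the sums. When
country totals cancel (global change ≈ 0) percentages are undefined and
the result is flagged degenerate rather than returning ±∞.

Decomposition operates throughout in 2021 international dollars.

## Projection (`hmburden.projection`)

**Scenarios** are pure multipliers anchored at 2021: baseline 1.00/yr,
negative 1.01/yr (rates rise), positive 0.99/yr. They commute with
aggregation over ages at fixed population.

**BAPC.** Poisson counts with log-linear age + period + cohort effects,
cohort index k = (A−1−i) + j. Smoothing: RW2 (second-difference) priors on
all three effect vectors with precision τ_e; τ_e carries a Gamma(1, 5e-5)
prior (equivalently inverse-gamma on the variance), the conventional
diffuse default. Identifiability: sum-to-zero constraints on α, β, γ plus
a zero-linear-trend constraint on γ, which assigns the shared drift to the
period (and age) effects; the synthetic truth generator applies the same
constraints, leaving the linear predictor invariant, so simulation-recovery
comparisons are well defined.

Inference is an empirical-Bayes Laplace approximation rather than INLA or
MCMC: penalized-likelihood Newton iterations (with step halving) find the
latent mode under the current precisions; an EM step updates each precision
from the posterior quadratic form `E[u'Ru] = m'Rm + tr(R Σ)`; the loop runs
to a 1e-3 relative precision tolerance (hard failure, with trace, beyond
200 outer iterations). Posterior summaries are Gaussian at the mode. The
choice keeps the engine self-contained, deterministic and fast (a 10×20
grid fits in ~20 ms), at the cost of ignoring hyperparameter uncertainty —
credible intervals are therefore slightly narrow, a known property of
plug-in Laplace summaries.

Forecasts use the RW2 predictive in closed form: the mean continues the
terminal linear trend of the period (and, for unseen cohorts, cohort)
effect; the log-rate variance adds `h(h+1)(2h+1)/6 · τ⁻¹` innovation
variance at horizon h to the posterior covariance of the terminal effects.
Interval width is measured (and guaranteed monotone in horizon) on the
log-rate scale; rate-scale bands are log-normal quantiles. Cohort
extrapolation beyond a configurable bound (default: the fitted period
count) is refused. Scenario and BAPC engines are alternatives, never
multiplied together.

## Bootstrap (`hmburden.uncertainty`)

Per replicate, each cell's DALYs are drawn from a normal within its 95%
uncertainty interval — sd = (upper − lower)/(2·1.959964) — truncated at
zero (DALYs cannot be negative), and its VSLY from the ±20% band. "Varied
by ±20%" is implemented as uniform sampling on [0.8, 1.2]·VSLY, which
yields proper percentile intervals; a two-endpoint mode
(`vsly_mode="endpoints"`) reproduces the min/max sensitivity variant.
Draws are independent across country-year-cause cells (no correlation
structure is specified for the inputs). Intervals are empirical 2.5/97.5
percentiles over 1,000 replicates by default, stratified by income group,
fully reproducible from the seed.

The calibration experiment (`coverage_experiment`) plants truth, observes
it exactly under this error model, and measures how often the interval
covers the true burden. At the scaled-down setting used in the tests and
the acceptance script (500 worlds × 200 replicates × 24 cells) measured
coverage is ≈94%: the small shortfall from the nominal 95% is the expected
finite-replicate noise of percentile quantiles at 200 draws.

## Synthetic worlds (`hmburden.synthetic`)

Defaults mirror the study conditions: 204 country-like units, years
1990–2021, twenty 5-year GBD-style age bands (open-ended 95+ band given a
nominal 10-year width so a midpoint exists), four subtype causes with DALY
weights ≈ 0.43/0.33/0.17/0.07 (leukemia/NHL/MM/HL), and an income mix of
0.30/0.25/0.25/0.20 over HIC/UMIC/LMIC/LIC. Per country: geometric GNIpc
growth drawn from −1%…+6%/yr; CPI inflation 1–2.5%/yr (HIC) or
1.5–4.5%/yr (others), kept below typical nominal income growth so real
incomes mostly rise; an exponential age pyramid whose decay parameter
shrinks over time (aging); life expectancy improving 0.08 yr/yr. Crude
all-subtype DALY rates target 0.25% (HIC) down to 0.10% (LIC) of
person-years — at the default world this yields ≈18M global DALYs in 2021,
the right order of magnitude for these cancers. Income groups are assigned
by package-defined PPP GNIpc thresholds (4,500 / 12,500 / 30,000 intl$)
that echo the World Bank scheme's ordering, and frozen at the 2021
classification.

Rate truth follows the same APC structure the projection module fits, so
simulation recovery is well specified. Smooth random effects are
doubly-integrated white noise rescaled to a fixed standard deviation
(raw double integration drifts like n^1.5 and would imply implausibly
steep terminal trends). Uncertainty intervals are symmetric multiplicative
bands, default half-width 15% of the point estimate — a typical cancer-DALY
interval width — chosen so the normal-resampling bootstrap is exactly
calibrated by construction.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: asymmetric GBD uncertainty intervals and their
draw-level correlation across cells; sex stratification; country-specific
data-quality artifacts and the "borrowing of strength" smoothing of the
real estimation pipeline; migration and cohort-size shocks in demography;
PPP revisions and income-group reclassification over time.

## Problem sizes

The default test and acceptance runs use deliberately modest sizes chosen
to exercise every code path at full statistical fidelity: 10–12 country
worlds for pipeline tests, a 10×20 grid at exposure 1e5 for BAPC recovery,
100 random instances for the Shapley oracle, and 500 worlds × 200
replicates for bootstrap calibration. The analysis drivers run the full
204-country, 32-year, 20-band world.

## Known limitations

* The Laplace/EM engine underestimates posterior spread relative to a full
  hierarchical treatment (no hyperparameter uncertainty).
* Percentile bootstrap intervals at 200 replicates are mildly
  anticonservative (≈94% measured vs 95% nominal); 1,000 replicates (the
  default) narrows the gap.
* The VSLY treats remaining life years as homogeneous across ages within a
  country-year; no cohort life tables.
* Burden bounds propagate DALY uncertainty only; valuation uncertainty
  enters solely through the bootstrap.
* Projections freeze income classification and use deterministic
  population paths; probabilistic demography is out of scope.
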