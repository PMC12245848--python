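# hmburden

Economic burden of hematologic malignancies (leukemia, non-Hodgkin
lymphoma, multiple myeloma, Hodgkin lymphoma), estimated by monetizing
disability-adjusted life years (DALYs) with the value of a statistical
life year (VSLY). The package is aimed at health economists and burden-of-
disease analysts: it implements the full analysis chain — benefit-transfer
valuation, burden aggregation, Shapley decomposition of drivers, projection
to 2050, and bootstrap uncertainty — as a tested library plus numbered
analysis drivers, validated end to end against synthetic worlds with known
ground truth.

## The model

**Valuation.** The US value of a statistical life, VSL_US = $11.23M (2021
US dollars), is transferred to country *x* by income-scaled benefit
transfer

```
VSL_x = VSL_US · (GNIpc_x / GNIpc_US)^E,     E = 1 (HIC), 1.5 (otherwise),
```

with a floor of 20·GNIpc_x, and spread evenly (undiscounted) over the
remaining life expectancy at the population's median age:
VSLY_x = VSL_x / e(median age). One DALY lost is valued at one VSLY, so a
country-year's burden is `C = Σ_a P·s_a·r_a·V` — population × age-structure
fraction × age-specific DALY rate × VSLY, summed over age bands. Money is
expressed in 2021 international dollars: CPI inflation before 2021, a 3%
annual discount after.

**Decomposition.** The 1990→2021 change in C is attributed to VSLY,
population growth, population aging, and epidemiological (rate) change by
exact Shapley attribution — each factor's marginal effect averaged over all
orderings — which is additive, order-independent, and gives an unchanged
factor exactly zero.

**Projection.** Either deterministic scenarios (rates constant at 2021
levels, or ±1%/yr) or a Bayesian age-period-cohort Poisson model,
`log λ_ij = μ + α_i + β_j + γ_k`, with second-order random-walk (RW2)
smoothing priors, inverse-gamma variance hyperpriors, sum-to-zero and
cohort-detrending identifiability constraints, fitted by an empirical-Bayes
Laplace approximation and forecast under the RW2 predictive distribution.
Future VSLY grows at each country's 2011–2020 GNI-per-capita growth rate.

**Uncertainty.** 1,000 bootstrap replicates: DALYs drawn from zero-truncated
normals inside their 95% uncertainty intervals, VSLY varied ±20%;
percentile 95% intervals per World Bank income group.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
204-country world (run them in order; outputs land in `results/`):

```sh
python analysis/01_simulate_world.py
python analysis/02_build_vsly.py
python analysis/03_monetize_burden.py
python analysis/04_decompose_change.py
```

which prints, for example:

```
global burden 1990: $2,342.6B   2021: $2,270.8B   change: -3.1%
  2021 income-group shares: {'HIC': '91.5%', 'LIC': '0.2%', 'LMIC': '2.0%', 'UMIC': '6.4%'}
  ...
decomposed 204 countries; global change $1,045.8B
  Total cost change             +100.00%
  Change due to VSLY             +97.35%
  Change due to DALYs             +2.65%
  Population growth              +43.43%
  Population aging                +7.75%
  Epidemiological changes        -48.54%
```

Read: in this synthetic world the monetized burden is roughly flat over
1990–2021 because declining age-specific rates (−48.5% contribution) offset
rising valuations (+97.3%) and demographic growth (+43.4% + 7.8%); the four
contributions sum exactly to the total change, and the VSLY/DALYs rollup
sums to 100%. `05_project_2050.py` and `06_bootstrap_uncertainty.py` add
the scenario/BAPC projections and the income-group confidence intervals.

Library use is equally direct:

```python
from hmburden import burden
burden.percent_change(992.0, 1516.0)   # 52.82  (% change of a global total)
burden.share_of_total(651.0, 1516.0)   # 42.94  (% share of a subtype)
```

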