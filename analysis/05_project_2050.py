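"""Project the burden to 2030/2040/2050 under both engines.

Scenario engine: country rates held at 2021 levels (baseline) or moved
±1%/yr; VSLY projected with each country's 2011–2020 GNI-per-capita growth;
future money discounted to 2021 at 3%.  BAPC engine: a Bayesian
age-period-cohort fit of the pooled global rate grid, forecast under the
RW2 predictive.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hmburden import io as hio
from hmburden import valuation
from hmburden.projection import ScenarioSpec, fit_bapc, forecast_bapc, project_burden, scenario_rates
from hmburden.valuation import VslParams

WORLD = Path("results/world")
OUT = Path("results")
YEARS = (2030, 2040, 2050)


def main():
    dalys = hio.read_gbd_csv(WORLD / "dalys.csv")
    econ = hio.read_panel_csv(WORLD / "econ.csv")
    pop_age = hio.read_panel_csv(WORLD / "pop_age.csv")
    vsly = hio.read_panel_csv(OUT / "vsly.csv")
    params = VslParams()
    income_map = econ[["country", "income_group"]].drop_duplicates()

    # future demography: continue each (country, age) log-linear trend
    from hmburden.pipeline import _project_demography
    pop_future = _project_demography(pop_age, YEARS)

    # future VSLY from 2011-2020 GNI growth
    growth = {c: valuation.gni_growth_rate(s.set_index("year")["gnipc"])
              for c, s in econ.groupby("country")}
    v21 = vsly[vsly.year == 2021][["country", "vsly"]]
    v_future = pd.concat([
        pd.DataFrame({"country": v21["country"], "year": y,
                      "vsly": [valuation.project_vsly(v, growth[c], y)
                               for c, v in zip(v21["country"], v21["vsly"])]})
        for y in YEARS], ignore_index=True)

    base = dalys[dalys.year == 2021].groupby(["country", "age"], as_index=False)["val"].sum()
    base = base.merge(pop_age[pop_age.year == 2021][["country", "age", "population"]],
                      on=["country", "age"])
    base["rate"] = base["val"] / base["population"]

    rows = []
    for name in ("baseline", "negative", "positive"):
        spec = ScenarioSpec(name)
        rates = pd.concat([base.assign(year=y, rate=scenario_rates(base["rate"], spec, y))
                           for y in YEARS], ignore_index=True)
        proj = project_burden(rates[["country", "year", "age", "rate"]],
                              pop_future, v_future, params, YEARS)
        proj["scenario"] = name
        rows.append(proj)
        totals = proj.groupby("year")["burden"].sum()
        print(f"scenario {name:9s}:",
              {int(y): f"${t/1e9:,.0f}B" for y, t in totals.items()})
    all_proj = pd.concat(rows, ignore_index=True)
    hio.write_panel_csv(all_proj, OUT / "projection_scenarios.csv",
                        hio.default_units(all_proj.columns))

    baseline = all_proj[all_proj.scenario == "baseline"]
    for y in (2030, 2050):
        ig = baseline[baseline.year == y].merge(income_map, on="country")
        shares = ig.groupby("income_group")["burden"].sum()
        shares = 100 * shares / shares.sum()
        print(f"  baseline {y} income-group shares:",
              {g: f"{v:.1f}%" for g, v in shares.items()})

    # BAPC on the pooled global grid
    age_order = list(dict.fromkeys(dalys["age"]))
    counts = (dalys.groupby(["age", "year"])["val"].sum().unstack().reindex(age_order))
    expo = (pop_age.groupby(["age", "year"])["population"].sum().unstack()
            .reindex(age_order).loc[:, counts.columns])
    fit = fit_bapc(np.round(counts.to_numpy()), expo.to_numpy())
    fc = forecast_bapc(fit, 2050 - 2021, max_extrapolation=29)
    print(f"BAPC pooled fit: converged={fit.converged} in {fit.n_outer} outer iterations; "
          f"precisions {{{', '.join(f'{k}={v:.3g}' for k, v in fit.tau.items())}}}")
    crude21 = counts.to_numpy()[:, -1] / expo.to_numpy()[:, -1]
    ratio = fc.median[:, -1] / crude21
    print(f"  2050/2021 median rate ratio across ages: "
          f"{np.min(ratio):.2f}-{np.max(ratio):.2f}")
    grid = pd.DataFrame({
        "age": np.repeat(age_order, 29),
        "year": np.tile(np.arange(2022, 2051), len(age_order)),
        "rate_median": fc.median.ravel(),
        "rate_lower": fc.lower.ravel(),
        "rate_upper": fc.upper.ravel(),
    })
    hio.write_panel_csv(grid, OUT / "projection_bapc_global_rates.csv",
                        {"rate_median": "DALYs per person-year"})


if __name__ == "__main__":
    main()
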