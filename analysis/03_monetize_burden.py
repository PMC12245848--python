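"""Monetize DALYs and report the burden's distribution.

One DALY = one VSLY.  Burden is expressed in 2021 international dollars
(country-CPI inflation before 2021).  Prints global totals for 1990 and
2021, the percent change, income-group and subtype shares, burden as a
share of GDP, and writes the burden table plus country quintile bins.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hmburden import burden as bd
from hmburden import io as hio
from hmburden.valuation import VslParams

WORLD = Path("results/world")
OUT = Path("results")


def main():
    dalys = hio.read_gbd_csv(WORLD / "dalys.csv")
    econ = hio.read_panel_csv(WORLD / "econ.csv")
    vsly = hio.read_panel_csv(OUT / "vsly.csv")
    params = VslParams()

    cells = dalys.groupby(["country", "year", "cause"], as_index=False)[
        ["val", "lower", "upper"]].sum()
    merged = cells.merge(vsly[["country", "year", "vsly"]], on=["country", "year"])
    merged = merged.merge(econ[["country", "year", "cpi"]], on=["country", "year"])
    cpi_base = econ[econ.year == params.base_year].set_index("country")["cpi"]
    factor = cpi_base.loc[merged["country"]].to_numpy() / merged["cpi"].to_numpy()
    scale = merged["vsly"].to_numpy() * factor
    btab = merged[["country", "year", "cause"]].copy()
    for src, dst in (("val", "burden"), ("lower", "lower"), ("upper", "upper")):
        btab[dst] = merged[src].to_numpy() * scale
    hio.write_panel_csv(btab, OUT / "burden.csv", hio.default_units(btab.columns))

    income_map = econ[["country", "income_group"]].drop_duplicates()
    g90 = float(bd.aggregate(btab, "global", year=1990)["burden"].iloc[0])
    g21 = float(bd.aggregate(btab, "global", year=2021)["burden"].iloc[0])
    print(f"global burden 1990: ${g90/1e9:,.1f}B   2021: ${g21/1e9:,.1f}B   "
          f"change: {bd.percent_change(g90, g21):+.1f}%")

    for year in (1990, 2021):
        ig = bd.aggregate(btab, "income_group", year=year, income_map=income_map)
        rep = bd.share_report(ig, "income_group").set_index("income_group")
        gdp = econ[econ.year == year].groupby(
            econ[econ.year == year]["income_group"])["gdp"].sum()
        print(f"  {year} income-group shares:",
              {g: f"{rep.loc[g, 'share_pct']:.1f}%" for g in rep.index},
              "| burden/GDP:",
              {g: f"{100*bd.gdp_share(rep.loc[g,'burden'], gdp[g]):.2f}%" for g in rep.index})

    cz = bd.aggregate(btab, "cause", year=2021)
    print("  2021 subtype shares:",
          {r.cause: f"{100*r.burden/g21:.1f}%" for r in cz.itertuples()})

    totals = btab[btab.year == 2021].groupby("country")["burden"].sum()
    bins = bd.quintile_bins(totals)
    bins.rename_axis("country").reset_index().to_csv(OUT / "quintiles_2021.csv", index=False)
    print("  quintile bin sizes:", np.bincount(bins)[1:].tolist())


if __name__ == "__main__":
    main()
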