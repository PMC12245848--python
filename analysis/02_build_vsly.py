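"""Transfer the US VSL to every country-year and derive the VSLY.

Reads the economic and demographic panels from results/world/, applies the
benefit transfer (elasticity 1.0 for HIC, 1.5 otherwise, 20x-GNIpc floor)
and spreads each VSL over the remaining life years at the median age.
"""

from pathlib import Path

from hmburden import io as hio
from hmburden import valuation

WORLD = Path("results/world")
OUT = Path("results")


def main():
    econ = hio.read_panel_csv(WORLD / "econ.csv")
    demog = hio.read_panel_csv(WORLD / "demog.csv")
    params = valuation.VslParams()
    vsly = valuation.build_vsly_table(econ, demog, params)
    hio.write_panel_csv(vsly, OUT / "vsly.csv", hio.default_units(vsly.columns))

    y = vsly[vsly["year"] == 2021].merge(
        econ[["country", "year", "gnipc"]], on=["country", "year"])
    floor_bound = (y["vsl"] <= params.floor_multiple * y["gnipc"] * (1 + 1e-9)).mean()
    print(f"VSLY rows: {len(vsly):,}")
    for g, sub in y.groupby("income_group"):
        print(f"  {g}: median VSL ${sub['vsl'].median()/1e6:.2f}M, "
              f"median VSLY ${sub['vsly'].median():,.0f}/life-year")
    print(f"share of countries at the 20x-GNIpc floor in 2021: {100*floor_bound:.1f}%")


if __name__ == "__main__":
    main()
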