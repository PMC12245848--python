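"""Attribute the 1990 -> 2021 burden change to its drivers.

Shapley-decomposes each country's change in monetized burden into VSLY,
population growth, population aging and epidemiological (rate) change, then
aggregates to the global table (the headline decomposition structure:
total = VSLY + DALYs; DALYs = growth + aging + epidemiology).
"""

from pathlib import Path

from hmburden import io as hio
from hmburden.decomposition import (
    aggregate_decomposition,
    decomposition_table,
    factor_states_from_tables,
    shapley_decompose,
)

WORLD = Path("results/world")
OUT = Path("results")


def main():
    dalys = hio.read_gbd_csv(WORLD / "dalys.csv")
    pop_age = hio.read_panel_csv(WORLD / "pop_age.csv")
    vsly = hio.read_panel_csv(OUT / "vsly.csv")
    age_order = list(dict.fromkeys(dalys["age"]))

    results = []
    for country in sorted(dalys["country"].unique()):
        s0 = factor_states_from_tables(dalys, pop_age, vsly, country, 1990, age_order)
        s1 = factor_states_from_tables(dalys, pop_age, vsly, country, 2021, age_order)
        results.append(shapley_decompose(s0, s1))
    world = aggregate_decomposition(results)
    table = decomposition_table(world)
    hio.write_panel_csv(table, OUT / "decomposition.csv", hio.default_units(table.columns))

    print(f"decomposed {len(results)} countries; global change "
          f"${world.total_change/1e9:,.1f}B")
    for row in table.itertuples():
        print(f"  {row.factor:28s} {row.percent_contribution:+8.2f}%")


if __name__ == "__main__":
    main()
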