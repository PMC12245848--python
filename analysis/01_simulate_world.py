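"""Generate the synthetic study world and write its input tables.

Emulates the study's input scale — 204 country-like units, the 1990–2021
panel, twenty 5-year age bands, four hematologic-malignancy subtypes —
with known APC rate structure, then writes the GBD-dialect DALY table and
the tidy economic/demographic panels under results/world/.
"""

from pathlib import Path

import pandas as pd

from hmburden import io as hio
from hmburden import synthetic

OUT = Path("results/world")
SEED = 20240901


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.WorldConfig(seed=SEED)
    world = synthetic.gen_world(cfg)
    dalys = pd.concat(
        [synthetic.gen_daly_table(world, c) for c in cfg.causes], ignore_index=True
    )

    hio.write_gbd_csv(dalys, OUT / "dalys.csv")
    hio.write_panel_csv(world.econ, OUT / "econ.csv",
                        {"gnipc": "intl$ per capita (PPP)", "gdp": "intl$", "cpi": "index"})
    hio.write_panel_csv(world.demog, OUT / "demog.csv",
                        {"median_age": "years", "le_at_median_age": "years"})
    hio.write_panel_csv(world.pop_age, OUT / "pop_age.csv", {"population": "persons"})

    n_cy = world.econ[["country", "year"]].drop_duplicates().shape[0]
    print(f"world: {cfg.n_countries} countries x {cfg.n_years} years "
          f"({n_cy} country-years), {len(dalys):,} DALY rows")
    print("income mix:",
          world.econ.drop_duplicates("country")["income_group"].value_counts().to_dict())
    print(f"global DALYs 2021: {dalys[dalys.year == 2021]['val'].sum():,.0f}")


if __name__ == "__main__":
    main()
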