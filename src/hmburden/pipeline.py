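"""End-to-end pipeline: simulate/ingest -> value -> monetize -> decompose
-> project -> bootstrap.

Driven by a :class:`RunConfig` (constructible from YAML); every stochastic
stage derives its seed from the run seed, every stage is timed and logged,
and a failure aborts with the stage name.  Outputs are tidy CSVs plus a
deterministic JSON summary holding the headline quantities (totals, shares,
percent changes, the decomposition table, projections, bootstrap CIs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import io as io_mod
from . import synthetic, valuation
from .decomposition import (
    aggregate_decomposition,
    decomposition_table,
    factor_states_from_tables,
    shapley_decompose,
)
from .errors import ConfigurationError, PipelineStageError
from .projection import ScenarioSpec, fit_bapc, forecast_bapc, project_burden, scenario_rates
from .uncertainty import BootstrapConfig, bootstrap_burden
from .valuation import VslParams

log = logging.getLogger("hmburden.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With no input paths the world is simulated from ``world``; otherwise
    ``dalys_path`` (GBD dialect), ``econ_path``, ``demog_path`` and
    ``pop_age_path`` (tidy panels) are ingested.  ``seed`` overrides the
    world and bootstrap seeds so one integer drives every random stage.
    """

    world: synthetic.WorldConfig = field(default_factory=synthetic.WorldConfig)
    vsl: VslParams = field(default_factory=VslParams)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    engine: str = "scenario"
    scenario: str = "baseline"
    projection_years: tuple[int, ...] = (2030, 2040, 2050)
    out_dir: str = "results/pipeline"
    log_level: str = "INFO"
    seed: int = 0
    dalys_path: str | None = None
    econ_path: str | None = None
    demog_path: str | None = None
    pop_age_path: str | None = None

    def __post_init__(self):
        if self.engine not in ("scenario", "bapc"):
            raise ConfigurationError("engine must be 'scenario' or 'bapc'")
        ss = np.random.SeedSequence(self.seed)
        w_seed, b_seed = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
        self.world = dataclasses.replace(self.world, seed=w_seed)
        self.bootstrap = dataclasses.replace(self.bootstrap, seed=b_seed)
        paths = [self.dalys_path, self.econ_path, self.demog_path, self.pop_age_path]
        if any(paths) and self.dalys_path is None:
            raise ConfigurationError("ingest mode requires dalys_path")
        for p in paths:
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "world" in kwargs:
            w = dict(kwargs["world"])
            if "years" in w:
                w["years"] = tuple(w["years"])
            if "income_group_mix" in w:
                w["income_group_mix"] = dict(w["income_group_mix"])
            kwargs["world"] = synthetic.WorldConfig(**w)
        if "vsl" in kwargs:
            kwargs["vsl"] = VslParams(**kwargs["vsl"])
        if "bootstrap" in kwargs:
            kwargs["bootstrap"] = BootstrapConfig(**kwargs["bootstrap"])
        if "projection_years" in kwargs:
            kwargs["projection_years"] = tuple(kwargs["projection_years"])
        return cls(**kwargs)


def _project_demography(pop_age: pd.DataFrame, years_future: tuple[int, ...],
                        window: int = 10) -> pd.DataFrame:
    """Extrapolate per-country age pyramids with a log-linear per-band trend.

    Each (country, age) population series is continued with the geometric
    trend fitted over the last ``window`` observed years — a simple
    deterministic stand-in for an external population projection input.
    """
    frames = []
    last = int(pop_age["year"].max())
    recent = pop_age[pop_age["year"] >= last - window + 1]
    for (country, age), sub in recent.groupby(["country", "age"], sort=False):
        sub = sub.sort_values("year")
        y = np.log(np.maximum(sub["population"].to_numpy(dtype=float), 1e-9))
        t = sub["year"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(t, y, 1)
        for yr in years_future:
            frames.append((country, yr, age, float(np.exp(intercept + slope * yr))))
    return pd.DataFrame(frames, columns=["country", "year", "age", "population"])


def _stage(name, summary, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        log.error("stage %s failed: %s", name, exc)
        raise PipelineStageError(name, str(exc)) from exc
    log.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the JSON-serializable summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "engine": config.engine}
    log.info("run seed %d (world seed %d, bootstrap seed %d)",
             config.seed, config.world.seed, config.bootstrap.seed)

    # --- simulate / ingest -------------------------------------------------
    def simulate():
        if config.dalys_path is not None:
            dalys = io_mod.read_gbd_csv(config.dalys_path)
            econ = io_mod.read_panel_csv(config.econ_path) if config.econ_path else None
            demog = io_mod.read_panel_csv(config.demog_path) if config.demog_path else None
            pop_age = io_mod.read_panel_csv(config.pop_age_path) if config.pop_age_path else None
            return dalys, econ, demog, pop_age, None
        world = synthetic.gen_world(config.world)
        dalys = pd.concat(
            [synthetic.gen_daly_table(world, c) for c in config.world.causes],
            ignore_index=True,
        )
        return dalys, world.econ, world.demog, world.pop_age, world

    dalys, econ, demog, pop_age, world = _stage("simulate", summary, simulate)
    io_mod.write_gbd_csv(dalys, out_dir / "dalys.csv")

    # --- valuation ---------------------------------------------------------
    def value():
        if econ is None or demog is None:
            raise ConfigurationError(
                "VSLY inputs missing: valuation needs both an economic panel and demography"
            )
        return valuation.build_vsly_table(econ, demog, config.vsl)

    vsly = _stage("valuation", summary, value)
    io_mod.write_panel_csv(vsly, out_dir / "vsly.csv", io_mod.default_units(vsly.columns))

    # --- monetize + aggregate ---------------------------------------------
    def monetize():
        # CPI varies by country in the synthetic world; deflate with each
        # country's own CPI by merging per country-year.
        if "cpi" in econ.columns:
            base = config.vsl.base_year
            cpi_tab = econ[["country", "year", "cpi"]]
            cpi_base = cpi_tab[cpi_tab["year"] == base][["country", "cpi"]].rename(
                columns={"cpi": "cpi_base"})
            merged_dalys = dalys.groupby(["country", "year", "cause"], as_index=False)[
                ["val", "lower", "upper"]].sum()
            merged = merged_dalys.merge(vsly[["country", "year", "vsly"]],
                                        on=["country", "year"], validate="many_to_one")
            merged = merged.merge(cpi_tab, on=["country", "year"]).merge(cpi_base, on="country")
            years = merged["year"].to_numpy()
            factor = np.ones(len(merged))
            past = years < base
            factor[past] = (merged["cpi_base"] / merged["cpi"]).to_numpy()[past]
            future = years > base
            factor[future] = (1.0 + config.vsl.discount_rate) ** -(years[future] - base)
            scale = merged["vsly"].to_numpy() * factor
            out = merged[["country", "year", "cause"]].copy()
            for col in ("val", "lower", "upper"):
                out[{"val": "burden", "lower": "lower", "upper": "upper"}[col]] = (
                    merged[col].to_numpy() * scale)
            return out
        return burden_mod.monetize(dalys, vsly, config.vsl)

    btab = _stage("monetize", summary, monetize)
    io_mod.write_panel_csv(btab, out_dir / "burden.csv", io_mod.default_units(btab.columns))

    y0 = int(btab["year"].min())
    y1 = int(min(btab["year"].max(), config.vsl.base_year))
    income_map = econ[["country", "income_group"]].drop_duplicates()

    def report():
        g0 = float(burden_mod.aggregate(btab, "global", year=y0)["burden"].iloc[0])
        g1 = float(burden_mod.aggregate(btab, "global", year=y1)["burden"].iloc[0])
        ig = burden_mod.aggregate(btab, "income_group", year=y1, income_map=income_map)
        ig_shares = burden_mod.share_report(ig, "income_group")
        cz = burden_mod.aggregate(btab, "cause", year=y1)
        cz_shares = burden_mod.share_report(cz, "cause")
        gdp = econ[econ["year"] == y1].merge(income_map, on="country", suffixes=("", "_r"))
        gdp_by_group = gdp.groupby("income_group")["gdp"].sum()
        ig_idx = ig.set_index("income_group")["burden"]
        gdp_pct = {g: 100.0 * burden_mod.gdp_share(float(ig_idx[g]), float(gdp_by_group[g]))
                   for g in ig_idx.index}
        return {
            "global_burden": {str(y0): g0, str(y1): g1},
            "global_pct_change": burden_mod.percent_change(g0, g1),
            "income_group_shares_pct": dict(zip(ig_shares["income_group"],
                                                ig_shares["share_pct"])),
            "cause_shares_pct": dict(zip(cz_shares["cause"], cz_shares["share_pct"])),
            "gdp_share_pct_by_income_group": gdp_pct,
        }

    summary.update(_stage("report", summary, report))

    # --- decomposition -----------------------------------------------------
    def decompose():
        age_order = [b.label for b in config.world.age_bands] if world is not None \
            else sorted(dalys["age"].unique())
        results = []
        for country in sorted(dalys["country"].unique()):
            s0 = factor_states_from_tables(dalys, pop_age, vsly, country, y0, age_order)
            s1 = factor_states_from_tables(dalys, pop_age, vsly, country, y1, age_order)
            results.append(shapley_decompose(s0, s1))
        return aggregate_decomposition(results)

    decomp = _stage("decompose", summary, decompose)
    dtable = decomposition_table(decomp)
    io_mod.write_panel_csv(dtable, out_dir / "decomposition.csv",
                           io_mod.default_units(dtable.columns))
    summary["decomposition_pct"] = {
        row.factor: row.percent_contribution for row in dtable.itertuples()
    }

    # --- projection --------------------------------------------------------
    def project():
        years = config.projection_years
        pop_future = _project_demography(pop_age, years)
        growth = {}
        for country, sub in econ.groupby("country"):
            series = sub.set_index("year")["gnipc"]
            lo = max(int(series.index.min()), 2011)
            hi = min(int(series.index.max()), 2020)
            growth[country] = valuation.gni_growth_rate(series, (lo, hi))
        v_base = vsly[vsly["year"] == y1][["country", "vsly"]]
        v_future = pd.concat([
            pd.DataFrame({
                "country": v_base["country"],
                "year": yr,
                "vsly": [valuation.project_vsly(v, growth[c], yr, y1)
                         for c, v in zip(v_base["country"], v_base["vsly"])],
            }) for yr in years
        ], ignore_index=True)

        base = dalys[dalys["year"] == y1].groupby(["country", "age"], as_index=False)["val"].sum()
        pop_base = pop_age[pop_age["year"] == y1]
        base = base.merge(pop_base[["country", "age", "population"]], on=["country", "age"])
        base["rate"] = base["val"] / base["population"]

        if config.engine == "scenario":
            spec = ScenarioSpec(config.scenario)
            rates = pd.concat([
                base.assign(year=yr, rate=lambda d, yr=yr: scenario_rates(d["rate"], spec, yr))
                for yr in years
            ], ignore_index=True)[["country", "year", "age", "rate"]]
        else:
            age_order = [b.label for b in config.world.age_bands] if world is not None \
                else sorted(dalys["age"].unique())
            frames = []
            for country in sorted(dalys["country"].unique()):
                counts = (dalys[dalys["country"] == country]
                          .groupby(["age", "year"])["val"].sum().unstack()
                          .reindex(age_order))
                expo = (pop_age[pop_age["country"] == country]
                        .pivot(index="age", columns="year", values="population")
                        .reindex(age_order).loc[:, counts.columns])
                fit = fit_bapc(np.round(counts.to_numpy()), expo.to_numpy())
                horizon = max(years) - y1
                fc = forecast_bapc(fit, horizon, max_extrapolation=horizon)
                for yr in years:
                    h = yr - y1 - 1
                    frames.append(pd.DataFrame({
                        "country": country, "year": yr, "age": age_order,
                        "rate": fc.median[:, h],
                    }))
            rates = pd.concat(frames, ignore_index=True)
        proj = project_burden(rates, pop_future, v_future, config.vsl, years)
        return proj

    proj = _stage("project", summary, project)
    io_mod.write_panel_csv(proj, out_dir / "projection.csv", io_mod.default_units(proj.columns))
    proj_summary = {}
    for yr in config.projection_years:
        sub = proj[proj["year"] == yr]
        total = float(sub["burden"].sum())
        ig = sub.merge(income_map, on="country").groupby("income_group")["burden"].sum()
        proj_summary[str(yr)] = {
            "global_burden": total,
            "income_group_shares_pct": {g: 100.0 * v / total for g, v in ig.items()},
        }
    summary["projection"] = proj_summary

    # --- bootstrap ---------------------------------------------------------
    def boot():
        cells = dalys[dalys["year"] == y1].groupby(
            ["country", "year", "cause"], as_index=False)[["val", "lower", "upper"]].sum()
        return bootstrap_burden(cells, vsly, config.bootstrap, income_map)

    ci = _stage("bootstrap", summary, boot)
    io_mod.write_panel_csv(ci, out_dir / "bootstrap.csv", io_mod.default_units(ci.columns))
    summary["bootstrap"] = {
        r.stratum: {"estimate": r.estimate, "ci_lower": r.ci_lower, "ci_upper": r.ci_upper}
        for r in ci.itertuples()
    }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
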