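"""Monetize DALYs into economic burden and compute descriptive statistics.

One DALY lost is valued at one VSLY.  Burden tables live in base-year
(2021) international dollars: money earned in earlier years is brought
forward with the CPI, money in later years is discounted back at the
configured rate.  On top of the burden table this module provides the
report arithmetic — percent changes, shares of a total, burden as a share
of GDP, and quintile binning of countries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DegenerateInputError, DomainError
from .valuation import MONEY_UNIT, VslParams

GROUPINGS = ("income_group", "country", "cause", "global")


def _year_adjustment(years: np.ndarray, params: VslParams, cpi: pd.Series | None) -> np.ndarray:
    """Multiplicative factor taking year-t money to base-year money."""
    factor = np.ones(len(years))
    future = years > params.base_year
    factor[future] = (1.0 + params.discount_rate) ** -(years[future] - params.base_year)
    past = years < params.base_year
    if past.any():
        if cpi is None:
            raise DataError(
                "rows predate the base year but no CPI series was supplied for inflation adjustment"
            )
        if params.base_year not in cpi.index:
            raise DataError(f"CPI series lacks the base year {params.base_year}")
        missing = sorted(set(years[past]) - set(cpi.index))
        if missing:
            raise DataError(f"CPI series lacks years {missing}")
        factor[past] = float(cpi.loc[params.base_year]) / cpi.loc[years[past]].to_numpy(dtype=float)
    return factor


def monetize(
    dalys: pd.DataFrame,
    vsly: pd.DataFrame,
    params: VslParams,
    cpi: pd.Series | None = None,
) -> pd.DataFrame:
    """Burden table: DALYs x VSLY, adjusted to base-year dollars.

    ``dalys`` has columns country, year, cause, val, lower, upper (an ``age``
    column, if present, is summed out first).  ``vsly`` must provide a VSLY
    for every (country, year) appearing in ``dalys``.  DALY uncertainty
    bounds propagate through the same multiplication; the VSLY is treated as
    fixed here (its ±20% variation is the uncertainty module's concern).
    ``cpi``, indexed by year, is required only when rows predate the base
    year.
    """
    dalys = dalys.copy()
    if "age" in dalys.columns:
        dalys = (
            dalys.groupby(["country", "year", "cause"], as_index=False)[["val", "lower", "upper"]]
            .sum()
        )
    merged = dalys.merge(
        vsly[["country", "year", "vsly"]], on=["country", "year"], how="left", validate="many_to_one"
    )
    missing = merged[merged["vsly"].isna()]
    if len(missing):
        offenders = [tuple(r) for r in missing[["country", "year"]].drop_duplicates().head(20).to_numpy()]
        raise DataError(f"no VSLY for {len(missing)} DALY rows, e.g. {offenders}")

    factor = _year_adjustment(merged["year"].to_numpy(), params, cpi)
    scale = merged["vsly"].to_numpy() * factor
    out = merged[["country", "year", "cause"]].copy()
    out["burden"] = merged["val"].to_numpy() * scale
    out["lower"] = merged["lower"].to_numpy() * scale
    out["upper"] = merged["upper"].to_numpy() * scale
    out.attrs["units"] = {"burden": MONEY_UNIT, "lower": MONEY_UNIT, "upper": MONEY_UNIT}
    return out


def aggregate(
    burden: pd.DataFrame,
    by: str,
    year: int | None = None,
    income_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sum burden by income group, country, cause, or globally.

    ``income_map`` (columns country, income_group) is required for
    ``by='income_group'``.  Returns one row per group with columns
    ``[<by>, burden, lower, upper]`` (a single ``'global'`` row for the
    global grouping).
    """
    if by not in GROUPINGS:
        raise ConfigurationError(f"unknown grouping {by!r}; expected one of {GROUPINGS}")
    df = burden if year is None else burden[burden["year"] == year]
    cols = ["burden", "lower", "upper"] if "lower" in df.columns else ["burden"]
    if by == "global":
        totals = df[cols].sum().to_frame().T
        totals.insert(0, "global", "global")
        return totals
    if by == "income_group":
        if income_map is None:
            raise ConfigurationError("income_map is required to aggregate by income group")
        df = df.merge(income_map[["country", "income_group"]].drop_duplicates(), on="country", how="left")
        if df["income_group"].isna().any():
            unknown = sorted(df.loc[df["income_group"].isna(), "country"].unique())
            raise DataError(f"countries missing from income_map: {unknown[:20]}")
    return df.groupby(by, as_index=False)[cols].sum()


def percent_change(v0: float, v1: float) -> float:
    """Signed percent change from v0 to v1: 100 * (v1 - v0) / v0."""
    if v0 <= 0:
        raise DomainError("baseline value must be positive for a percent change")
    return 100.0 * (v1 - v0) / v0


def share_of_total(part: float, total: float) -> float:
    """Share of a total as a percentage: 100 * part / total."""
    if total <= 0:
        raise DomainError("total must be positive")
    return 100.0 * part / total


def gdp_share(burden: float, gdp: float) -> float:
    """Burden as a fraction (not percent) of GDP."""
    if gdp <= 0:
        raise DomainError("GDP must be positive")
    return burden / gdp


def quintile_bins(values: pd.Series) -> pd.Series:
    """Assign each country to a quintile bin 1..5 of its burden value.

    Split points are the empirical 20/40/60/80 percentiles with inclusive
    linear interpolation; values equal to a split point fall in the lower
    bin, and ties keep the input's stable order.
    """
    if len(values) < 5:
        raise DegenerateInputError("quintile binning needs at least 5 countries")
    v = values.to_numpy(dtype=float)
    if len(np.unique(v)) < 5:
        raise DegenerateInputError("quintile binning needs at least 5 distinct values")
    cuts = np.percentile(v, [20, 40, 60, 80], method="linear")
    bins = 1 + np.searchsorted(cuts, v, side="left")
    return pd.Series(bins, index=values.index, name="quintile")


def share_report(totals: pd.DataFrame, group_col: str, value_col: str = "burden") -> pd.DataFrame:
    """Shares over an exhaustive partition; the ``share_pct`` column sums to 100."""
    total = float(totals[value_col].sum())
    if total <= 0:
        raise DomainError("partition total must be positive")
    out = totals[[group_col, value_col]].copy()
    out["share_pct"] = 100.0 * out[value_col] / total
    return out
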