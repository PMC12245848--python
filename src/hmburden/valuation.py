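"""Benefit-transfer valuation: VSL -> country VSL -> VSLY, and money-over-time.

The value of a statistical life (VSL) estimated for the United States is
transferred to every other country by scaling with the ratio of gross
national incomes per capita raised to an income elasticity,

    VSL_x = VSL_US * (GNIpc_x / GNIpc_US) ** E,

with E = 1 for high-income countries and E = 1.5 otherwise, and a floor of
20x the country's GNI per capita.  The value of a statistical life *year*
(VSLY) spreads the VSL evenly over the remaining life years of the median-
aged person — no discounting enters this division.  Moving money across
calendar years is a separate concern: consumer-price-index scaling before
the base year, a 3% annual discount after it, and a GNI-growth projection
of future VSLY levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError

MONEY_UNIT = "2021 international dollars"


@dataclass(frozen=True)
class VslParams:
    """Parameters of the VSL benefit transfer.

    vsl_us
        US value of a statistical life in base-year dollars ($11.23M, the
        2015 HHS estimate of $9.4M inflated to 2021 prices).
    gnipc_us
        US GNI per capita, PPP, at the transfer reference year (2019).
    elasticity_hic / elasticity_non_hic
        Income elasticity of VSL for high-income vs all other countries.
    floor_multiple
        Minimum VSL as a multiple of the country's own GNI per capita.
    discount_rate
        Annual rate used to bring post-base-year money back to base.
    """

    vsl_us: float = 11.23e6
    gnipc_us: float = 66_080.0
    elasticity_hic: float = 1.0
    elasticity_non_hic: float = 1.5
    floor_multiple: float = 20.0
    discount_rate: float = 0.03
    base_year: int = 2021
    reference_year: int = 2019

    def __post_init__(self):
        if min(self.vsl_us, self.gnipc_us, self.elasticity_hic,
               self.elasticity_non_hic, self.floor_multiple) <= 0:
            raise ConfigurationError("VslParams monetary/elasticity fields must be positive")
        if self.elasticity_non_hic < self.elasticity_hic:
            raise ConfigurationError("elasticity_non_hic must be >= elasticity_hic")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ConfigurationError("discount_rate must be in [0, 1)")

    def elasticity(self, income_group: str) -> float:
        return self.elasticity_hic if income_group == "HIC" else self.elasticity_non_hic


def transfer_vsl(gnipc_target, params: VslParams, income_group: str):
    """Benefit-transferred VSL, no floor applied.

    Accepts scalars or arrays for ``gnipc_target``; the elasticity is chosen
    by the income group (1.0 for HIC, 1.5 for UMIC/LMIC/LIC).
    """
    gnipc_target = np.asarray(gnipc_target, dtype=float)
    if np.any(gnipc_target <= 0):
        raise DomainError("GNI per capita must be positive")
    e = params.elasticity(income_group)
    out = params.vsl_us * (gnipc_target / params.gnipc_us) ** e
    return float(out) if out.ndim == 0 else out


def apply_vsl_floor(vsl, gnipc, floor_multiple: float = 20.0):
    """max(vsl, floor_multiple * gnipc) — the 20x-GNIpc minimum."""
    vsl = np.asarray(vsl, dtype=float)
    gnipc = np.asarray(gnipc, dtype=float)
    if np.any(vsl <= 0) or np.any(gnipc <= 0) or floor_multiple <= 0:
        raise DomainError("vsl, gnipc and floor_multiple must be positive")
    out = np.maximum(vsl, floor_multiple * gnipc)
    return float(out) if out.ndim == 0 else out


def vsly_from_vsl(vsl, median_age, le_at_median_age):
    """VSL spread evenly over remaining life years at the median age.

    ``median_age`` is carried for provenance; the division uses only the
    remaining life expectancy.  No discounting is applied here.
    """
    vsl = np.asarray(vsl, dtype=float)
    le = np.asarray(le_at_median_age, dtype=float)
    if np.any(le <= 0):
        raise DomainError("remaining life years must be positive")
    if np.any(np.asarray(median_age, dtype=float) < 0):
        raise DomainError("median age cannot be negative")
    out = vsl / le
    return float(out) if out.ndim == 0 else out


def gni_growth_rate(gnipc_series: pd.Series, window: tuple[int, int] = (2011, 2020)) -> float:
    """Geometric-mean annual GNIpc growth over ``window`` (default 2011–2020).

    ``gnipc_series`` is indexed by calendar year.  Both window endpoints
    must be present and non-missing.
    """
    start, end = window
    if end <= start:
        raise ConfigurationError("growth window must span at least one year")
    for y in (start, end):
        if y not in gnipc_series.index or pd.isna(gnipc_series.loc[y]):
            raise DataError(f"GNI per capita series is missing year {y}")
    v0, v1 = float(gnipc_series.loc[start]), float(gnipc_series.loc[end])
    if v0 <= 0 or v1 <= 0:
        raise DomainError("GNI per capita must be positive at the window endpoints")
    return (v1 / v0) ** (1.0 / (end - start)) - 1.0


def project_vsly(vsly_base, growth: float, target_year: int, base_year: int = 2021):
    """VSLY projected forward at a constant annual growth rate."""
    if target_year < base_year:
        raise DomainError("target_year must be >= base_year")
    if growth <= -1.0:
        raise DomainError("growth rate must exceed -100%")
    out = np.asarray(vsly_base, dtype=float) * (1.0 + growth) ** (target_year - base_year)
    return float(out) if out.ndim == 0 else out


def cpi_adjust(amount, cpi_source_year, cpi_base):
    """Inflate money from the source year's price level to the base year's."""
    cpi_source_year = np.asarray(cpi_source_year, dtype=float)
    cpi_base = np.asarray(cpi_base, dtype=float)
    if np.any(cpi_source_year <= 0) or np.any(cpi_base <= 0):
        raise DomainError("CPI values must be positive")
    out = np.asarray(amount, dtype=float) * cpi_base / cpi_source_year
    return float(out) if out.ndim == 0 else out


def discount_to_base(amount, year: int, params: VslParams):
    """Discount post-base-year money back to the base year at the discount rate."""
    if year < params.base_year:
        raise DomainError(
            f"year {year} precedes base year {params.base_year}; use cpi_adjust for past money"
        )
    out = np.asarray(amount, dtype=float) / (1.0 + params.discount_rate) ** (year - params.base_year)
    return float(out) if out.ndim == 0 else out


def build_vsly_table(econ: pd.DataFrame, demog: pd.DataFrame, params: VslParams) -> pd.DataFrame:
    """Per country-year VSL and VSLY: transfer -> floor -> divide by remaining years.

    The GNIpc ratio uses each country-year's own GNI per capita over the
    fixed US reference-year GNIpc, so the VSLY evolves with national income
    (the paper-level driver of valuation change over the panel).  Output
    columns: country, year, income_group, vsl, remaining_life_years, vsly;
    monetary columns are in ``MONEY_UNIT``.

    Raises DataError listing the offending (country, year) pairs if any
    economic row lacks demography.
    """
    merged = econ.merge(demog, on=["country", "year"], how="left", validate="one_to_one")
    missing = merged[merged["le_at_median_age"].isna()]
    if len(missing):
        offenders = [tuple(r) for r in missing[["country", "year"]].head(20).to_numpy()]
        raise DataError(f"missing demography for {len(missing)} country-years, e.g. {offenders}")

    is_hic = (merged["income_group"] == "HIC").to_numpy()
    e = np.where(is_hic, params.elasticity_hic, params.elasticity_non_hic)
    gnipc = merged["gnipc"].to_numpy(dtype=float)
    if np.any(gnipc <= 0):
        raise DomainError("GNI per capita must be positive")
    vsl = params.vsl_us * (gnipc / params.gnipc_us) ** e
    vsl = np.maximum(vsl, params.floor_multiple * gnipc)
    le = merged["le_at_median_age"].to_numpy(dtype=float)
    if np.any(le <= 0):
        raise DomainError("remaining life years must be positive")

    out = merged[["country", "year", "income_group"]].copy()
    out["vsl"] = vsl
    out["remaining_life_years"] = le
    out["vsly"] = vsl / le
    out.attrs["units"] = {"vsl": MONEY_UNIT, "vsly": MONEY_UNIT + " per life year"}
    return out
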