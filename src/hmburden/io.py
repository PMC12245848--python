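"""Readers and writers for the standard tabular dialects.

DALY tables travel in the GBD-results CSV dialect (columns measure,
location, sex, age, cause, metric, year, val, upper, lower); economic
indicators in either the tidy (country, year, value) or the wide
(country x year-columns) World Bank dialect, auto-detected.  Internal
tables use the package's own tidy schemas; every writer emits a commented
units header line so the files are self-describing, and every writer/reader
pair round-trips.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .valuation import MONEY_UNIT

GBD_COLUMNS = ["measure", "location", "sex", "age", "cause", "metric", "year",
               "val", "upper", "lower"]
GBD_MEASURE = "DALYs (Disability-Adjusted Life Years)"

#: GBD and World Bank spell some countries differently; canonical name wins.
LOCATION_ALIASES = {
    "United States": "United States of America",
    "Russian Federation": "Russia",
    "Iran (Islamic Republic of)": "Iran",
    "Republic of Korea": "South Korea",
    "Viet Nam": "Vietnam",
    "Turkiye": "Turkey",
}


def canonicalize_locations(names: pd.Series, aliases: dict[str, str] | None = None) -> pd.Series:
    """Map location spellings onto their canonical form."""
    table = dict(LOCATION_ALIASES)
    if aliases:
        table.update(aliases)
    return names.replace(table)


def write_gbd_csv(dalys: pd.DataFrame, path) -> None:
    """Write an internal DALY table (country, year, age, cause, val, lower, upper)
    in the GBD-results dialect."""
    out = pd.DataFrame({
        "measure": GBD_MEASURE,
        "location": dalys["country"],
        "sex": "Both",
        "age": dalys["age"],
        "cause": dalys["cause"],
        "metric": "Number",
        "year": dalys["year"],
        "val": dalys["val"],
        "upper": dalys["upper"],
        "lower": dalys["lower"],
    })
    out.to_csv(path, index=False)


def read_gbd_csv(path) -> pd.DataFrame:
    """Parse a GBD-results CSV into the internal DALY schema.

    Validates the schema (raising SchemaError naming any missing column),
    requires metric == 'Number', reports malformed numeric cells by row,
    and rejects rows whose bounds do not bracket the point estimate.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty — not a GBD results file") from None
    missing = [c for c in GBD_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} is missing mandatory column(s) {missing}")
    if len(raw) == 0:
        raise SchemaError(f"{path} has a header but no data rows")

    bad_rows: dict[int, str] = {}
    numeric = {}
    for col in ("year", "val", "upper", "lower"):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        for idx in raw.index[parsed.isna() & raw[col].notna()]:
            bad_rows.setdefault(int(idx), f"non-numeric {col}={raw.loc[idx, col]!r}")
        for idx in raw.index[raw[col].isna()]:
            bad_rows.setdefault(int(idx), f"missing {col}")
        numeric[col] = parsed
    if bad_rows:
        listing = "; ".join(f"row {i}: {msg}" for i, msg in sorted(bad_rows.items())[:20])
        raise DataError(f"{path}: {len(bad_rows)} malformed row(s): {listing}")

    not_number = raw["metric"] != "Number"
    if not_number.any():
        vals = sorted(raw.loc[not_number, "metric"].unique())
        raise SchemaError(f"{path}: expected metric 'Number' for DALY counts, found {vals}")
    swapped = numeric["upper"] < numeric["lower"]
    if swapped.any():
        rows = [int(i) for i in raw.index[swapped][:20]]
        raise DataError(f"{path}: upper < lower on row(s) {rows}")

    out = pd.DataFrame({
        "country": raw["location"],
        "year": numeric["year"].astype(int),
        "age": raw["age"],
        "cause": raw["cause"],
        "val": numeric["val"],
        "lower": numeric["lower"],
        "upper": numeric["upper"],
    })
    return out


_YEAR_COL = re.compile(r"^\d{4}$")


def read_worldbank_csv(path, indicator: str | None = None) -> pd.DataFrame:
    """Read a World Bank style indicator table, tidy or wide, auto-detected.

    Tidy files carry columns (country, year, value) — optionally an
    ``indicator`` column, filtered when ``indicator`` is given.  Wide files
    carry one row per country with 4-digit year columns.  Missing cells
    become NaN, never zero.  Returns tidy (country, year, value).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None

    year_cols = [c for c in raw.columns if _YEAR_COL.match(str(c))]
    if year_cols and "country" in raw.columns:
        tidy = raw.melt(id_vars=[c for c in raw.columns if c not in year_cols],
                        value_vars=year_cols, var_name="year", value_name="value")
        tidy["year"] = tidy["year"].astype(int)
    elif {"country", "year", "value"} <= set(raw.columns):
        tidy = raw.copy()
        tidy["year"] = pd.to_numeric(tidy["year"], errors="coerce")
        if tidy["year"].isna().any():
            rows = [int(i) for i in tidy.index[tidy["year"].isna()][:20]]
            raise DataError(f"{path}: non-numeric year on row(s) {rows}")
        tidy["year"] = tidy["year"].astype(int)
    else:
        raise SchemaError(
            f"{path}: unrecognized dialect — need either 4-digit year columns "
            "or (country, year, value) columns"
        )
    if indicator is not None and "indicator" in tidy.columns:
        tidy = tidy[tidy["indicator"] == indicator]
    value = pd.to_numeric(tidy["value"], errors="coerce")
    bad = value.isna() & tidy["value"].notna()
    if bad.any():
        where = [(int(i), str(tidy.loc[i, "country"])) for i in tidy.index[bad][:20]]
        raise DataError(f"{path}: non-numeric value cells at (row, country) {where}")
    out = tidy[["country", "year"]].copy()
    out["value"] = value
    return out.sort_values(["country", "year"], ignore_index=True)


def write_panel_csv(df: pd.DataFrame, path, units: dict[str, str] | None = None) -> None:
    """Tidy CSV with a commented units header line."""
    units = units or df.attrs.get("units", {})
    with open(path, "w") as fh:
        if units:
            fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        df.to_csv(fh, index=False)


def read_panel_csv(path) -> pd.DataFrame:
    """Read a tidy CSV written by :func:`write_panel_csv`, restoring units metadata."""
    path = Path(path)
    units = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# units:"):
        for part in first[len("# units:"):].strip().split(", "):
            if "=" in part:
                k, v = part.split("=", 1)
                units[k] = v
    df = pd.read_csv(path, comment="#")
    if units:
        df.attrs["units"] = units
    return df


def default_units(columns) -> dict[str, str]:
    """Column -> unit labels for the monetary outputs."""
    money_cols = {"burden", "lower", "upper", "vsl", "vsly", "gdp", "gnipc",
                  "estimate", "ci_lower", "ci_upper", "absolute_contribution"}
    return {c: MONEY_UNIT for c in columns if c in money_cols}


def summary_shares_ok(summary: dict, tol: float = 0.1) -> bool:
    """Check that every share partition in a pipeline summary sums to ~100."""
    ok = True
    for key, block in summary.items():
        if isinstance(block, dict) and key.endswith("_shares_pct"):
            ok = ok and abs(sum(block.values()) - 100.0) <= tol
    return ok
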