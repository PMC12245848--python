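"""Monetization, aggregation and report arithmetic."""

import numpy as np
import pandas as pd
import pytest

from hmburden import burden as bd
from hmburden.errors import (
    ConfigurationError,
    DataError,
    DegenerateInputError,
    DomainError,
)
from hmburden.valuation import VslParams


def _dalys(rows):
    return pd.DataFrame(rows, columns=["country", "year", "cause", "val", "lower", "upper"])


def _vsly(rows):
    return pd.DataFrame(rows, columns=["country", "year", "vsly"])


def test_monetize_base_year_is_pure_multiplication(params):
    out = bd.monetize(
        _dalys([("A", 2021, "HM", 1000.0, 900.0, 1100.0)]),
        _vsly([("A", 2021, 50_000.0)]),
        params,
    )
    assert out["burden"].iloc[0] == pytest.approx(5.0e7)
    assert out["lower"].iloc[0] == pytest.approx(4.5e7)
    assert out["upper"].iloc[0] == pytest.approx(5.5e7)


def test_monetize_zero_dalys_zero_burden(params):
    out = bd.monetize(_dalys([("A", 2021, "HM", 0.0, 0.0, 0.0)]),
                      _vsly([("A", 2021, 50_000.0)]), params)
    assert out["burden"].iloc[0] == 0.0


def test_monetize_discounts_future_years(params):
    out = bd.monetize(_dalys([("A", 2022, "HM", 1000.0, 1000.0, 1000.0)]),
                      _vsly([("A", 2022, 50_000.0)]), params)
    assert out["burden"].iloc[0] == pytest.approx(5.0e7 / 1.03)


def test_monetize_cpi_adjusts_past_years(params):
    cpi = pd.Series({1990: 50.0, 2021: 100.0})
    out = bd.monetize(_dalys([("A", 1990, "HM", 10.0, 10.0, 10.0)]),
                      _vsly([("A", 1990, 1000.0)]), params, cpi)
    assert out["burden"].iloc[0] == pytest.approx(10.0 * 1000.0 * 2.0)


def test_monetize_requires_vsly_rows(params):
    with pytest.raises(DataError, match="no VSLY"):
        bd.monetize(_dalys([("A", 2021, "HM", 1.0, 1.0, 1.0)]),
                    _vsly([("B", 2021, 1.0)]), params)


def test_monetize_sums_out_age_column(params):
    dalys = pd.DataFrame({
        "country": "A", "year": 2021, "cause": "HM",
        "age": ["0-4", "5-9"], "val": [10.0, 20.0],
        "lower": [8.0, 16.0], "upper": [12.0, 24.0],
    })
    out = bd.monetize(dalys, _vsly([("A", 2021, 100.0)]), params)
    assert len(out) == 1
    assert out["burden"].iloc[0] == pytest.approx(3000.0)


def test_monetize_is_bilinear(params):
    dalys = _dalys([("A", 2021, "HM", 100.0, 90.0, 110.0),
                    ("B", 2021, "HM", 7.0, 6.0, 8.0)])
    vsly = _vsly([("A", 2021, 10.0), ("B", 2021, 20.0)])
    base = bd.monetize(dalys, vsly, params)
    scaled = dalys.copy()
    scaled[["val", "lower", "upper"]] *= 3.0
    out = bd.monetize(scaled, vsly, params)
    np.testing.assert_allclose(out["burden"], 3.0 * base["burden"])
    # shares are invariant under the scaling
    assert bd.share_of_total(out["burden"][0], out["burden"].sum()) == pytest.approx(
        bd.share_of_total(base["burden"][0], base["burden"].sum()))


@pytest.fixture
def planted_burden():
    """Four income groups with planted totals 1, 2, 3, 4 (billions)."""
    rows, imap = [], []
    for i, (g, total) in enumerate(zip(["HIC", "UMIC", "LMIC", "LIC"], [1e9, 2e9, 3e9, 4e9])):
        for j in range(2):  # two countries per group, splitting the total 60/40
            c = f"{g}{j}"
            rows.append((c, 2021, "HM", total * (0.6 if j == 0 else 0.4), np.nan, np.nan))
            imap.append((c, g))
    burden = pd.DataFrame(rows, columns=["country", "year", "cause", "burden", "lower", "upper"])
    burden = burden.drop(columns=["lower", "upper"])
    income_map = pd.DataFrame(imap, columns=["country", "income_group"])
    return burden, income_map


def test_aggregate_recovers_planted_totals(planted_burden):
    burden, income_map = planted_burden
    ig = bd.aggregate(burden, "income_group", income_map=income_map)
    got = ig.set_index("income_group")["burden"]
    assert got["HIC"] == pytest.approx(1e9) and got["LIC"] == pytest.approx(4e9)
    # partition-sum identity
    total = bd.aggregate(burden, "global")["burden"].iloc[0]
    assert ig["burden"].sum() == pytest.approx(total)
    assert total == pytest.approx(1e10)


def test_aggregate_single_country_equals_global():
    burden = pd.DataFrame({"country": ["A"], "year": [2021], "cause": ["HM"], "burden": [5.0]})
    assert bd.aggregate(burden, "country")["burden"].iloc[0] == pytest.approx(
        bd.aggregate(burden, "global")["burden"].iloc[0])


def test_aggregate_unknown_grouping(planted_burden):
    with pytest.raises(ConfigurationError):
        bd.aggregate(planted_burden[0], "continent")


def test_share_report_sums_to_100(planted_burden):
    burden, income_map = planted_burden
    ig = bd.aggregate(burden, "income_group", income_map=income_map)
    rep = bd.share_report(ig, "income_group")
    assert rep["share_pct"].sum() == pytest.approx(100.0, abs=1e-9)


@pytest.mark.parametrize(
    "v0, v1, expected",
    [
        (992.0, 1516.0, 52.8),      # global burden 1990 -> 2021
        (462.63, 651.0, 40.7),      # leukemia
        (337.66, 542.91, 60.8),     # non-Hodgkin lymphoma
        (138.71, 278.17, 100.5),    # multiple myeloma
        (55.48, 43.84, -21.0),      # Hodgkin lymphoma declines
        (7.0, 7.0, 0.0),
    ],
)
def test_percent_change(v0, v1, expected):
    assert bd.percent_change(v0, v1) == pytest.approx(expected, abs=0.05)


def test_percent_change_rejects_zero_baseline():
    with pytest.raises(DomainError):
        bd.percent_change(0.0, 1.0)


@pytest.mark.parametrize(
    "part, total, expected",
    [(651.0, 1516.0, 42.94), (855.0, 992.0, 86.2), (542.91, 1516.0, 35.81), (5.0, 5.0, 100.0)],
)
def test_share_of_total(part, total, expected):
    assert bd.share_of_total(part, total) == pytest.approx(expected, abs=0.05)


def test_gdp_share():
    assert bd.gdp_share(5.0, 5.0) == 1.0
    assert bd.gdp_share(0.0, 5.0) == 0.0
    assert bd.gdp_share(0.01 * 3e12, 3e12) == pytest.approx(0.01)
    with pytest.raises(DomainError):
        bd.gdp_share(1.0, 0.0)


def test_quintile_bins_exact_split():
    values = pd.Series(np.arange(1.0, 11.0), index=[f"C{i}" for i in range(10)])
    assert list(bd.quintile_bins(values)) == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]


def test_quintile_bins_rejects_degenerate():
    with pytest.raises(DegenerateInputError):
        bd.quintile_bins(pd.Series([1.0] * 10))
    with pytest.raises(DegenerateInputError):
        bd.quintile_bins(pd.Series([1.0, 2.0, 3.0]))


def test_quintile_bins_balanced_at_study_scale(rng):
    values = pd.Series(rng.lognormal(20, 2, size=204))
    sizes = bd.quintile_bins(values).value_counts()
    assert set(sizes.index) == {1, 2, 3, 4, 5}
    assert sizes.min() >= 40 and sizes.max() <= 41
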