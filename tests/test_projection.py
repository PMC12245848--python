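"""Scenario closed forms, BAPC recovery, forecasting, burden projection."""

import numpy as np
import pandas as pd
import pytest

from hmburden import synthetic
from hmburden.errors import ConfigurationError, DataError, DomainError
from hmburden.projection import (
    BapcPriorConfig,
    ScenarioSpec,
    fit_bapc,
    forecast_bapc,
    project_burden,
    scenario_rates,
)
from hmburden.synthetic import ApcTruth
from hmburden.valuation import VslParams


# --- scenarios -------------------------------------------------------------


def test_scenario_spec_validates_multiplier():
    assert ScenarioSpec("baseline").annual_multiplier == 1.0
    with pytest.raises(ConfigurationError):
        ScenarioSpec("negative", annual_multiplier=0.99)
    with pytest.raises(ConfigurationError):
        ScenarioSpec("worst-case")


@pytest.mark.parametrize(
    "name, year, factor",
    [
        ("baseline", 2035, 1.0),
        ("baseline", 2050, 1.0),
        ("negative", 2022, 1.01),
        ("negative", 2050, 1.01**29),
        ("positive", 2050, 0.99**29),
    ],
)
def test_scenario_closed_forms(name, year, factor):
    rates = np.array([0.1, 0.2, 0.5])
    np.testing.assert_allclose(scenario_rates(rates, ScenarioSpec(name), year), rates * factor)


def test_scenario_rejects_past_years():
    with pytest.raises(DomainError):
        scenario_rates(np.array([0.1]), ScenarioSpec("baseline"), 2019)


def test_scenario_commutes_with_age_aggregation():
    rates = np.array([0.1, 0.3])
    pops = np.array([100.0, 300.0])
    spec = ScenarioSpec("positive")
    direct = pops @ scenario_rates(rates, spec, 2040)
    aggregated = scenario_rates(pops @ rates, spec, 2040)
    assert direct == pytest.approx(aggregated)


# --- BAPC fit --------------------------------------------------------------


def test_bapc_input_validation():
    good = np.ones((5, 8))
    with pytest.raises(DataError, match="5 ages x 8 periods"):
        fit_bapc(np.ones((4, 8)), np.ones((4, 8)))
    with pytest.raises(DataError, match="integer"):
        fit_bapc(good + 0.5, np.ones((5, 8)))
    with pytest.raises(DataError, match="positive"):
        fit_bapc(good, np.zeros((5, 8)))
    with pytest.raises(DataError, match="shape"):
        fit_bapc(good, np.ones((5, 9)))


def test_bapc_null_model_recovery():
    """Data with no age/period/cohort structure: every effect's posterior
    mean lies inside its own 95% credible interval of zero, and mu recovers
    the log rate."""
    A, J = 8, 12
    truth = ApcTruth(np.log(0.01), np.zeros(A), np.zeros(J), np.zeros(A + J - 1),
                     constrained=True)
    counts = synthetic.gen_apc_counts(truth, 5e4, seed=11)
    fit = fit_bapc(counts, np.full((A, J), 5e4))
    assert fit.converged
    for name in ("alpha", "beta", "gamma"):
        mean = getattr(fit, f"{name}_mean")
        sd = getattr(fit, f"{name}_sd")
        assert np.all(np.abs(mean) <= 1.959964 * sd), name
    assert fit.mu_mean == pytest.approx(np.log(0.01), abs=0.05)


def test_bapc_simulation_recovery():
    """Known smooth APC effects on a 10x20 grid, exposure 1e5: the
    posterior-mean age effect correlates > 0.95 with the truth."""
    rng = np.random.default_rng(42)
    truth = synthetic.make_smooth_apc_truth(10, 20, rng, mu=np.log(1e-3),
                                            period_slope=0.02)
    counts = synthetic.gen_apc_counts(truth, 1e5, seed=7)
    fit = fit_bapc(counts, np.full((10, 20), 1e5))
    corr = np.corrcoef(fit.alpha_mean, truth.alpha)[0, 1]
    assert corr > 0.95
    # constrained effects sum to ~0
    for v in (fit.alpha_mean, fit.beta_mean, fit.gamma_mean):
        assert abs(v.sum()) < 1e-6
    assert np.all(fit.fitted_rates > 0)


def test_bapc_fitted_rates_track_crude_rates():
    """In well-specified simulations the fitted rates stay within 2 predictive
    sd of the observed crude rates on >= 95% of cells (averaged over
    replicate grids to tame single-grid binomial noise)."""
    rng = np.random.default_rng(1)
    truth = synthetic.make_smooth_apc_truth(8, 15, rng, mu=np.log(2e-3), period_slope=-0.01)
    E = 2e5
    fractions = []
    for seed in range(2, 8):
        counts = synthetic.gen_apc_counts(truth, E, seed=seed)
        fit = fit_bapc(counts, np.full((8, 15), E))
        crude = counts / E
        resid = np.abs(fit.fitted_rates - crude)
        # predictive sd per cell: Poisson noise of the crude rate plus the
        # posterior sd of the fitted rate
        sd = np.sqrt(np.maximum(counts, 1.0) / E**2 + fit.fitted_rate_sd**2)
        fractions.append(np.mean(resid <= 2.0 * sd))
    assert np.mean(fractions) >= 0.95


def test_bapc_exposure_scale_invariance():
    rng = np.random.default_rng(0)
    truth = synthetic.make_smooth_apc_truth(10, 20, rng, mu=np.log(1e-3), period_slope=0.01)
    f1 = fit_bapc(synthetic.gen_apc_counts(truth, 1e5, 1), np.full((10, 20), 1e5))
    f2 = fit_bapc(synthetic.gen_apc_counts(truth, 2e5, 2), np.full((10, 20), 2e5))
    dlog = np.abs(np.log(f1.fitted_rates) - np.log(f2.fitted_rates))
    assert np.median(dlog) < 0.05


# --- BAPC forecast ---------------------------------------------------------


@pytest.fixture(scope="module")
def linear_trend_fit():
    A, J = 6, 12
    slope = 0.05
    beta = slope * (np.arange(J) - np.arange(J).mean())
    truth = ApcTruth(np.log(5e-3), np.zeros(A), beta, np.zeros(A + J - 1), constrained=True)
    counts = np.round(np.full((A, J), 1e6) * np.exp(truth.linear_predictor()))
    strong = BapcPriorConfig(ig_shape=1e6, ig_rate=1e-2)  # pins the RW2 variances near zero
    return slope, fit_bapc(counts, np.full((A, J), 1e6), strong)


def test_forecast_continues_linear_trend(linear_trend_fit):
    """In the zero-variance RW2 limit the forecast continues the in-sample
    linear log-rate trend; the horizon-5 slope stays within 10%."""
    slope, fit = linear_trend_fit
    fc = forecast_bapc(fit, 5)
    in_sample_last = np.log(fit.fitted_rates[:, -1])
    implied_slope = (fc.mean_log[:, 4] - in_sample_last) / 5.0
    np.testing.assert_allclose(implied_slope, slope, rtol=0.10)


def test_forecast_interval_width_monotone_in_horizon():
    rng = np.random.default_rng(5)
    truth = synthetic.make_smooth_apc_truth(8, 15, rng, mu=np.log(1e-3))
    counts = synthetic.gen_apc_counts(truth, 5e4, seed=3)
    fit = fit_bapc(counts, np.full((8, 15), 5e4))
    fc = forecast_bapc(fit, 6)
    assert np.all(np.diff(fc.sd_log, axis=1) >= -1e-12)
    assert np.all(fc.lower <= fc.median) and np.all(fc.median <= fc.upper)


def test_forecast_horizon_bounds():
    rng = np.random.default_rng(6)
    truth = synthetic.make_smooth_apc_truth(6, 10, rng)
    fit = fit_bapc(synthetic.gen_apc_counts(truth, 1e4, 1), np.full((6, 10), 1e4))
    with pytest.raises(DomainError):
        forecast_bapc(fit, 0)
    with pytest.raises(ConfigurationError):
        forecast_bapc(fit, 50, max_extrapolation=10)


# --- burden projection -----------------------------------------------------


def _proj_inputs(years=(2030, 2040, 2050), rate=1e-3, pop=1e6, vsly=5e4):
    rates = pd.DataFrame([("A", y, "all", rate) for y in years],
                         columns=["country", "year", "age", "rate"])
    population = pd.DataFrame([("A", y, "all", pop) for y in years],
                              columns=["country", "year", "age", "population"])
    v = pd.DataFrame([("A", y, vsly) for y in years], columns=["country", "year", "vsly"])
    return rates, population, v


def test_project_burden_growth_cancels_discount(params):
    """Constant rates and population with VSLY growing at the discount rate
    give a constant discounted burden."""
    years = (2030, 2040, 2050)
    rates, population, v = _proj_inputs(years)
    v["vsly"] = 5e4 * 1.03 ** (v["year"] - 2021)
    out = project_burden(rates, population, v, params, years)
    np.testing.assert_allclose(out["burden"], out["burden"].iloc[0], rtol=1e-12)


def test_project_burden_zero_rates(params):
    rates, population, v = _proj_inputs(rate=0.0)
    out = project_burden(rates, population, v, params)
    assert (out["burden"] == 0.0).all()


def test_project_burden_planted_product(params):
    rates, population, v = _proj_inputs(years=(2050,), rate=2e-3, pop=1e7, vsly=1e5)
    out = project_burden(rates, population, v, params, years=(2050,))
    dalys = 2e-3 * 1e7
    assert out["dalys"].iloc[0] == pytest.approx(dalys)
    assert out["burden"].iloc[0] == pytest.approx(dalys * 1e5 / 1.03**29)


def test_project_burden_missing_year(params):
    rates, population, v = _proj_inputs(years=(2030, 2040))
    with pytest.raises(DataError, match="2050"):
        project_burden(rates, population, v, params, years=(2030, 2040, 2050))


def test_burden_share_shifts_from_hic_to_umic(params):
    """When rates fall sharply in the HIC and its valuation stagnates while
    the UMIC's valuation surges, the projected global share moves from the
    HIC to the UMIC group."""
    years = (2030, 2040, 2050)
    rows_r, rows_p, rows_v = [], [], []
    for y in [2021, *years]:
        h = y - 2021
        rows_r += [("HIC1", y, "all", 2e-3 * 0.96**h), ("UMIC1", y, "all", 1e-3)]
        rows_p += [("HIC1", y, "all", 5e7), ("UMIC1", y, "all", 2e8)]
        rows_v += [("HIC1", y, 2e5 * 1.003**h), ("UMIC1", y, 2e4 * 1.06**h)]
    rates = pd.DataFrame(rows_r, columns=["country", "year", "age", "rate"])
    pop = pd.DataFrame(rows_p, columns=["country", "year", "age", "population"])
    v = pd.DataFrame(rows_v, columns=["country", "year", "vsly"])
    out = project_burden(rates, pop, v, params, years=(2021, *years))
    shares = out.pivot(index="year", columns="country", values="burden")
    share_hic = shares["HIC1"] / shares.sum(axis=1)
    assert share_hic.loc[2050] < share_hic.loc[2021]
    assert (1 - share_hic).loc[2050] > (1 - share_hic).loc[2021]
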