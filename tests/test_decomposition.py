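"""Shapley decomposition: oracle equivalence, axioms, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmburden.decomposition import (
    FACTORS,
    DecompositionResult,
    FactorState,
    aggregate_decomposition,
    burden_from_factors,
    decomposition_table,
    shapley_decompose,
    shapley_decompose_bruteforce,
)
from hmburden.errors import DataError, DomainError, ShapeError


def _random_state(rng, n_age=4):
    s = rng.dirichlet(np.ones(n_age))
    return FactorState(
        population=float(rng.uniform(1e5, 1e8)),
        age_structure=s,
        daly_rates=rng.uniform(0.0, 5e-3, n_age),
        vsly=float(rng.uniform(1e3, 5e5)),
    )


def test_burden_from_factors_single_age():
    state = FactorState(1e6, np.array([1.0]), np.array([0.001]), 50_000.0)
    assert burden_from_factors(state) == pytest.approx(5.0e7)


def test_burden_from_factors_zero_rates():
    state = FactorState(1e6, np.array([0.5, 0.5]), np.array([0.0, 0.0]), 50_000.0)
    assert burden_from_factors(state) == 0.0


def test_collapsed_age_groups_preserve_cost():
    """Two age groups and their one-group collapse with the matched aggregate
    rate give the same cost."""
    s = np.array([0.3, 0.7])
    r = np.array([0.004, 0.001])
    full = FactorState(2e6, s, r, 1e4)
    collapsed = FactorState(2e6, np.array([1.0]), np.array([float(s @ r)]), 1e4)
    assert burden_from_factors(full) == pytest.approx(burden_from_factors(collapsed))


def test_two_factor_hand_oracle():
    """D: 10 -> 20 and V: 5 -> 8 in C = D x V; total 110 splits 65/45."""
    s0 = FactorState(10.0, np.array([1.0]), np.array([1.0]), 5.0)
    s1 = FactorState(20.0, np.array([1.0]), np.array([1.0]), 8.0)
    res = shapley_decompose(s0, s1)
    assert res.total_change == pytest.approx(110.0)
    assert res.absolute["population_growth"] == pytest.approx(65.0)
    assert res.absolute["vsly"] == pytest.approx(45.0)
    assert res.absolute["population_aging"] == 0.0
    assert res.absolute["epidemiological_change"] == 0.0


def test_dummy_factor_gets_zero(rng):
    s0 = _random_state(rng)
    s1 = FactorState(s0.population * 1.7, s0.age_structure, s0.daly_rates, s0.vsly)
    res = shapley_decompose(s0, s1)
    assert res.percent["population_growth"] == pytest.approx(100.0)
    for f in ("vsly", "population_aging", "epidemiological_change"):
        assert res.absolute[f] == pytest.approx(0.0, abs=1e-9)


def test_identical_states_are_degenerate(rng):
    s0 = _random_state(rng)
    res = shapley_decompose(s0, s0)
    assert res.degenerate and res.percent is None
    assert all(abs(v) < 1e-9 for v in res.absolute.values())


def test_efficient_matches_bruteforce_on_100_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(100):
        s0, s1 = _random_state(rng), _random_state(rng)
        fast = shapley_decompose(s0, s1)
        slow = shapley_decompose_bruteforce(s0, s1)
        scale = max(abs(fast.total_change), 1e-12)
        for f in FACTORS:
            assert abs(fast.absolute[f] - slow.absolute[f]) < 1e-9 * scale
        # additivity: contributions sum to the total change
        assert abs(sum(fast.absolute.values()) - fast.total_change) < 1e-9 * scale


@settings(max_examples=50, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_additivity_and_rollup(seed):
    rng = np.random.default_rng(seed)
    s0, s1 = _random_state(rng), _random_state(rng)
    res = shapley_decompose(s0, s1)
    scale = max(abs(res.total_change), 1e-12)
    assert abs(sum(res.absolute.values()) - res.total_change) <= 1e-9 * scale
    if not res.degenerate:
        assert res.grouped_percent["vsly"] + res.grouped_percent["dalys"] == pytest.approx(100.0)
        daly_sum = sum(res.percent[f] for f in FACTORS if f != "vsly")
        assert res.grouped_percent["dalys"] == pytest.approx(daly_sum, abs=1e-6)


def test_order_independence(rng):
    s0, s1 = _random_state(rng), _random_state(rng)
    a = shapley_decompose(s0, s1, FACTORS)
    b = shapley_decompose(s0, s1, tuple(reversed(FACTORS)))
    for f in FACTORS:
        assert a.absolute[f] == pytest.approx(b.absolute[f], rel=1e-12)


def test_state_validation():
    with pytest.raises(DomainError):
        FactorState(0.0, np.array([1.0]), np.array([0.1]), 1.0)
    with pytest.raises(DomainError):
        FactorState(1.0, np.array([0.6, 0.6]), np.array([0.1, 0.1]), 1.0)
    with pytest.raises(ShapeError):
        FactorState(1.0, np.array([1.0]), np.array([0.1, 0.2]), 1.0)


def test_aggregate_identity_and_planted_world(rng):
    s0 = _random_state(rng)
    s1 = FactorState(s0.population, s0.age_structure, s0.daly_rates, s0.vsly * 2.0)
    single = shapley_decompose(s0, s1)
    agg = aggregate_decomposition([single])
    assert agg.absolute == pytest.approx(single.absolute)
    # a world where only the VSLY changes in every country
    results = []
    for _ in range(5):
        a = _random_state(rng)
        b = FactorState(a.population, a.age_structure, a.daly_rates, a.vsly * rng.uniform(1.2, 3.0))
        results.append(shapley_decompose(a, b))
    world = aggregate_decomposition(results)
    assert world.percent["vsly"] == pytest.approx(100.0)
    assert world.grouped_percent["dalys"] == pytest.approx(0.0, abs=1e-9)


def test_aggregate_cancelling_changes_flagged_degenerate():
    s = FactorState(10.0, np.array([1.0]), np.array([1.0]), 5.0)
    up = shapley_decompose(s, FactorState(20.0, np.array([1.0]), np.array([1.0]), 5.0))
    down = shapley_decompose(s, FactorState(10.0, np.array([1.0]), np.array([1.0]), 5.0))
    # build an exact mirror of `up`
    mirror = DecompositionResult(
        absolute={f: -v for f, v in up.absolute.items()},
        total_change=-up.total_change,
        percent=None, grouped_absolute={}, grouped_percent=None, degenerate=False,
    )
    agg = aggregate_decomposition([up, mirror])
    assert agg.degenerate and agg.percent is None
    del down


def test_aggregate_empty_list_rejected():
    with pytest.raises(DataError):
        aggregate_decomposition([])


def test_decomposition_table_structure(rng):
    s0, s1 = _random_state(rng), _random_state(rng)
    table = decomposition_table(shapley_decompose(s0, s1))
    assert list(table["factor"])[:3] == ["Total cost change", "Change due to VSLY",
                                         "Change due to DALYs"]
    assert table["percent_contribution"].iloc[0] == pytest.approx(100.0)
    assert table["percent_contribution"].iloc[1] + table["percent_contribution"].iloc[2] == (
        pytest.approx(100.0))
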