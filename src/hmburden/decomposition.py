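"""Shapley decomposition of the change in monetized burden.

The burden of one country in one year factors as

    C = sum_a  P * s_a * r_a * V

with P the total population, s the age-structure fractions, r the
age-specific DALY rates and V the VSLY.  The change in C between two years
is attributed to four factors — VSLY (V), population growth (P), population
aging (s) and epidemiological change (r) — by the Shapley rule: each
factor's contribution is its marginal effect on C averaged over all orders
in which the factors could be switched from the start-year to the end-year
state.  The rule is exactly additive (contributions sum to the total
change), order-independent, and gives zero to a factor that did not change.

Country-level results aggregate to global ones by summing absolute
contributions; global percentages are re-derived from the summed totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np

from .errors import DataError, DomainError, ShapeError

FACTORS = ("vsly", "population_growth", "population_aging", "epidemiological_change")

#: Grouped rollup: the valuation factor vs the three DALY-side factors.
DALY_FACTORS = ("population_growth", "population_aging", "epidemiological_change")


@dataclass(frozen=True)
class FactorState:
    """One country-year in factorized form: (P, s, r, V)."""

    population: float
    age_structure: np.ndarray
    daly_rates: np.ndarray
    vsly: float

    def __post_init__(self):
        object.__setattr__(self, "age_structure", np.asarray(self.age_structure, dtype=float))
        object.__setattr__(self, "daly_rates", np.asarray(self.daly_rates, dtype=float))
        if self.population <= 0:
            raise DomainError("population must be positive")
        if self.vsly <= 0:
            raise DomainError("VSLY must be positive")
        if self.age_structure.shape != self.daly_rates.shape:
            raise ShapeError("age_structure and daly_rates must have equal length")
        if abs(self.age_structure.sum() - 1.0) > 1e-9:
            raise DomainError("age-structure fractions must sum to 1")
        if np.any(self.daly_rates < 0):
            raise DomainError("DALY rates must be non-negative")


def burden_from_factors(state: FactorState) -> float:
    """C = sum_a P * s_a * r_a * V."""
    return float(state.population * state.vsly * (state.age_structure @ state.daly_rates))


@dataclass
class DecompositionResult:
    """Absolute and percent contributions per factor, with the VSLY/DALYs rollup.

    ``percent`` entries are None when the total change is (numerically)
    zero, in which case ``degenerate`` is True.
    """

    absolute: dict[str, float]
    total_change: float
    percent: dict[str, float] | None
    grouped_absolute: dict[str, float]
    grouped_percent: dict[str, float] | None
    degenerate: bool = False


def _finalize(absolute: dict[str, float], total_change: float) -> DecompositionResult:
    grouped_abs = {
        "vsly": absolute.get("vsly", 0.0),
        "dalys": sum(absolute[f] for f in absolute if f != "vsly"),
    }
    scale = max(sum(abs(v) for v in absolute.values()), abs(total_change))
    degenerate = abs(total_change) <= 1e-12 * max(scale, 1e-300) or total_change == 0.0
    if degenerate:
        return DecompositionResult(absolute, total_change, None, grouped_abs, None, True)
    percent = {f: 100.0 * v / total_change for f, v in absolute.items()}
    grouped_pct = {g: 100.0 * v / total_change for g, v in grouped_abs.items()}
    return DecompositionResult(absolute, total_change, percent, grouped_abs, grouped_pct, False)


def _hybrid(state_0: FactorState, state_1: FactorState, flipped: frozenset) -> FactorState:
    return FactorState(
        population=(state_1 if "population_growth" in flipped else state_0).population,
        age_structure=(state_1 if "population_aging" in flipped else state_0).age_structure,
        daly_rates=(state_1 if "epidemiological_change" in flipped else state_0).daly_rates,
        vsly=(state_1 if "vsly" in flipped else state_0).vsly,
    )


def shapley_decompose(
    state_0: FactorState,
    state_1: FactorState,
    factors: tuple[str, ...] = FACTORS,
) -> DecompositionResult:
    """Exact Shapley attribution of C(state_1) - C(state_0) to ``factors``.

    Uses the subset-weighted form (2^n cost evaluations) rather than
    enumerating all n! orderings; both are exact and the permutation form
    serves as an independent oracle in the test suite.
    """
    if len(set(factors)) != len(factors):
        raise DataError("factor names must be unique")
    unknown = set(factors) - set(FACTORS)
    if unknown:
        raise DataError(f"unknown factors {sorted(unknown)}; expected a subset of {FACTORS}")
    if state_0.age_structure.shape != state_1.age_structure.shape:
        raise ShapeError("states must share the age grid")

    n = len(factors)
    cost = {
        frozenset(s): burden_from_factors(_hybrid(state_0, state_1, frozenset(s)))
        for size in range(n + 1)
        for s in combinations(factors, size)
    }
    absolute = {}
    for f in factors:
        others = [g for g in factors if g != f]
        contrib = 0.0
        for size in range(n):
            w = factorial(size) * factorial(n - size - 1) / factorial(n)
            for s in combinations(others, size):
                contrib += w * (cost[frozenset(s) | {f}] - cost[frozenset(s)])
        absolute[f] = contrib
    total = cost[frozenset(factors)] - cost[frozenset()]
    return _finalize(absolute, total)


def shapley_decompose_bruteforce(
    state_0: FactorState,
    state_1: FactorState,
    factors: tuple[str, ...] = FACTORS,
) -> DecompositionResult:
    """Reference implementation: average marginal contributions over all n! orderings."""
    from itertools import permutations

    absolute = {f: 0.0 for f in factors}
    n_orders = factorial(len(factors))
    for order in permutations(factors):
        flipped: set[str] = set()
        prev = burden_from_factors(_hybrid(state_0, state_1, frozenset()))
        for f in order:
            flipped.add(f)
            cur = burden_from_factors(_hybrid(state_0, state_1, frozenset(flipped)))
            absolute[f] += (cur - prev) / n_orders
            prev = cur
    total = burden_from_factors(state_1) - burden_from_factors(state_0)
    return _finalize(absolute, total)


def aggregate_decomposition(per_country: list[DecompositionResult]) -> DecompositionResult:
    """Sum absolute contributions across countries; percentages from the sums.

    If country-level total changes cancel (global denominator ~ 0) the
    result is flagged degenerate and percentages are None.
    """
    if not per_country:
        raise DataError("cannot aggregate an empty list of decompositions")
    factors = list(per_country[0].absolute)
    absolute = {f: sum(r.absolute[f] for r in per_country) for f in factors}
    total = sum(r.total_change for r in per_country)
    scale = sum(abs(r.total_change) for r in per_country)
    if abs(total) <= 1e-9 * max(scale, 1e-300):
        return _finalize(absolute, 0.0)
    return _finalize(absolute, total)


def decomposition_table(result: DecompositionResult):
    """Tidy factor/contribution table in the headline report's row order."""
    import pandas as pd

    if result.degenerate or result.percent is None:
        raise DataError("degenerate decomposition (total change ~ 0) has no percent table")
    rows = [
        ("Total cost change", result.total_change, 100.0),
        ("Change due to VSLY", result.grouped_absolute["vsly"], result.grouped_percent["vsly"]),
        ("Change due to DALYs", result.grouped_absolute["dalys"], result.grouped_percent["dalys"]),
        ("Population growth", result.absolute["population_growth"], result.percent["population_growth"]),
        ("Population aging", result.absolute["population_aging"], result.percent["population_aging"]),
        ("Epidemiological changes", result.absolute["epidemiological_change"],
         result.percent["epidemiological_change"]),
    ]
    return pd.DataFrame(rows, columns=["factor", "absolute_contribution", "percent_contribution"])


def factor_states_from_tables(dalys, pop_age, vsly, country: str, year: int,
                              age_order: list[str]) -> FactorState:
    """Build a FactorState for one country-year from the pipeline tables.

    ``dalys`` is an age-resolved DALY table (all causes summed or one
    cause), ``pop_age`` the population-by-age panel, ``vsly`` the VSLY
    table.  Age-specific rates are DALYs per person-year.
    """
    pops = (
        pop_age[(pop_age["country"] == country) & (pop_age["year"] == year)]
        .set_index("age")["population"].reindex(age_order)
    )
    if pops.isna().any():
        raise DataError(f"missing population by age for {country} {year}")
    d = (
        dalys[(dalys["country"] == country) & (dalys["year"] == year)]
        .groupby("age")["val"].sum().reindex(age_order).fillna(0.0)
    )
    v = vsly[(vsly["country"] == country) & (vsly["year"] == year)]["vsly"]
    if len(v) != 1:
        raise DataError(f"expected exactly one VSLY row for {country} {year}, got {len(v)}")
    P = float(pops.sum())
    s = pops.to_numpy() / P
    r = d.to_numpy() / pops.to_numpy()
    return FactorState(population=P, age_structure=s, daly_rates=r, vsly=float(v.iloc[0]))
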