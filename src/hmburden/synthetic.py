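"""Synthetic GBD-style worlds with known ground truth.

Everything downstream (valuation, monetization, decomposition, projection,
uncertainty) is exercised against worlds generated here, where the true
age-period-cohort rate structure, economic growth paths and demography are
known exactly.  The generator emulates the *shape* of the real inputs — a
burden-of-disease panel of DALY counts with 95% uncertainty intervals, a
World Bank style economic panel (GNI per capita PPP, GDP, CPI, income
group), and UN-WPP style demography (population by 5-year age band, median
age, life expectancy at the median age) — for 204 country-like units over
1990–2021 by default.

Age-specific DALY rates follow a log-linear age-period-cohort model

    log lambda_ij = mu + alpha_i + beta_j + gamma_k,   k = (A - 1 - i) + j

with Poisson sampling around population x rate, so the projection module's
inference can be validated by simulation recovery.  Uncertainty intervals
are symmetric multiplicative bands around the point estimate (real GBD UIs
are asymmetric; symmetry is chosen so the normal-resampling bootstrap stage
is exactly calibrated by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ShapeError

#: Hematologic malignancy subtypes, GBD cause-name spelling.
DEFAULT_CAUSES = (
    "Leukemia",
    "Non-Hodgkin lymphoma",
    "Multiple myeloma",
    "Hodgkin lymphoma",
)

#: Approximate share of total hematologic-malignancy DALYs per subtype.
CAUSE_WEIGHTS = {
    "Leukemia": 0.43,
    "Non-Hodgkin lymphoma": 0.33,
    "Multiple myeloma": 0.17,
    "Hodgkin lymphoma": 0.07,
}

INCOME_GROUPS = ("HIC", "UMIC", "LMIC", "LIC")

#: GNI-per-capita (PPP, international $) thresholds separating income groups,
#: echoing the World Bank scheme's ordering: a country with GNIpc below the
#: first threshold is LIC, between the first and second LMIC, and so on.
INCOME_THRESHOLDS = (4500.0, 12500.0, 30000.0)

# 2021-anchored GNIpc sampling bands (log-uniform) per target income group.
_GNI_BANDS = {
    "LIC": (1500.0, 4200.0),
    "LMIC": (5000.0, 12000.0),
    "UMIC": (13500.0, 28000.0),
    "HIC": (32000.0, 75000.0),
}

# Target crude DALY rate (all HM causes, per person-year) per income group;
# older populations carry more hematologic-malignancy burden.
_TARGET_CRUDE_RATE = {"HIC": 0.0025, "UMIC": 0.0015, "LMIC": 0.0012, "LIC": 0.0010}

# Period life expectancy at birth (start-of-panel) per income group.
_LE0 = {"HIC": 78.0, "UMIC": 72.0, "LMIC": 66.0, "LIC": 58.0}


@dataclass(frozen=True)
class AgeBand:
    """One age band: label, lower edge and width in years."""

    label: str
    lower: float
    width: float

    @property
    def midpoint(self) -> float:
        return self.lower + self.width / 2.0


def default_age_bands(n: int = 20) -> tuple[AgeBand, ...]:
    """GBD-style 5-year bands 0-4 ... with an open-ended top band.

    The open-ended band is represented with a nominal 10-year width so a
    midpoint exists for rate computations.
    """
    bands = []
    for i in range(n - 1):
        lo = 5 * i
        bands.append(AgeBand(f"{lo}-{lo + 4}", lo, 5.0))
    top = 5 * (n - 1)
    bands.append(AgeBand(f"{top}+", top, 10.0))
    return tuple(bands)


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of a synthetic world.

    Defaults mirror the study conditions: 204 country-like units, the
    1990–2021 panel, twenty 5-year age bands, and an income-group mix close
    to the World Bank 2021 classification.
    """

    n_countries: int = 204
    years: tuple[int, int] = (1990, 2021)
    age_bands: tuple[AgeBand, ...] = field(default_factory=default_age_bands)
    income_group_mix: dict[str, float] = field(
        default_factory=lambda: {"HIC": 0.30, "UMIC": 0.25, "LMIC": 0.25, "LIC": 0.20}
    )
    causes: tuple[str, ...] = DEFAULT_CAUSES
    gni_growth_range: tuple[float, float] = (-0.01, 0.06)
    seed: int = 0

    def __post_init__(self):
        if self.n_countries < 1:
            raise ConfigurationError("n_countries must be >= 1")
        if self.years[1] - self.years[0] < 1:
            raise ConfigurationError("years must span at least 2 calendar years")
        mix_sum = sum(self.income_group_mix.get(g, 0.0) for g in INCOME_GROUPS)
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigurationError(
                f"income_group_mix fractions must sum to 1 (got {mix_sum!r})"
            )
        if any(f < 0 for f in self.income_group_mix.values()):
            raise ConfigurationError("income_group_mix fractions must be non-negative")
        lowers = [b.lower for b in self.age_bands]
        uppers = [b.lower + b.width for b in self.age_bands]
        for i in range(1, len(lowers)):
            if lowers[i] < uppers[i - 1]:
                raise ConfigurationError("age bands must be ordered and non-overlapping")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1


@dataclass
class ApcTruth:
    """True age-period-cohort effects on the log-rate scale.

    ``gamma`` has length ``n_age + n_period - 1`` with cohort index
    ``k = (n_age - 1 - i) + j`` (oldest age band = earliest cohort).
    ``constrained`` records whether the identifiability constraints
    (sum-to-zero on all three effects, zero linear trend on cohort) have
    been applied.
    """

    mu: float
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    constrained: bool = False

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape[0] != self.alpha.shape[0] + self.beta.shape[0] - 1:
            raise ShapeError(
                "gamma must have length n_age + n_period - 1 "
                f"(got {self.gamma.shape[0]}, expected "
                f"{self.alpha.shape[0] + self.beta.shape[0] - 1})"
            )
        if self.constrained:
            for name, v in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
                if v.size and abs(v.sum()) > 1e-9 * max(1.0, np.abs(v).max()):
                    raise ConfigurationError(f"constrained {name} must sum to zero")

    @property
    def n_age(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_period(self) -> int:
        return self.beta.shape[0]

    def linear_predictor(self) -> np.ndarray:
        """(n_age, n_period) grid of mu + alpha_i + beta_j + gamma_k."""
        A, J = self.n_age, self.n_period
        i = np.arange(A)[:, None]
        j = np.arange(J)[None, :]
        k = (A - 1 - i) + j
        return self.mu + self.alpha[:, None] + self.beta[None, :] + self.gamma[k]

    def constrain(self) -> "ApcTruth":
        """Return an equivalent truth satisfying the identifiability constraints.

        The linear predictor is left exactly invariant: effect means move
        into ``mu``, and the cohort linear trend is reallocated to age and
        period (the shared-drift ambiguity of APC models).
        """
        A, J = self.n_age, self.n_period
        K = self.gamma.shape[0]
        alpha = self.alpha - self.alpha.mean()
        beta = self.beta - self.beta.mean()
        gamma = self.gamma - self.gamma.mean()
        mu = self.mu + self.alpha.mean() + self.beta.mean() + self.gamma.mean()
        # remove cohort linear trend c*(k - kbar); since k - kbar =
        # -(i - ibar) + (j - jbar) the trend moves into alpha and beta.
        k = np.arange(K, dtype=float)
        kc = k - k.mean()
        c = (gamma @ kc) / (kc @ kc)
        gamma = gamma - c * kc
        i = np.arange(A, dtype=float)
        j = np.arange(J, dtype=float)
        alpha = alpha - c * (i - i.mean())
        beta = beta + c * (j - j.mean())
        # re-center (detrending alpha/beta shifts are already mean-zero)
        return ApcTruth(mu=mu, alpha=alpha, beta=beta, gamma=gamma, constrained=True)


@dataclass
class SyntheticWorld:
    """A generated world: economy, demography, and per-country-cause rate truth."""

    config: WorldConfig
    econ: pd.DataFrame          # country, year, gnipc, gdp, cpi, income_group
    demog: pd.DataFrame         # country, year, population, median_age, le_at_median_age
    pop_age: pd.DataFrame       # country, year, age, population
    truth: dict[tuple[str, str], ApcTruth]  # (country, cause) -> ApcTruth

    @property
    def countries(self) -> list[str]:
        return sorted(self.econ["country"].unique())


def income_group_from_gnipc(gnipc, thresholds: tuple[float, ...] = INCOME_THRESHOLDS):
    """Classify GNI per capita into LIC/LMIC/UMIC/HIC — a monotone step function."""
    idx = np.searchsorted(np.asarray(thresholds), np.asarray(gnipc, dtype=float), side="right")
    groups = np.array(["LIC", "LMIC", "UMIC", "HIC"])
    out = groups[idx]
    return out if np.ndim(gnipc) else str(out)


def _largest_remainder_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    raw = {g: mix.get(g, 0.0) * n for g in INCOME_GROUPS}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(INCOME_GROUPS, key=lambda g: raw[g] - counts[g], reverse=True)
    for g in remainders[:short]:
        counts[g] += 1
    return counts


def _smooth_series(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Mean-zero smooth curve with standard deviation ``scale``.

    Doubly-integrated white noise, demeaned and rescaled so the amplitude
    does not grow with the series length (raw double integration drifts
    like n^1.5, which would imply implausibly steep terminal trends).
    """
    if n < 3 or scale == 0.0:
        return np.zeros(n)
    z = rng.normal(0.0, 1.0, size=n - 2)
    curve = np.concatenate([[0.0, 0.0], z]).cumsum().cumsum()
    curve = curve - curve.mean()
    sd = curve.std()
    return curve * (scale / sd) if sd > 0 else curve


def make_smooth_apc_truth(
    n_age: int,
    n_period: int,
    rng: np.random.Generator,
    mu: float = np.log(1e-3),
    age_amplitude: float = 1.0,
    period_slope: float = 0.0,
    wiggle: float = 0.02,
) -> ApcTruth:
    """Smooth random APC truth on the identifiable scale.

    Age effects combine a rising-with-age trend (hematologic-malignancy
    burden concentrates in older ages) with smooth noise; period effects get
    a linear drift plus smooth noise; cohort effects are smooth noise only.
    The result is returned fully constrained.
    """
    i = np.linspace(-1.0, 1.0, n_age)
    alpha = age_amplitude * (1.1 * i + 0.4 * i**2) + _smooth_series(rng, n_age, wiggle)
    j = np.arange(n_period, dtype=float)
    beta = period_slope * (j - j.mean()) + _smooth_series(rng, n_period, wiggle)
    gamma = _smooth_series(rng, n_age + n_period - 1, wiggle)
    return ApcTruth(mu=mu, alpha=alpha, beta=beta, gamma=gamma).constrain()


def gen_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a reproducible synthetic world from ``config``.

    GNI per capita follows country-specific geometric growth drawn from
    ``config.gni_growth_range``; age pyramids age smoothly via a per-country
    drift on the pyramid's exponential decay parameter; income groups are
    consistent with the GNIpc thresholds at the classification year (the
    panel's final year, capped at 2021) and frozen across the panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    years = np.array(config.year_list)
    class_year = min(config.years[1], 2021)
    counts = _largest_remainder_counts(config.income_group_mix, config.n_countries)

    groups: list[str] = []
    for g in INCOME_GROUPS:
        groups += [g] * counts[g]
    order = rng.permutation(config.n_countries)
    groups = [groups[o] for o in order]

    mids = np.array([b.midpoint for b in config.age_bands])
    n_age = len(config.age_bands)
    n_years = config.n_years

    econ_rows, demog_rows, pop_rows = [], [], []
    truth: dict[tuple[str, str], ApcTruth] = {}

    for c in range(config.n_countries):
        code = f"C{c + 1:03d}"
        group = groups[c]
        lo, hi = _GNI_BANDS[group]
        gni_at_class = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        growth = rng.uniform(*config.gni_growth_range)
        gni = gni_at_class * (1.0 + growth) ** (years - class_year)

        pop_total0 = np.exp(rng.uniform(np.log(1e5), np.log(3e8)))
        pop_growth = rng.uniform(0.0, 0.025)
        pop_total = pop_total0 * (1.0 + pop_growth) ** (years - years[0])

        # age pyramid: share_a ∝ exp(-lam * midpoint/100); lam shrinks over
        # time (population aging)
        lam0 = {"HIC": 0.9, "UMIC": 1.6, "LMIC": 2.3, "LIC": 3.0}[group] * rng.uniform(0.85, 1.15)
        aging_drift = rng.uniform(0.003, 0.015)
        # consumer-price inflation sits below typical nominal income growth
        inflation = rng.uniform(0.010, 0.025) if group == "HIC" else rng.uniform(0.015, 0.045)
        gdp_factor = rng.uniform(0.95, 1.05)

        le0 = _LE0[group] * rng.uniform(0.97, 1.03)

        for t, year in enumerate(years):
            lam = max(0.15, lam0 * np.exp(-aging_drift * t))
            shares = np.exp(-lam * mids / 100.0)
            shares = shares / shares.sum()
            pops = pop_total[t] * shares

            cum = np.cumsum(shares)
            b = int(np.searchsorted(cum, 0.5))
            prev_cum = cum[b - 1] if b > 0 else 0.0
            band = config.age_bands[b]
            median_age = band.lower + band.width * (0.5 - prev_cum) / shares[b]

            le_total = le0 + 0.08 * t
            le_at_median = max(5.0, le_total - 0.92 * median_age)

            econ_rows.append(
                (code, int(year), gni[t], gni[t] * pop_total[t] * gdp_factor,
                 100.0 * (1.0 + inflation) ** t, group)
            )
            demog_rows.append((code, int(year), pop_total[t], median_age, le_at_median))
            for a, bandx in enumerate(config.age_bands):
                pop_rows.append((code, int(year), bandx.label, pops[a]))

        # rate truth per cause, anchored to the group's target crude rate
        lam_anchor = max(0.15, lam0)
        shares0 = np.exp(-lam_anchor * mids / 100.0)
        shares0 = shares0 / shares0.sum()
        base = make_smooth_apc_truth(
            n_age, n_years, rng,
            mu=0.0,
            age_amplitude=rng.uniform(0.8, 1.2),
            period_slope=(rng.uniform(-0.02, 0.0) if group == "HIC" else rng.uniform(-0.01, 0.01)),
            wiggle=0.015,
        )
        crude0 = float(shares0 @ np.exp(base.alpha))  # at beta=gamma=0
        total_rate = _TARGET_CRUDE_RATE[group] * rng.uniform(0.7, 1.3)
        for cause in config.causes:
            w = CAUSE_WEIGHTS.get(cause, 1.0 / len(config.causes))
            mu_c = np.log(total_rate * w / crude0)
            truth[(code, cause)] = replace(base, mu=mu_c)

    econ = pd.DataFrame(
        econ_rows, columns=["country", "year", "gnipc", "gdp", "cpi", "income_group"]
    )
    demog = pd.DataFrame(
        demog_rows, columns=["country", "year", "population", "median_age", "le_at_median_age"]
    )
    pop_age = pd.DataFrame(pop_rows, columns=["country", "year", "age", "population"])
    return SyntheticWorld(config=config, econ=econ, demog=demog, pop_age=pop_age, truth=truth)


def gen_apc_counts(truth: ApcTruth, exposure, seed) -> np.ndarray:
    """Poisson counts on the age x period grid: counts ~ Pois(exposure * exp(eta)).

    ``exposure`` is broadcast to (n_age, n_period) person-years and must be
    strictly positive.
    """
    eta = truth.linear_predictor()
    exposure = np.broadcast_to(np.asarray(exposure, dtype=float), eta.shape)
    if np.any(exposure <= 0):
        raise DataError("exposure must be strictly positive")
    rng = np.random.default_rng(seed)
    return rng.poisson(exposure * np.exp(eta))


def expected_dalys(world: SyntheticWorld, cause: str) -> pd.DataFrame:
    """Noise-free expected DALY counts: population x exp(linear predictor).

    Returns columns country, year, age, expected.
    """
    cfg = world.config
    labels = [b.label for b in cfg.age_bands]
    frames = []
    for code in world.countries:
        key = (code, cause)
        if key not in world.truth:
            raise DataError(f"no rate truth for cause {cause!r} in country {code}")
        eta = world.truth[key].linear_predictor()  # (n_age, n_years)
        pops = (
            world.pop_age[world.pop_age["country"] == code]
            .pivot(index="age", columns="year", values="population")
            .reindex(labels)
        )
        exp_counts = pops.to_numpy() * np.exp(eta)
        df = pd.DataFrame(exp_counts, index=labels, columns=pops.columns)
        df = df.reset_index(names="age").melt(id_vars="age", var_name="year", value_name="expected")
        df.insert(0, "country", code)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def gen_daly_table(
    world: SyntheticWorld,
    cause: str,
    ui_halfwidth_frac: float = 0.15,
    poisson: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """DALY table for one cause: Poisson draws around population x rate.

    Lower/upper are the symmetric band ``val * (1 -/+ ui_halfwidth_frac)``.
    With ``poisson=False`` the noise-free expectation is returned as ``val``
    (useful for planted-value checks).  The default seed derives from the
    world seed and the cause's position so different causes get independent
    draws while the whole table stays reproducible.
    """
    if not 0.0 <= ui_halfwidth_frac < 1.0:
        raise ConfigurationError("ui_halfwidth_frac must be in [0, 1)")
    if not any(k[1] == cause for k in world.truth):
        raise DataError(f"unknown cause {cause!r}: no rate truth in this world")
    if seed is None:
        idx = world.config.causes.index(cause) if cause in world.config.causes else 0
        seed_seq = np.random.SeedSequence([world.config.seed, 7919, idx])
    else:
        seed_seq = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed_seq)

    exp_df = expected_dalys(world, cause)
    mean = exp_df["expected"].to_numpy()
    val = rng.poisson(mean).astype(float) if poisson else mean.copy()
    out = exp_df.drop(columns="expected")
    out["cause"] = cause
    out["val"] = val
    out["lower"] = val * (1.0 - ui_halfwidth_frac)
    out["upper"] = val * (1.0 + ui_halfwidth_frac)
    return out[["country", "year", "age", "cause", "val", "lower", "upper"]]
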