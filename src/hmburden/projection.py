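"""Projection of DALY rates and monetized burden to 2050.

Two engines, never combined:

* **Scenario** — deterministic: rates held at their 2021 level (baseline),
  or multiplied by 1.01 (negative trend, +1%/yr) or 0.99 (positive trend,
  -1%/yr) per year past 2021.

* **BAPC** — a Bayesian age-period-cohort Poisson model.  Counts y_ij on an
  age x period grid with person-year exposures E_ij follow

      y_ij ~ Poisson(E_ij * exp(eta_ij)),
      eta_ij = mu + alpha_i + beta_j + gamma_k,   k = (A - 1 - i) + j,

  with second-order random-walk (RW2) smoothing priors on the age, period
  and cohort effects and inverse-gamma priors (shape 1, rate 5e-5) on the
  RW2 variances.  Identifiability: all three effect vectors are constrained
  to sum to zero and the cohort effect to have zero linear trend, assigning
  the shared drift to the period (and age) effects.  Inference is an
  empirical-Bayes Laplace approximation: penalized-likelihood Newton
  iterations for the latent effects alternate with EM updates of the RW2
  precisions; posterior summaries come from the Gaussian approximation at
  the mode.  Forecasts extrapolate period and future-cohort effects under
  the RW2 predictive distribution, whose mean continues the terminal linear
  trend and whose variance grows with the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .errors import (
    ConfigurationError,
    ConvergenceError,
    DataError,
    DomainError,
)
from .valuation import VslParams

SCENARIO_MULTIPLIERS = {"baseline": 1.00, "negative": 1.01, "positive": 0.99}


@dataclass(frozen=True)
class ScenarioSpec:
    """A deterministic rate scenario anchored at 2021."""

    name: str
    annual_multiplier: float = field(default=None)  # type: ignore[assignment]
    anchor_year: int = 2021

    def __post_init__(self):
        if self.name not in SCENARIO_MULTIPLIERS:
            raise ConfigurationError(
                f"unknown scenario {self.name!r}; expected one of {sorted(SCENARIO_MULTIPLIERS)}"
            )
        expected = SCENARIO_MULTIPLIERS[self.name]
        if self.annual_multiplier is None:
            object.__setattr__(self, "annual_multiplier", expected)
        elif abs(self.annual_multiplier - expected) > 1e-12:
            raise ConfigurationError(
                f"scenario {self.name!r} implies multiplier {expected}, got {self.annual_multiplier}"
            )


def scenario_rates(rates_anchor, spec: ScenarioSpec, year: int):
    """Rates at ``year``: anchor rates x multiplier^(year - anchor)."""
    if year < spec.anchor_year:
        raise DomainError(f"scenario projection requires year >= {spec.anchor_year}")
    out = np.asarray(rates_anchor, dtype=float) * spec.annual_multiplier ** (year - spec.anchor_year)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# BAPC


@dataclass(frozen=True)
class BapcPriorConfig:
    """Hyperparameters and iteration controls for the BAPC fit.

    ``ig_shape``/``ig_rate`` parameterize the inverse-gamma prior on each
    RW2 variance (equivalently a Gamma prior on the precision); the
    conventional diffuse default is shape 1, rate 5e-5.
    """

    ig_shape: float = 1.0
    ig_rate: float = 5e-5
    tau_init: float = 10.0
    max_outer: int = 200
    max_newton: int = 100
    tau_tol: float = 1e-3
    tau_bounds: tuple[float, float] = (1e-6, 1e12)


def _rw2_structure(n: int) -> np.ndarray:
    """R = D2' D2 for the second-difference operator on n points (rank n-2)."""
    if n < 3:
        return np.zeros((n, n))
    D = np.zeros((n - 2, n))
    for t in range(n - 2):
        D[t, t], D[t, t + 1], D[t, t + 2] = 1.0, -2.0, 1.0
    return D.T @ D


@dataclass
class ApcFit:
    """Posterior summaries of a BAPC fit plus what forecasting needs."""

    mu_mean: float
    mu_sd: float
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    gamma_mean: np.ndarray
    gamma_sd: np.ndarray
    tau: dict[str, float]
    fitted_rates: np.ndarray
    fitted_rate_sd: np.ndarray
    converged: bool
    n_outer: int
    grad_norm: float
    method: str = "empirical-Bayes Laplace (penalized Poisson IRLS + EM precisions)"
    # internals for the predictive distribution
    _x_mean: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _Z: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _cov_z: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_age(self) -> int:
        return self.alpha_mean.shape[0]

    @property
    def n_period(self) -> int:
        return self.beta_mean.shape[0]

    def summary(self) -> pd.DataFrame:
        """Tidy effect table: mean, sd and normal-approximation 95% bounds."""
        rows = [("mu", 0, self.mu_mean, self.mu_sd)]
        for name, m, s in (
            ("alpha", self.alpha_mean, self.alpha_sd),
            ("beta", self.beta_mean, self.beta_sd),
            ("gamma", self.gamma_mean, self.gamma_sd),
        ):
            rows += [(name, i, m[i], s[i]) for i in range(len(m))]
        df = pd.DataFrame(rows, columns=["effect", "index", "mean", "sd"])
        df["q2.5"] = df["mean"] - 1.959964 * df["sd"]
        df["q97.5"] = df["mean"] + 1.959964 * df["sd"]
        return df


def _design(A: int, J: int) -> tuple[np.ndarray, np.ndarray]:
    """Full design matrix (A*J x p) and the cell->cohort index grid."""
    K = A + J - 1
    p = 1 + A + J + K
    i = np.repeat(np.arange(A), J)
    j = np.tile(np.arange(J), A)
    k = (A - 1 - i) + j
    M = np.zeros((A * J, p))
    M[:, 0] = 1.0
    M[np.arange(A * J), 1 + i] = 1.0
    M[np.arange(A * J), 1 + A + j] += 1.0
    M[np.arange(A * J), 1 + A + J + k] += 1.0
    return M, k.reshape(A, J)


def fit_bapc(
    counts: np.ndarray,
    exposure: np.ndarray,
    prior_config: BapcPriorConfig | None = None,
) -> ApcFit:
    """Fit the BAPC model to an age x period grid of counts and exposures.

    Requires at least a 5-age x 8-period grid, integer-valued counts and
    strictly positive exposures.  Raises ConvergenceError (with iteration
    trace info) if the precision updates fail to stabilize.
    """
    cfg = prior_config or BapcPriorConfig()
    counts = np.asarray(counts, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if counts.ndim != 2:
        raise DataError("counts must be a 2-d age x period grid")
    if counts.shape != exposure.shape:
        raise DataError(f"counts {counts.shape} and exposure {exposure.shape} shapes differ")
    A, J = counts.shape
    if A < 5 or J < 8:
        raise DataError(f"grid must be at least 5 ages x 8 periods, got {A} x {J}")
    if np.any(exposure <= 0):
        raise DataError("exposures must be strictly positive")
    if np.any(counts < 0) or np.any(np.abs(counts - np.round(counts)) > 1e-9):
        raise DataError("counts must be non-negative integers")

    K = A + J - 1
    p = 1 + A + J + K
    M, _ = _design(A, J)
    y = counts.ravel()
    E = exposure.ravel()

    # constraints: sum-to-zero on alpha, beta, gamma; zero linear trend on gamma
    C = np.zeros((4, p))
    C[0, 1:1 + A] = 1.0
    C[1, 1 + A:1 + A + J] = 1.0
    C[2, 1 + A + J:] = 1.0
    kk = np.arange(K, dtype=float)
    C[3, 1 + A + J:] = kk - kk.mean()
    Z = null_space(C)  # p x (p-4), orthonormal
    MZ = M @ Z

    slices = {
        "alpha": slice(1, 1 + A),
        "beta": slice(1 + A, 1 + A + J),
        "gamma": slice(1 + A + J, p),
    }
    R = {"alpha": _rw2_structure(A), "beta": _rw2_structure(J), "gamma": _rw2_structure(K)}
    rank = {"alpha": A - 2, "beta": J - 2, "gamma": K - 2}
    tau = {e: cfg.tau_init for e in R}

    def penalty_matrix(tau):
        P = np.zeros((p, p))
        for e, sl in slices.items():
            P[sl, sl] = tau[e] * R[e]
        return Z.T @ P @ Z

    # initialize at the crude overall log-rate
    x0 = np.zeros(p)
    x0[0] = np.log(max(y.sum(), 0.5) / E.sum())
    z = Z.T @ x0

    def objective(z, Pz):
        eta = MZ @ z
        return float(np.sum(E * np.exp(eta) - y * eta) + 0.5 * z @ Pz @ z)

    H = None
    n_outer = 0
    grad_norm = np.inf
    tau_trace = []
    converged = False
    for n_outer in range(1, cfg.max_outer + 1):
        Pz = penalty_matrix(tau)
        # Newton with step halving to the penalized-likelihood mode
        for _ in range(cfg.max_newton):
            eta = MZ @ z
            w = E * np.exp(eta)
            grad = MZ.T @ (w - y) + Pz @ z
            H = MZ.T @ (w[:, None] * MZ) + Pz
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ConvergenceError(f"singular Hessian at outer iter {n_outer}") from exc
            f0 = objective(z, Pz)
            t = 1.0
            for _ in range(40):
                z_new = z - t * step
                f1 = objective(z_new, Pz)
                if np.isfinite(f1) and f1 <= f0 + 1e-12 * abs(f0):
                    break
                t /= 2.0
            z = z_new
            grad_norm = float(np.linalg.norm(grad))
            if grad_norm < 1e-8 * (1.0 + abs(f0)):
                break
        if not np.all(np.isfinite(z)):
            raise ConvergenceError(f"non-finite latent state at outer iter {n_outer}")

        cov_z = np.linalg.inv(H)
        x = Z @ z
        # EM update of the RW2 precisions under the Gamma(shape, rate) prior
        new_tau = {}
        for e, sl in slices.items():
            Ze = Z[sl, :]
            quad = float(x[sl] @ R[e] @ x[sl] + np.trace(R[e] @ (Ze @ cov_z @ Ze.T)))
            t_new = (cfg.ig_shape + rank[e] / 2.0) / (cfg.ig_rate + quad / 2.0)
            new_tau[e] = float(np.clip(t_new, *cfg.tau_bounds))
        tau_trace.append(dict(new_tau))
        rel = max(abs(new_tau[e] - tau[e]) / max(tau[e], 1e-12) for e in tau)
        tau = new_tau
        if rel < cfg.tau_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"RW2 precisions did not stabilize in {cfg.max_outer} outer iterations; "
            f"last taus {tau_trace[-3:]}"
        )

    cov_z = np.linalg.inv(H)
    x = Z @ z
    cov_x_diag = np.einsum("ij,jk,ik->i", Z, cov_z, Z)
    sd = np.sqrt(np.maximum(cov_x_diag, 0.0))
    eta_grid = (M @ x).reshape(A, J)
    eta_var = np.einsum("ij,jk,ik->i", MZ, cov_z, MZ).reshape(A, J)
    rate_grid = np.exp(eta_grid)
    return ApcFit(
        mu_mean=float(x[0]),
        mu_sd=float(sd[0]),
        alpha_mean=x[slices["alpha"]].copy(),
        alpha_sd=sd[slices["alpha"]].copy(),
        beta_mean=x[slices["beta"]].copy(),
        beta_sd=sd[slices["beta"]].copy(),
        gamma_mean=x[slices["gamma"]].copy(),
        gamma_sd=sd[slices["gamma"]].copy(),
        tau=tau,
        fitted_rates=rate_grid,
        fitted_rate_sd=rate_grid * np.sqrt(np.maximum(eta_var, 0.0)),
        converged=converged,
        n_outer=n_outer,
        grad_norm=grad_norm,
        _x_mean=x,
        _Z=Z,
        _cov_z=cov_z,
    )


@dataclass
class BapcForecast:
    """Forecast rate grids (n_age x horizon) with pointwise 95% credible bands.

    ``sd_log`` is the predictive standard deviation of the log rate; the
    bands are log-normal quantiles around the median ``exp(mean_log)``.
    """

    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mean_log: np.ndarray
    sd_log: np.ndarray


def forecast_bapc(fit: ApcFit, horizon: int, max_extrapolation: int | None = None) -> BapcForecast:
    """Project rates ``horizon`` periods past the fitted grid.

    Period effects (and cohort effects for cohorts unseen in the data)
    follow the RW2 predictive: mean continues the terminal linear trend,
    variance accumulates innovation variance 1/tau per squared step
    (sum m^2 over the integration weights) on top of the posterior
    covariance of the terminal effects.  Credible-interval width in log
    space is monotonically non-decreasing in the horizon.
    """
    if horizon < 1:
        raise DomainError("horizon must be >= 1")
    A, J = fit.n_age, fit.n_period
    K = A + J - 1
    limit = max_extrapolation if max_extrapolation is not None else J
    if horizon > limit:
        raise ConfigurationError(
            f"horizon {horizon} exceeds the configured extrapolation bound {limit}"
        )
    p = fit._x_mean.shape[0]
    i_beta = 1 + A
    i_gamma = 1 + A + J

    mean_log = np.zeros((A, horizon))
    sd_log = np.zeros((A, horizon))
    for h in range(1, horizon + 1):
        for i in range(A):
            l = np.zeros(p)
            l[0] = 1.0
            l[1 + i] = 1.0
            # RW2 mean extrapolation of the period effect
            l[i_beta + J - 1] += 1.0 + h
            l[i_beta + J - 2] += -float(h)
            var_inn = h * (h + 1) * (2 * h + 1) / 6.0 / fit.tau["beta"]
            kf = (A - 1 - i) + (J - 1 + h)
            m = kf - (K - 1)
            if m <= 0:
                l[i_gamma + kf] += 1.0
            else:
                l[i_gamma + K - 1] += 1.0 + m
                l[i_gamma + K - 2] += -float(m)
                var_inn += m * (m + 1) * (2 * m + 1) / 6.0 / fit.tau["gamma"]
            lz = fit._Z.T @ l
            var = float(lz @ fit._cov_z @ lz) + var_inn
            mean_log[i, h - 1] = float(l @ fit._x_mean)
            sd_log[i, h - 1] = np.sqrt(max(var, 0.0))
    z95 = 1.959964
    return BapcForecast(
        median=np.exp(mean_log),
        lower=np.exp(mean_log - z95 * sd_log),
        upper=np.exp(mean_log + z95 * sd_log),
        mean_log=mean_log,
        sd_log=sd_log,
    )


# ---------------------------------------------------------------------------
# burden projection


def project_burden(
    rates: pd.DataFrame,
    population: pd.DataFrame,
    vsly: pd.DataFrame,
    params: VslParams,
    years: tuple[int, ...] = (2030, 2040, 2050),
) -> pd.DataFrame:
    """Monetized burden for projection years, discounted to the base year.

    ``rates`` (country, year, age, rate[, cause]) holds age-specific DALY
    rates per person-year; ``population`` (country, year, age, population)
    the projected age pyramids; ``vsly`` (country, year, vsly) the projected
    valuation.  Burden_t = (sum_a pop_a,t * rate_a,t) * VSLY_t / (1+d)^(t-base).
    """
    keys = ["country", "year"] + (["cause"] if "cause" in rates.columns else [])
    for y in years:
        for name, df, col in (("rates", rates, "year"), ("population", population, "year"),
                              ("vsly", vsly, "year")):
            if y not in set(df[col].unique()):
                raise DataError(f"projection year {y} missing from {name}")
    rates = rates[rates["year"].isin(years)]
    merged = rates.merge(population, on=["country", "year", "age"], how="left")
    if merged["population"].isna().any():
        bad = merged.loc[merged["population"].isna(), ["country", "year", "age"]].head(10)
        raise DataError(f"missing population for rate cells:\n{bad}")
    merged["dalys"] = merged["population"] * merged["rate"]
    out = merged.groupby(keys, as_index=False)["dalys"].sum()
    out = out.merge(vsly[["country", "year", "vsly"]], on=["country", "year"], how="left")
    if out["vsly"].isna().any():
        bad = out.loc[out["vsly"].isna(), ["country", "year"]].drop_duplicates().head(10)
        raise DataError(f"missing VSLY for projected country-years:\n{bad}")
    disc = (1.0 + params.discount_rate) ** -(out["year"].to_numpy() - params.base_year)
    out["burden"] = out["dalys"] * out["vsly"] * disc
    return out[keys + ["dalys", "burden"]]
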