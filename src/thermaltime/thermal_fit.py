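"""Thermal-time normalization and log-normal distribution fits (logit/probit).

The population-based threshold model assumes each seed i requires a fixed
thermal time θ_i = (T − T_b)·t_i degree-days to germinate, with θ varying
log-normally across the seed population.  Censuses from all sub-optimal
temperatures are therefore pooled on a common thermal-time axis
(Covell normalization, θ = (T_m − T_b)·t) and the cumulative fraction is
regressed on ln θ through the logit (default) or probit link:

    logit(p)  = α·ln θ + β        ln θ_T(50) = −β/α,  σ_θT = (π/√3)/α
    probit(p) = (1/σ)·ln θ + c    ln θ_T(50) = −c·σ,  σ_θT = σ

"log" throughout is the natural logarithm (the printed °d values pair with
their logs only on base e, e.g. exp(2.41) = 11.13).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit as _logit
from scipy.stats import norm

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    OrientationError,
    SubBaseTemperatureError,
)

#: Scale factor linking the logistic slope to a normal standard deviation.
LOGIT_SIGMA_FACTOR = math.pi / math.sqrt(3.0)

#: Cumulative fractions at or above this value are excluded from the fits.
MAX_FRACTION = 0.95

HOURS_PER_DAY = 24.0


def thermal_time(t_m: float, t_b: float, t: float) -> float:
    """θ = (T_m − T_b)·t in degree-days (°d); degree-hours are 24× this."""
    if t_m <= t_b:
        raise SubBaseTemperatureError(
            f"T_m={t_m} <= T_b={t_b}: no thermal accumulation"
        )
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    return (t_m - t_b) * t


def theta50_from_rate(t_m: float, t_b: float, gr_50: float) -> float:
    """Covell normalization θ_T(50) = (T_m − T_b)/GR_50 in °d."""
    if t_m <= t_b:
        raise SubBaseTemperatureError(
            f"T_m={t_m} <= T_b={t_b}: no thermal accumulation"
        )
    if gr_50 <= 0:
        raise ValueError(f"GR_50 must be positive, got {gr_50}")
    return (t_m - t_b) / gr_50


def derive_sigma_logit(alpha: float) -> float:
    """σ_θT = (π/√3)·(1/α) — the normal SD matched to a logistic slope α."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return LOGIT_SIGMA_FACTOR / alpha


def _prepare_observations(obs: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(obs), dtype=float)
    if arr.ndim != 2 or len(arr) < 3:
        raise InsufficientDataError(
            f"distribution fit needs >=3 (theta, fraction) observations, got "
            f"{0 if arr.ndim != 2 else len(arr)}"
        )
    theta, frac = arr[:, 0], arr[:, 1]
    if np.any(theta <= 0):
        raise ValueError("thermal time must be positive")
    if np.any((frac <= 0) | (frac >= 1)):
        raise ValueError(
            "fractions must lie strictly in (0, 1); apply the inclusion rule upstream"
        )
    if np.allclose(frac, frac[0]):
        raise DegenerateFitError("all cumulative fractions are equal")
    return theta, frac


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    return float(slope), float(intercept), float(res.rsquared)


def fit_logit(obs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Unweighted OLS of logit(fraction) on ln θ; returns (alpha, beta).

    Solving logit = 0 gives ln θ_T(50) = −β/α.
    """
    theta, frac = _prepare_observations(obs)
    alpha, beta, _ = _linear_fit(np.log(theta), _logit(frac))
    if alpha <= 0:
        raise OrientationError(
            f"logit slope must be positive (fractions increase with theta), got {alpha:.4g}"
        )
    return alpha, beta


def fit_probit(obs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """OLS of probit(fraction) on ln θ; returns (slope = 1/σ_θT, intercept)."""
    theta, frac = _prepare_observations(obs)
    slope, intercept, _ = _linear_fit(np.log(theta), norm.ppf(frac))
    if slope <= 0:
        raise OrientationError(
            f"probit slope must be positive, got {slope:.4g}"
        )
    return slope, intercept


@dataclass(frozen=True)
class ThermalModel:
    """Fitted thermal-time distribution for one population × regime class × DT."""

    population: str
    regime_class: str
    darkness_days: int
    t_b: float          # °C
    se_t_b: float       # °C
    t_o: float          # °C
    alpha: float        # link-scale slope per ln(°d): logit α, or probit 1/σ
    beta: float         # link-scale intercept
    method: str = "logit"  # "logit" or "probit"
    n_obs: int = 0

    def __post_init__(self):
        if self.method not in ("logit", "probit"):
            raise ValueError(f"method must be 'logit' or 'probit', got {self.method!r}")
        if self.alpha <= 0:
            raise OrientationError(f"alpha must be positive, got {self.alpha}")

    @property
    def group(self) -> tuple[str, str, int]:
        return (self.population, self.regime_class, self.darkness_days)

    @property
    def code(self) -> str:
        return f"{self.population}{self.regime_class}DT{self.darkness_days}d"

    @property
    def ln_theta50(self) -> float:
        """ln θ_T(50) in ln(°d); the link midpoint −β/α on either scale."""
        return -self.beta / self.alpha

    @property
    def sigma_theta(self) -> float:
        """SD of ln θ across the seed population."""
        if self.method == "logit":
            return derive_sigma_logit(self.alpha)
        return 1.0 / self.alpha

    @property
    def theta50_degday(self) -> float:
        return math.exp(self.ln_theta50)

    @property
    def theta50_deghour(self) -> float:
        return HOURS_PER_DAY * self.theta50_degday

    def predict_fraction(self, theta) -> np.ndarray:
        """Cumulative germination fraction at thermal time θ (°d)."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= 0):
            raise ValueError("thermal time must be positive")
        z = self.alpha * np.log(theta) + self.beta
        return expit(z) if self.method == "logit" else norm.cdf(z)

    def expected_log_theta(self, g) -> np.ndarray:
        """Model quantile ln θ_T(g) for percentile g (in %)."""
        g = np.asarray(g, dtype=float)
        if np.any((g <= 0) | (g >= 100)):
            raise ValueError("percentiles must lie in (0, 100)")
        p = g / 100.0
        link = _logit(p) if self.method == "logit" else norm.ppf(p)
        return (link - self.beta) / self.alpha


def thermal_observations(
    treatments: Sequence[tuple[float, np.ndarray, np.ndarray]],
    t_b: float,
    max_fraction: float = MAX_FRACTION,
) -> list[tuple[float, float]]:
    """Pool (θ, fraction) observations across treatments on the thermal-time axis.

    ``treatments`` holds (t_mean, census_days, fractions) triples, typically
    the sub-optimal temperatures of one population × regime class × DT group.
    Fractions of exactly 0 (undefined on the link scales) or >= ``max_fraction``
    (the 95% inclusion rule) are dropped; treatments at or below T_b
    contribute nothing.
    """
    obs: list[tuple[float, float]] = []
    for t_m, days, fractions in treatments:
        if t_m <= t_b:
            continue
        for day, frac in zip(np.asarray(days, float), np.asarray(fractions, float)):
            if 0.0 < frac < max_fraction:
                obs.append((thermal_time(t_m, t_b, day), float(frac)))
    return obs


def fit_thermal_model(
    *,
    population: str,
    regime_class: str,
    darkness_days: int,
    t_b: float,
    se_t_b: float,
    t_o: float,
    observations: Sequence[tuple[float, float]],
    method: str = "logit",
) -> ThermalModel:
    """Fit the pooled thermal-time distribution and assemble a :class:`ThermalModel`."""
    if method == "logit":
        alpha, beta = fit_logit(observations)
    elif method == "probit":
        alpha, beta = fit_probit(observations)
    else:
        raise ValueError(f"method must be 'logit' or 'probit', got {method!r}")
    return ThermalModel(
        population=population,
        regime_class=regime_class,
        darkness_days=darkness_days,
        t_b=t_b,
        se_t_b=se_t_b,
        t_o=t_o,
        alpha=alpha,
        beta=beta,
        method=method,
        n_obs=len(observations),
    )
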