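"""Published thermal-model parameter estimates for Spanish cattail populations.

These are the reported parameter tables for *Typha domingensis* seed lots
from Badajoz (Ba), Cuenca (Cu), Madrid (Ma) and Seville (Se), fitted under
constant (C) and alternating (A) thermal regimes and darkness pretreatments
of 0–10 days (20-day total darkness yields no germination and no fit).
Values are stored exactly as printed — a few degree-day/degree-hour pairs
carry rounding inconsistencies in the source tables, so consistency checks
should use rows where exp(ln θ50) matches the printed θ50.

The tables anchor the synthetic-data presets and serve as fixed inputs for
the darkness-delay regressions, which are reconstructible from ln θ_T(50)
alone.
"""

from __future__ import annotations

import pandas as pd

# (population, regime_class, darkness_days, t_b, t_b_sd, t_o,
#  ln_theta50, sigma_theta, theta50_degday, theta50_deghour)
_THERMAL_ROWS = [
    ("Ba", "C", 0, 16.0, 0.3, 25.0, 2.72, 0.5, 15.33, 368.0),
    ("Ba", "C", 3, 16.0, 0.3, 25.0, 2.81, 0.5, 16.61, 399.0),
    ("Ba", "C", 5, 16.0, 0.3, 25.0, 2.87, 0.5, 17.64, 423.0),
    ("Ba", "C", 7, 16.0, 0.3, 25.0, 2.96, 0.5, 19.21, 461.0),
    ("Ba", "C", 10, 16.0, 0.3, 25.0, 3.06, 0.5, 21.27, 510.0),
    ("Ba", "A", 0, 16.0, 0.2, 22.5, 2.81, 0.3, 16.61, 399.0),
    ("Ba", "A", 3, 16.0, 0.2, 22.5, 2.94, 0.3, 18.02, 454.0),
    ("Ba", "A", 5, 16.0, 0.2, 22.5, 3.00, 0.3, 20.09, 482.0),
    ("Ba", "A", 7, 16.0, 0.2, 22.5, 3.06, 0.3, 21.33, 512.0),
    ("Ba", "A", 10, 16.0, 0.2, 22.5, 3.12, 0.3, 22.65, 544.0),
    ("Cu", "C", 0, 16.0, 0.2, 22.5, 2.41, 0.4, 11.13, 267.0),
    ("Cu", "C", 3, 16.0, 0.2, 22.5, 2.50, 0.4, 12.18, 292.0),
    ("Cu", "C", 5, 16.0, 0.2, 22.5, 2.63, 0.4, 13.87, 333.0),
    ("Cu", "C", 7, 16.0, 0.2, 22.5, 2.71, 0.4, 15.03, 361.0),
    ("Cu", "C", 10, 16.0, 0.2, 22.5, 2.84, 0.4, 17.11, 411.0),
    ("Cu", "A", 0, 16.0, 0.5, 22.5, 2.70, 0.4, 14.88, 357.0),
    ("Cu", "A", 3, 16.0, 0.5, 22.5, 2.73, 0.4, 15.45, 378.0),
    ("Cu", "A", 5, 16.0, 0.5, 22.5, 2.79, 0.4, 16.28, 391.0),
    ("Cu", "A", 7, 16.0, 0.5, 22.5, 2.87, 0.4, 17.58, 422.0),
    ("Cu", "A", 10, 16.0, 0.5, 22.5, 2.90, 0.4, 18.23, 438.0),
    ("Ma", "C", 0, 16.0, 0.5, 25.0, 2.57, 0.5, 13.06, 314.0),
    ("Ma", "C", 3, 16.0, 0.5, 25.0, 2.70, 0.5, 14.92, 358.0),
    ("Ma", "C", 5, 16.0, 0.5, 25.0, 2.80, 0.5, 16.44, 395.0),
    ("Ma", "C", 7, 16.0, 0.5, 25.0, 2.90, 0.5, 18.17, 436.0),
    ("Ma", "C", 10, 16.0, 0.5, 25.0, 3.01, 0.5, 20.29, 487.0),
    ("Ma", "A", 0, 16.0, 0.7, 25.0, 2.76, 0.4, 15.80, 379.0),
    ("Ma", "A", 3, 16.0, 0.7, 25.0, 2.80, 0.4, 16.44, 395.0),
    ("Ma", "A", 5, 16.0, 0.7, 25.0, 2.91, 0.4, 18.30, 419.0),
    ("Ma", "A", 7, 16.0, 0.7, 25.0, 3.00, 0.4, 20.09, 482.0),
    ("Ma", "A", 10, 16.0, 0.7, 25.0, 3.03, 0.4, 20.78, 499.0),
    ("Se", "C", 0, 16.0, 0.1, 22.5, 2.75, 0.4, 15.70, 377.0),
    ("Se", "C", 3, 16.0, 0.1, 22.5, 2.80, 0.4, 16.44, 395.0),
    ("Se", "C", 5, 16.0, 0.1, 22.5, 2.89, 0.4, 17.99, 432.0),
    ("Se", "C", 7, 16.0, 0.1, 22.5, 3.08, 0.4, 21.76, 522.0),
    ("Se", "C", 10, 16.0, 0.1, 22.5, 3.16, 0.4, 23.57, 566.0),
    ("Se", "A", 0, 16.0, 0.5, 22.5, 2.98, 0.4, 19.69, 473.0),
    ("Se", "A", 3, 16.0, 0.5, 22.5, 3.02, 0.4, 20.49, 498.0),
    ("Se", "A", 5, 16.0, 0.5, 22.5, 3.11, 0.4, 22.42, 538.0),
    ("Se", "A", 7, 16.0, 0.5, 22.5, 3.21, 0.4, 24.78, 595.0),
    ("Se", "A", 10, 16.0, 0.5, 22.5, 3.24, 0.4, 25.53, 613.0),
]

# (population, regime_class, a, b, r2) for ln θ_T(50) = a + b·DT
_DARKNESS_ROWS = [
    ("Ba", "C", 2.71, 0.034, 0.993),
    ("Ba", "A", 2.83, 0.031, 0.965),
    ("Cu", "C", 2.39, 0.044, 0.986),
    ("Cu", "A", 2.69, 0.022, 0.927),
    ("Ma", "C", 2.57, 0.045, 0.996),
    ("Ma", "A", 2.75, 0.030, 0.910),
    ("Se", "C", 2.71, 0.045, 0.908),
    ("Se", "A", 2.96, 0.029, 0.938),
]


def published_thermal_parameters() -> pd.DataFrame:
    """Reported thermal-model parameters per population × regime class × DT."""
    return pd.DataFrame(
        _THERMAL_ROWS,
        columns=[
            "population", "regime_class", "darkness_days", "t_b", "t_b_sd",
            "t_o", "ln_theta50", "sigma_theta", "theta50_degday",
            "theta50_deghour",
        ],
    )


def published_darkness_regressions() -> pd.DataFrame:
    """Reported darkness-delay regressions ln θ_T(50) = a + b·DT."""
    return pd.DataFrame(
        _DARKNESS_ROWS, columns=["population", "regime_class", "a", "b", "r2"]
    )
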