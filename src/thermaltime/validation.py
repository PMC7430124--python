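"""Held-out validation of thermal models against an independent population.

A fitted :class:`~thermaltime.thermal_fit.ThermalModel` predicts the thermal
time ln θ_T(g) needed for each germination percentile g.  The same quantity
is observed directly on the holdout population's censuses by applying the
model's T_b: ln θ_obs = ln((T_m − T_b)·t_g) for each sub-optimal T_m and
each percentile the holdout curve reaches.  Agreement is summarized by the
squared Pearson correlation (R²) and the root-mean-square error (RMSE) of
expected vs observed ln θ_T(g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, PercentileNotReached, UndefinedCurveError
from .io_data import TimeCourse, group_by_treatment
from .percentiles import cumulative_fraction, percentile_time
from .thermal_fit import ThermalModel

#: Central percentile grid used for expected/observed comparisons.
DEFAULT_G_GRID = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)


@dataclass(frozen=True)
class ValidationResult:
    model_group: tuple[str, str, int]   # (population, regime_class, darkness_days)
    holdout_population: str
    g: np.ndarray          # percentile of each paired point
    t_mean: np.ndarray     # holdout T_m of each paired point, °C
    expected: np.ndarray   # model ln θ_T(g)
    observed: np.ndarray   # holdout ln θ_T(g)
    r2: float
    rmse: float            # ln(°d)
    degenerate: bool = False


def observed_log_theta(
    holdout: Sequence[TimeCourse],
    t_b: float,
    g_grid: Sequence[float] = DEFAULT_G_GRID,
    t_o: float | None = None,
    basis: str = "final",
) -> list[tuple[float, float, float]]:
    """Observed (g, T_m, ln θ_T(g)) triples from holdout censuses.

    Treatments with T_m <= T_b (no thermal accumulation) or above ``t_o``
    (supra-optimal branch, when given) are skipped, as are percentiles the
    pooled curve never reaches.
    """
    triples: list[tuple[float, float, float]] = []
    for code, tcs in sorted(group_by_treatment(holdout).items()):
        t_m = tcs[0].treatment.t_mean
        if t_m <= t_b or (t_o is not None and t_m > t_o):
            continue
        try:
            days, fractions = cumulative_fraction(tcs, basis=basis)
        except UndefinedCurveError:
            continue  # zero germination: nothing observable
        for g in g_grid:
            try:
                t_g = percentile_time(days, fractions, g)
            except PercentileNotReached:
                continue
            triples.append((float(g), float(t_m), math.log((t_m - t_b) * t_g)))
    if not triples:
        raise InsufficientDataError(
            "no percentile reached on any sub-optimal holdout treatment"
        )
    return triples


def evaluate(
    expected: Sequence[float], observed: Sequence[float]
) -> tuple[float, float, bool]:
    """R² (squared Pearson correlation) and RMSE of paired vectors.

    Returns (r2, rmse, degenerate); zero variance in either vector flags the
    pair degenerate and reports R² = 0.
    """
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape or e.ndim != 1 or len(e) < 3:
        raise InsufficientDataError(
            "evaluate needs paired vectors of equal length >= 3"
        )
    rmse = float(np.sqrt(np.mean((e - o) ** 2)))
    if np.allclose(e, e[0]) or np.allclose(o, o[0]):
        return 0.0, rmse, True
    r = float(np.corrcoef(e, o)[0, 1])
    return r * r, rmse, False


def validate_model(
    model: ThermalModel,
    holdout: Sequence[TimeCourse],
    g_grid: Sequence[float] = DEFAULT_G_GRID,
    basis: str = "final",
) -> ValidationResult:
    """Score ``model`` against an independent population's censuses.

    Holdout treatments must match the model's regime class and darkness
    treatment; they are consumed as raw censuses only (the holdout gets no
    thermal model of its own).
    """
    matching = [
        tc for tc in holdout
        if tc.treatment.regime_class == model.regime_class
        and tc.treatment.darkness_days == model.darkness_days
    ]
    if not matching:
        raise InsufficientDataError(
            f"no holdout censuses match regime class {model.regime_class} "
            f"and DT{model.darkness_days}d"
        )
    triples = observed_log_theta(
        matching, t_b=model.t_b, g_grid=g_grid, t_o=model.t_o, basis=basis
    )
    g = np.array([t[0] for t in triples])
    t_m = np.array([t[1] for t in triples])
    observed = np.array([t[2] for t in triples])
    expected = model.expected_log_theta(g)
    r2, rmse, degenerate = evaluate(expected, observed)
    return ValidationResult(
        model_group=model.group,
        holdout_population=matching[0].treatment.population,
        g=g,
        t_mean=t_m,
        expected=expected,
        observed=observed,
        r2=r2,
        rmse=rmse,
        degenerate=degenerate,
    )
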