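"""Darkness-delay regressions: ln θ_T(50) = a + b·DT per population × regime class.

Initial days under a 24 h dark photoperiod delay germination; the delay is
phenomenologically linear in ln thermal time.  The regression consumes the
fitted ln θ_T(50) per darkness level (not seed-level data); total-darkness
treatments (DT = 20 d) yield no germination and contribute no point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import InsufficientDataError


@dataclass(frozen=True)
class DarknessRegression:
    population: str
    regime_class: str
    a: float    # intercept, ln(°d) at DT = 0
    b: float    # slope, ln(°d) per darkness day
    r2: float
    n: int      # darkness levels used
    degenerate: bool = False  # flat response: b = 0, r2 reported as 0


def fit_darkness_regression(
    points: Sequence[tuple[float, float]],
    population: str = "",
    regime_class: str = "",
) -> DarknessRegression:
    """OLS of ln θ_T(50) on darkness days over >=3 distinct DT levels."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or len(np.unique(pts[:, 0])) < 3:
        raise InsufficientDataError(
            "darkness regression needs >=3 distinct darkness levels"
        )
    dt, y = pts[:, 0], pts[:, 1]
    if np.allclose(y, y[0]):
        return DarknessRegression(
            population=population, regime_class=regime_class,
            a=float(y[0]), b=0.0, r2=0.0, n=len(pts), degenerate=True,
        )
    res = sm.OLS(y, sm.add_constant(dt)).fit()
    a, b = res.params
    return DarknessRegression(
        population=population, regime_class=regime_class,
        a=float(a), b=float(b), r2=float(res.rsquared), n=len(pts),
    )
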