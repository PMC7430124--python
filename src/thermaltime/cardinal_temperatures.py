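"""Cardinal-temperature estimation: base temperature T_b and optimum T_o.

Below the optimum, germination rate rises linearly with temperature,
GR_50 = (T_m − T_b)/θ_T(50); the x-intercept of the fitted GR_50-vs-T_m
line estimates T_b and its slope approximates 1/θ_T(50).  T_o is read off
the tested temperature grid as the argmax of the GR_g profiles for
g ∈ {30, 50, 70} (ties broken toward the lower temperature; no peak is
curve-fitted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateFitError, InsufficientDataError, OrientationError


@dataclass(frozen=True)
class BaseTempFit:
    """Sub-optimal linear fit GR_50 = slope·T_m + intercept with T_b = −intercept/slope."""

    slope: float      # day^-1 °C^-1, ≈ 1/θ_T(50)
    intercept: float  # day^-1
    t_b: float        # °C
    se_t_b: float     # °C, delta-method SE
    n_points: int
    r2: float

    def predict(self, t_m):
        return self.slope * np.asarray(t_m, dtype=float) + self.intercept


@dataclass(frozen=True)
class OptimumTemp:
    t_o: float                              # °C, from the GR_50 profile
    t_o_by_percentile: dict[float, float]   # g -> °C
    delta_t_o: float                        # °C, spread among percentiles


def fit_base_temperature(points: Sequence[tuple[float, float]]) -> BaseTempFit:
    """OLS of GR_50 on T_m over sub-optimal points; T_b is the x-intercept.

    The standard error of T_b = −intercept/slope follows by the delta method
    from the OLS coefficient covariance.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise InsufficientDataError(
            f"base-temperature regression needs >=3 (T_m, GR_50) points, got {len(pts)}"
        )
    t_m, gr = pts[:, 0], pts[:, 1]
    if np.allclose(t_m, t_m[0]):
        raise DegenerateFitError("all points share the same T_m")
    res = sm.OLS(gr, sm.add_constant(t_m)).fit()
    intercept, slope = res.params
    if slope <= 0:
        raise OrientationError(
            f"GR_50-vs-T_m slope must be positive below T_o, got {slope:.4g}"
        )
    t_b = -intercept / slope
    grad = np.array([-1.0 / slope, intercept / slope**2])
    cov = np.asarray(res.cov_params())
    se_t_b = float(np.sqrt(grad @ cov @ grad))
    return BaseTempFit(
        slope=float(slope),
        intercept=float(intercept),
        t_b=float(t_b),
        se_t_b=se_t_b,
        n_points=len(pts),
        r2=float(res.rsquared),
    )


def estimate_optimum_temperature(
    profiles: Mapping[float, Sequence[tuple[float, float]]]
) -> OptimumTemp:
    """T_o as the tested T_m with maximal GR_g, per percentile profile.

    ``profiles`` maps percentile g to (T_m, GR_g) points.  Ties go to the
    lower T_m.  ``t_o`` is the g=50 value; ``delta_t_o`` is the spread of
    the per-percentile optima.
    """
    if 50.0 not in {float(g) for g in profiles}:
        raise InsufficientDataError("profiles must include the g=50 percentile")
    t_o_by_g: dict[float, float] = {}
    for g, pts in profiles.items():
        pts = np.asarray(list(pts), dtype=float)
        if len(pts) == 0:
            raise InsufficientDataError(f"empty GR profile for g={g}")
        t_m, gr = pts[:, 0], pts[:, 1]
        best = gr.max()
        t_o_by_g[float(g)] = float(t_m[gr == best].min())
    optima = np.array(list(t_o_by_g.values()))
    return OptimumTemp(
        t_o=t_o_by_g[50.0],
        t_o_by_percentile=t_o_by_g,
        delta_t_o=float(optima.max() - optima.min()),
    )


def suboptimal_points(
    points: Sequence[tuple],
    t_o: float,
    max_final_fraction: float | None = None,
) -> list[tuple]:
    """Restrict observations to the sub-optimal branch T_m <= T_o.

    Each point is (T_m, GR) or (T_m, GR, final_fraction).  When
    ``max_final_fraction`` is given, treatments whose final germination
    fraction reaches it are additionally dropped — a stricter, treatment-level
    reading of the rule that caps cumulative percentages entering the logit
    regression at 95%.  The default applies only the temperature filter; the
    fraction cap is enforced where the logit observations are assembled.
    """
    kept = []
    for pt in points:
        t_m = pt[0]
        if t_m > t_o:
            continue
        if (
            max_final_fraction is not None
            and len(pt) >= 3
            and pt[2] is not None
            and pt[2] >= max_final_fraction
        ):
            continue
        kept.append(pt)
    return kept
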