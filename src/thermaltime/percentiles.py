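"""Percentile germination times t_g and germination rates GR_g = 1/t_g.

Cumulative censuses are pooled across replicates (summed counts over summed
seeds sown) and the time at which the curve crosses a percentile g is found
by linear interpolation between daily censuses.  By default g is a
percentage of SOWN seeds — the population percentile the threshold model is
written in — with a ``basis='final'`` option for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PercentileNotReached, UndefinedCurveError
from .io_data import TimeCourse, TreatmentSpec

DEFAULT_PERCENTILES = (30.0, 50.0, 70.0)


@dataclass(frozen=True)
class PercentileEstimate:
    treatment: TreatmentSpec
    g: float        # percentile, % of sown seeds
    t_g: float      # days
    gr_g: float     # day^-1, = 1/t_g

    def __post_init__(self):
        if self.t_g <= 0:
            raise ValueError(f"t_g must be positive, got {self.t_g}")


def cumulative_fraction(
    tcs: Sequence[TimeCourse], basis: str = "sown"
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled cumulative germination fraction per census day.

    Replicate counts are summed per day and divided by pooled seeds sown
    (``basis='sown'``) or by the pooled final germinated count
    (``basis='final'``).
    """
    if not tcs:
        raise UndefinedCurveError("no time courses supplied")
    if basis not in ("sown", "final"):
        raise ValueError(f"basis must be 'sown' or 'final', got {basis!r}")
    days = tcs[0].census_days
    for tc in tcs[1:]:
        if not np.array_equal(tc.census_days, days):
            raise UndefinedCurveError(
                f"replicates of {tc.treatment.code} have mismatched census days"
            )
    pooled = np.sum([tc.cumulative_germinated for tc in tcs], axis=0).astype(float)
    if basis == "sown":
        denom = float(sum(tc.seeds_sown for tc in tcs))
    else:
        denom = float(pooled[-1])
        if denom == 0:
            raise UndefinedCurveError(
                f"{tcs[0].treatment.code}: basis='final' undefined with zero germination"
            )
    return days.astype(float), pooled / denom


def percentile_time(
    days: np.ndarray, fractions: np.ndarray, g: float
) -> float:
    """Time t_g (days) at which the pooled curve reaches percentile g.

    Linear interpolation between the last census with fraction < g/100 and
    the first with fraction >= g/100; if the first census already exceeds
    g/100 the segment starts at (0, 0).  Raises
    :class:`~thermaltime.errors.PercentileNotReached` when the final
    fraction stays below g/100 (right-censored treatment).
    """
    if not 0 < g < 100:
        raise ValueError(f"percentile g must lie in (0, 100), got {g}")
    days = np.asarray(days, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    target = g / 100.0
    above = np.nonzero(fractions >= target)[0]
    if len(above) == 0:
        raise PercentileNotReached(
            f"final fraction {fractions[-1]:.3f} < {target:.3f} (g={g}%)"
        )
    i = int(above[0])
    d1, f1 = days[i], fractions[i]
    if i == 0:
        d0, f0 = 0.0, 0.0
    else:
        d0, f0 = days[i - 1], fractions[i - 1]
    if f1 == f0:  # curve jumps exactly onto the target at d1
        return float(d1)
    return float(d0 + (target - f0) / (f1 - f0) * (d1 - d0))


def germination_rate(t_g: float) -> float:
    """GR_g = 1/t_g in day^-1."""
    if t_g <= 0:
        raise ValueError(f"t_g must be positive, got {t_g}")
    return 1.0 / t_g


def estimate_percentiles(
    tcs: Sequence[TimeCourse],
    g_values: Iterable[float] = DEFAULT_PERCENTILES,
    basis: str = "sown",
) -> list[PercentileEstimate]:
    """Percentile estimates for one treatment; unreached percentiles are skipped."""
    days, fractions = cumulative_fraction(tcs, basis=basis)
    out = []
    for g in g_values:
        try:
            t_g = percentile_time(days, fractions, g)
        except PercentileNotReached:
            continue
        out.append(
            PercentileEstimate(
                treatment=tcs[0].treatment, g=float(g),
                t_g=t_g, gr_g=germination_rate(t_g),
            )
        )
    return out


def percentile_table(
    grouped: dict[str, list[TimeCourse]],
    g_values: Iterable[float] = DEFAULT_PERCENTILES,
    basis: str = "sown",
) -> pd.DataFrame:
    """Long-format table of percentile estimates for many treatments.

    Columns: code, population, regime_class, t_mean, delta_t, darkness_days,
    final_fraction, g, t_g, gr_g.  Treatments whose curve never reaches a
    percentile contribute no row for it.
    """
    rows = []
    for code, tcs in sorted(grouped.items()):
        spec = tcs[0].treatment
        _, fractions = cumulative_fraction(tcs, basis="sown")
        final_fraction = float(fractions[-1])
        for est in estimate_percentiles(tcs, g_values, basis=basis):
            rows.append(
                {
                    "code": code,
                    "population": spec.population,
                    "regime_class": spec.regime_class,
                    "t_mean": spec.t_mean,
                    "delta_t": spec.delta_t,
                    "darkness_days": spec.darkness_days,
                    "final_fraction": final_fraction,
                    "g": est.g,
                    "t_g": est.t_g,
                    "gr_g": est.gr_g,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "code", "population", "regime_class", "t_mean", "delta_t",
            "darkness_days", "final_fraction", "g", "t_g", "gr_g",
        ],
    )
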