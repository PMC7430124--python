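import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermaltime.errors import PercentileNotReached, UndefinedCurveError
from thermaltime.percentiles import (
    cumulative_fraction,
    estimate_percentiles,
    germination_rate,
    percentile_time,
)
from tests.conftest import make_timecourse


def dense_first_crossing(days, frac, target):
    """Brute-force oracle: first crossing of the piecewise-linear curve.

    Coarse dense-grid scan to bracket the crossing, then bisection on the
    interpolant; independent of the interpolation arithmetic under test.
    """
    xs = np.concatenate([[0.0], np.asarray(days, float)])
    ys = np.concatenate([[0.0], np.asarray(frac, float)])
    grid = np.linspace(0.0, xs[-1], 200_001)
    curve = np.interp(grid, xs, ys)
    i = int(np.nonzero(curve >= target)[0][0])
    if i == 0:
        return grid[0]
    lo, hi = grid[i - 1], grid[i]
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.interp(mid, xs, ys) >= target:
            hi = mid
        else:
            lo = mid
    return hi


class TestCumulativeFraction:
    def test_pooled_sown_basis(self, cu_constant_dt0):
        days, frac = cumulative_fraction(cu_constant_dt0, basis="sown")
        # pooled day-2 count is 12+14+11 = 37 of 99 sown
        assert frac[1] == pytest.approx(37 / 99)
        assert frac[-1] == pytest.approx(1.0)
        assert np.all(np.diff(frac) >= 0)

    def test_final_basis_rescales_to_one(self):
        tcs = [make_timecourse(counts=[5, 10, 20], replicate=r) for r in (1, 2)]
        _, frac = cumulative_fraction(tcs, basis="final")
        assert frac[-1] == pytest.approx(1.0)
        assert frac[0] == pytest.approx(5 / 20)

    def test_final_basis_zero_germination_undefined(self):
        tcs = [make_timecourse(replicate=1)]
        with pytest.raises(UndefinedCurveError):
            cumulative_fraction(tcs, basis="final")


class TestPercentileTime:
    def test_midpoint_interpolation(self):
        # fractions 0.40 at day 4 and 0.60 at day 5 -> t50 = 4.5
        days = np.arange(1, 21)
        frac = np.concatenate([[0, 0, 0, 0.40], np.full(16, 0.60)])
        assert percentile_time(days, frac, 50) == pytest.approx(4.5)

    def test_exact_census_value_needs_no_interpolation(self):
        days = np.arange(1, 21)
        frac = np.concatenate([[0.1, 0.3, 0.5], np.full(17, 0.8)])
        assert percentile_time(days, frac, 50) == pytest.approx(3.0)

    def test_first_day_crossing_interpolates_from_origin(self):
        days = np.arange(1, 21)
        frac = np.full(20, 0.8)  # jumps to 0.8 on day 1
        assert percentile_time(days, frac, 40) == pytest.approx(0.5)

    def test_not_reached_signals(self):
        days = np.arange(1, 21)
        frac = np.full(20, 0.45)
        with pytest.raises(PercentileNotReached):
            percentile_time(days, frac, 50)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=20, max_size=20),
           st.floats(1.0, 99.0))
    def test_matches_dense_grid_oracle(self, increments, g):
        """Interpolated crossing equals a brute-force search on a dense grid."""
        raw = np.cumsum(np.asarray(increments))
        frac = raw / max(raw.max(), 1e-9)  # monotone curve reaching 1.0
        days = np.arange(1, 21, dtype=float)
        target = g / 100.0
        if frac[-1] < target:
            with pytest.raises(PercentileNotReached):
                percentile_time(days, frac, g)
            return
        t = percentile_time(days, frac, g)
        assert abs(t - dense_first_crossing(days, frac, target)) <= 1e-9

    def test_percentile_order_is_monotone(self, cu_constant_dt0):
        ests = {e.g: e.t_g for e in estimate_percentiles(cu_constant_dt0, (30, 50, 70))}
        assert ests[30] <= ests[50] <= ests[70]

    def test_scaling_counts_and_sown_leaves_t_g_unchanged(self, cu_constant_dt0):
        scaled = [
            make_timecourse(
                counts=tc.cumulative_germinated * 3,
                seeds_sown=tc.seeds_sown * 3,
                replicate=tc.replicate_id,
            )
            for tc in cu_constant_dt0
        ]
        for g in (30, 50, 70):
            d1, f1 = cumulative_fraction(cu_constant_dt0)
            d2, f2 = cumulative_fraction(scaled)
            assert percentile_time(d1, f1, g) == pytest.approx(
                percentile_time(d2, f2, g), abs=1e-12
            )


def test_germination_rate_is_reciprocal_time():
    assert germination_rate(1.0) == 1.0
    assert germination_rate(2.94) == pytest.approx(0.34, abs=0.005)
    assert germination_rate(4.35) == pytest.approx(0.23, abs=0.005)
    with pytest.raises(ValueError):
        germination_rate(0.0)
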