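import numpy as np
import pytest

from thermaltime.io_data import TimeCourse, parse_treatment_code


def make_timecourse(code="Cu22.5C0DT0d", replicate=1, seeds_sown=33, counts=None):
    """Build a 20-day TimeCourse from a (possibly short) cumulative count list."""
    days = np.arange(1, 21)
    if counts is None:
        counts = np.zeros(20, dtype=int)
    counts = np.asarray(counts, dtype=int)
    if len(counts) < 20:  # pad with the final value (plateau)
        counts = np.concatenate([counts, np.full(20 - len(counts), counts[-1])])
    return TimeCourse(
        treatment=parse_treatment_code(code),
        replicate_id=replicate,
        seeds_sown=seeds_sown,
        census_days=days,
        cumulative_germinated=counts,
    )


@pytest.fixture
def cu_constant_dt0():
    """Three replicates of a fast-germinating treatment (saturating by day 6)."""
    return [
        make_timecourse(counts=[2, 12, 24, 30, 32, 33], replicate=1),
        make_timecourse(counts=[1, 14, 22, 29, 33, 33], replicate=2),
        make_timecourse(counts=[3, 11, 25, 31, 32, 33], replicate=3),
    ]
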