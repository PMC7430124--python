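"""Census-table I/O, treatment-code parsing, and final-germination summaries.

Germination experiments of the kind modelled here are encoded as compact
treatment codes such as ``Ba25C0DT5d``:

* ``Ba`` — population label (seed provenance),
* ``25`` — mean incubation temperature T_m in °C (may carry a decimal,
  e.g. ``17.5``),
* ``C``/``A`` — constant or alternating (diurnal) thermal regime,
* ``0`` — temperature amplitude ΔT = t_high − t_low in °C (0 for constant),
* ``DT5d`` — five initial days under a 24 h dark photoperiod.

Censuses are cumulative daily counts of germinated seeds per replicate dish
over a 20-day experiment.  The canonical storage is cumulative counts;
incremental counts are accepted on read and cumulated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CensusValidationError, TreatmentCodeError

#: Length of the germination test in days (daily censuses, right-censored after).
EXPERIMENT_DAYS = 20

#: Default number of seeds per replicate dish.
DEFAULT_SEEDS_SOWN = 33

_CODE_RE = re.compile(
    r"^(?P<pop>[A-Za-z][a-z]*)"      # population label, e.g. Ba, Cu, To
    r"(?P<tm>\d+(?:\.\d+)?)"         # mean temperature T_m
    r"(?P<cls>[CA])"                 # regime class: first alphabetic after T_m
    r"(?P<delta>\d+(?:\.\d+)?)"      # amplitude ΔT
    r"DT(?P<dd>\d+)d$"               # darkness days
)


@dataclass(frozen=True)
class TreatmentSpec:
    """One experimental treatment: population × thermal regime × darkness days."""

    population: str
    regime_class: str  # "C" (constant) or "A" (alternating)
    t_low: float       # °C, dark-period temperature
    t_high: float      # °C, light-period temperature
    darkness_days: int  # initial days under 24 h darkness

    def __post_init__(self) -> None:
        if self.regime_class not in ("C", "A"):
            raise TreatmentCodeError(
                f"regime_class must be 'C' or 'A', got {self.regime_class!r}"
            )
        if self.regime_class == "C" and self.t_low != self.t_high:
            raise TreatmentCodeError(
                f"constant regime requires t_low == t_high, got "
                f"{self.t_low}/{self.t_high}"
            )
        if self.regime_class == "A" and self.t_low >= self.t_high:
            raise TreatmentCodeError(
                f"alternating regime requires t_low < t_high, got "
                f"{self.t_low}/{self.t_high}"
            )
        if not 0 <= self.darkness_days <= EXPERIMENT_DAYS:
            raise TreatmentCodeError(
                f"darkness_days must lie in [0, {EXPERIMENT_DAYS}], got "
                f"{self.darkness_days}"
            )

    @property
    def t_mean(self) -> float:
        """Mean temperature T_m in °C — the temperature the models use."""
        return (self.t_low + self.t_high) / 2.0

    @property
    def delta_t(self) -> float:
        """Diurnal amplitude ΔT = t_high − t_low in °C (0 for constant regimes)."""
        return self.t_high - self.t_low

    @property
    def code(self) -> str:
        return format_treatment_code(self)

    @property
    def group(self) -> tuple[str, str, int]:
        """(population, regime_class, darkness_days) — the model-fitting unit."""
        return (self.population, self.regime_class, self.darkness_days)


def _fmt_temperature(value: float) -> str:
    """Render a temperature the way the codes do: '25' not '25.0', '17.5' kept."""
    if float(value) == int(value):
        return str(int(value))
    return f"{value:g}"


def format_treatment_code(spec: TreatmentSpec) -> str:
    return (
        f"{spec.population}{_fmt_temperature(spec.t_mean)}{spec.regime_class}"
        f"{_fmt_temperature(spec.delta_t)}DT{spec.darkness_days}d"
    )


def parse_treatment_code(code: str) -> TreatmentSpec:
    """Parse a treatment code like ``Ba25A10DT3d`` into a :class:`TreatmentSpec`.

    The regime letter is the first alphabetic character after the population
    label, which disambiguates decimal mean temperatures such as ``17.5``.
    ``t_low``/``t_high`` are reconstructed from T_m and ΔT
    (t_low = T_m − ΔT/2, t_high = T_m + ΔT/2).
    """
    m = _CODE_RE.match(code)
    if m is None:
        raise TreatmentCodeError(_diagnose_code(code))
    t_mean = float(m.group("tm"))
    delta_t = float(m.group("delta"))
    cls = m.group("cls")
    if cls == "C" and delta_t != 0:
        raise TreatmentCodeError(
            f"{code!r}: constant regime ('C') with non-zero amplitude ΔT={delta_t}"
        )
    if cls == "A" and delta_t == 0:
        raise TreatmentCodeError(
            f"{code!r}: alternating regime ('A') with zero amplitude"
        )
    return TreatmentSpec(
        population=m.group("pop"),
        regime_class=cls,
        t_low=t_mean - delta_t / 2.0,
        t_high=t_mean + delta_t / 2.0,
        darkness_days=int(m.group("dd")),
    )


def _diagnose_code(code: str) -> str:
    """Name the offending segment of a malformed treatment code."""
    rest = code
    m = re.match(r"[A-Za-z][a-z]*", rest)
    if m is None:
        return f"{code!r}: missing population label at start"
    rest = rest[m.end():]
    m = re.match(r"\d+(?:\.\d+)?", rest)
    if m is None:
        return f"{code!r}: missing mean temperature after population label"
    rest = rest[m.end():]
    if not rest or rest[0] not in "CA":
        return f"{code!r}: missing regime letter 'C' or 'A' after mean temperature"
    rest = rest[1:]
    m = re.match(r"\d+(?:\.\d+)?", rest)
    if m is None:
        return f"{code!r}: missing amplitude ΔT after regime letter"
    rest = rest[m.end():]
    m = re.match(r"DT(\d+)d$", rest)
    if m is None:
        return f"{code!r}: missing darkness segment 'DT<n>d' at end"
    return f"{code!r}: malformed treatment code"


@dataclass
class TimeCourse:
    """One treatment × replicate cumulative germination census."""

    treatment: TreatmentSpec
    replicate_id: int
    seeds_sown: int
    census_days: np.ndarray   # ordered integer days 1..EXPERIMENT_DAYS
    cumulative_germinated: np.ndarray  # aligned counts, non-decreasing

    def __post_init__(self) -> None:
        self.census_days = np.asarray(self.census_days, dtype=int)
        self.cumulative_germinated = np.asarray(self.cumulative_germinated, dtype=int)
        self.validate()

    def validate(self) -> None:
        days = self.census_days
        counts = self.cumulative_germinated
        label = f"{self.treatment.code} rep {self.replicate_id}"
        if days.shape != counts.shape:
            raise CensusValidationError(f"{label}: days/counts length mismatch")
        if len(days) == 0:
            raise CensusValidationError(f"{label}: empty census")
        if np.any(np.diff(days) <= 0):
            raise CensusValidationError(f"{label}: census days not strictly increasing")
        if days[0] < 1 or days[-1] != EXPERIMENT_DAYS:
            raise CensusValidationError(
                f"{label}: censuses must span days 1..{EXPERIMENT_DAYS} "
                f"(last census day must be {EXPERIMENT_DAYS}, got {days[-1]})"
            )
        if np.any(np.diff(counts) < 0):
            bad = int(days[1:][np.diff(counts) < 0][0])
            raise CensusValidationError(
                f"{label}: cumulative count decreases at day {bad}"
            )
        if np.any(counts < 0) or np.any(counts > self.seeds_sown):
            raise CensusValidationError(
                f"{label}: counts must lie in [0, seeds_sown={self.seeds_sown}]"
            )

    @property
    def final_count(self) -> int:
        return int(self.cumulative_germinated[-1])

    @property
    def final_fraction(self) -> float:
        return self.final_count / self.seeds_sown


@dataclass(frozen=True)
class FinalGermination:
    """Day-20 germination summary for one treatment across replicates."""

    treatment: TreatmentSpec
    mean_pct: float   # % of sown seeds germinated at the final census
    sd_pct: float     # sample SD across replicates (%)
    transformed: float  # arcsine-square-root of the mean proportion, radians
    n_replicates: int = 3


def arcsine_sqrt(proportion: float) -> float:
    """Variance-stabilizing arcsine-√ transform used for percentage ANOVA."""
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion}")
    return math.asin(math.sqrt(proportion))


def final_germination(tcs: Sequence[TimeCourse]) -> FinalGermination:
    """Mean ± SD final germination percentage for one treatment.

    SD is the sample standard deviation (ddof=1) across replicates; with a
    single replicate it is reported as 0.
    """
    if not tcs:
        raise InsufficientReplicates("final_germination needs at least one replicate")
    codes = {tc.treatment.code for tc in tcs}
    if len(codes) > 1:
        raise CensusValidationError(
            f"final_germination mixes treatments: {sorted(codes)}"
        )
    pcts = np.array([100.0 * tc.final_fraction for tc in tcs])
    mean = float(pcts.mean())
    sd = float(pcts.std(ddof=1)) if len(pcts) > 1 else 0.0
    return FinalGermination(
        treatment=tcs[0].treatment,
        mean_pct=mean,
        sd_pct=sd,
        transformed=arcsine_sqrt(mean / 100.0),
        n_replicates=len(tcs),
    )


class InsufficientReplicates(CensusValidationError):
    pass


_CENSUS_COLUMNS = ["treatment", "replicate", "day", "cumulative_germinated", "seeds_sown"]


def read_census_table(path, counts: str = "cumulative") -> list[TimeCourse]:
    """Read a long-format CSV census table into validated :class:`TimeCourse` records.

    Expected columns: ``treatment`` (code string), ``replicate`` (int),
    ``day`` (int), ``cumulative_germinated`` (count), ``seeds_sown`` (count).
    With ``counts='incremental'`` the count column holds newly germinated
    seeds per day and is cumulated on read.
    """
    if counts not in ("cumulative", "incremental"):
        raise ValueError(f"counts must be 'cumulative' or 'incremental', got {counts!r}")
    df = pd.read_csv(path)
    missing = [c for c in _CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise CensusValidationError(f"census table missing columns: {missing}")
    dup = df.duplicated(subset=["treatment", "replicate", "day"])
    if dup.any():
        row = df[dup].iloc[0]
        raise CensusValidationError(
            f"duplicate census row: treatment={row['treatment']} "
            f"replicate={row['replicate']} day={row['day']}"
        )
    out: list[TimeCourse] = []
    for (code, rep), sub in df.groupby(["treatment", "replicate"], sort=True):
        spec = parse_treatment_code(str(code))
        sub = sub.sort_values("day")
        sown = sub["seeds_sown"].unique()
        if len(sown) != 1:
            raise CensusValidationError(
                f"{code} rep {rep}: inconsistent seeds_sown values {sown.tolist()}"
            )
        values = sub["cumulative_germinated"].to_numpy()
        if counts == "incremental":
            values = np.cumsum(values)
        out.append(
            TimeCourse(
                treatment=spec,
                replicate_id=int(rep),
                seeds_sown=int(sown[0]),
                census_days=sub["day"].to_numpy(),
                cumulative_germinated=values,
            )
        )
    return out


def write_census_table(tcs: Iterable[TimeCourse], path) -> None:
    """Write time courses to the canonical long-format CSV dialect."""
    rows = []
    for tc in tcs:
        for day, count in zip(tc.census_days, tc.cumulative_germinated):
            rows.append(
                {
                    "treatment": tc.treatment.code,
                    "replicate": tc.replicate_id,
                    "day": int(day),
                    "cumulative_germinated": int(count),
                    "seeds_sown": tc.seeds_sown,
                }
            )
    pd.DataFrame(rows, columns=_CENSUS_COLUMNS).to_csv(path, index=False)


def group_by_treatment(tcs: Iterable[TimeCourse]) -> dict[str, list[TimeCourse]]:
    """Group time courses by treatment code (replicates together)."""
    groups: dict[str, list[TimeCourse]] = {}
    for tc in tcs:
        groups.setdefault(tc.treatment.code, []).append(tc)
    return groups
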