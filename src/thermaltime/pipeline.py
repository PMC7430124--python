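"""End-to-end orchestration: censuses → percentiles → cardinal temperatures →
thermal-time fits → darkness regressions → holdout validation.

One :class:`ThermalModel` is fitted per population × regime class × darkness
treatment; the optimum temperature is estimated once per population × regime
class from the DT0d profiles and reused across darkness levels (the optimum
does not shift with darkness pretreatment); base temperatures are fitted per
group and summarized as mean ± SD per population × regime class.  Every
exclusion (percentile not reached, supra-optimal temperatures, sub-base
temperatures, zero-germination groups) is logged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cardinal_temperatures import (
    BaseTempFit,
    OptimumTemp,
    estimate_optimum_temperature,
    fit_base_temperature,
    suboptimal_points,
)
from .darkness_response import DarknessRegression, fit_darkness_regression
from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    OrientationError,
    ThermalTimeError,
)
from .io_data import TimeCourse, group_by_treatment, read_census_table
from .percentiles import cumulative_fraction, percentile_table
from .synthetic_data import generate, published_presets
from .thermal_fit import (
    MAX_FRACTION,
    ThermalModel,
    fit_thermal_model,
    thermal_observations,
)
from .validation import DEFAULT_G_GRID, ValidationResult, validate_model


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`."""

    censuses: str | Path | None = None       # CSV path; None → synthetic presets
    presets: Sequence[str] | None = None     # preset names; None → all
    holdout_population: str = "To"
    basis: str = "sown"                      # percentile basis for t_g / GR_g
    fit_basis: str = "final"                 # fraction basis for link fits & validation
    g_cardinal: tuple[float, ...] = (30.0, 50.0, 70.0)
    g_validation: tuple[float, ...] = DEFAULT_G_GRID
    method: str = "logit"                    # "logit" or "probit"
    max_fraction: float = MAX_FRACTION       # inclusion rule for link fits
    seed: int = 0                            # reseeds the synthetic presets
    out_dir: str | Path | None = None


@dataclass
class PipelineResult:
    models: list[ThermalModel]
    base_fits: dict[tuple[str, str, int], BaseTempFit]
    optima: dict[tuple[str, str], OptimumTemp]
    darkness: list[DarknessRegression]
    validations: list[ValidationResult]
    percentiles: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def models_table(self) -> pd.DataFrame:
        """Parameter table: one row per fitted model (Table-3-shaped)."""
        rows = []
        for m in sorted(self.models, key=lambda m: m.group):
            rows.append(
                {
                    "code": m.code,
                    "population": m.population,
                    "regime_class": m.regime_class,
                    "darkness_days": m.darkness_days,
                    "t_b": round(m.t_b, 4),
                    "se_t_b": round(m.se_t_b, 4),
                    "t_o": m.t_o,
                    "ln_theta50": round(m.ln_theta50, 4),
                    "sigma_theta": round(m.sigma_theta, 4),
                    "theta50_degday": round(m.theta50_degday, 4),
                    "theta50_deghour": round(m.theta50_deghour, 2),
                    "method": m.method,
                    "n_obs": m.n_obs,
                }
            )
        return pd.DataFrame(rows)

    def darkness_table(self) -> pd.DataFrame:
        """Darkness-regression table (Table-4-shaped): code, a, b, R²."""
        rows = []
        for d in sorted(self.darkness, key=lambda d: (d.population, d.regime_class)):
            rows.append(
                {
                    "code": f"{d.population}{d.regime_class}",
                    "a": round(d.a, 4),
                    "b": round(d.b, 4),
                    "r2": round(d.r2, 4),
                    "n_levels": d.n,
                }
            )
        return pd.DataFrame(rows)

    def validation_table(self) -> pd.DataFrame:
        """Holdout-validation table (Table-6-shaped): code, R², RMSE."""
        rows = []
        for v in sorted(self.validations, key=lambda v: v.model_group):
            pop, cls, dt = v.model_group
            rows.append(
                {
                    "code": f"{pop}{cls}DT{dt}d",
                    "holdout": v.holdout_population,
                    "r2": round(v.r2, 4),
                    "rmse": round(v.rmse, 4),
                    "n_points": len(v.observed),
                }
            )
        return pd.DataFrame(rows)

    def mean_base_temperature(self) -> float:
        return float(np.mean([m.t_b for m in self.models]))

    def write_tables(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "models": out / "models.csv",
            "darkness": out / "darkness.csv",
            "validation": out / "validation.csv",
            "percentiles": out / "percentiles.csv",
        }
        self.models_table().to_csv(paths["models"], index=False)
        self.darkness_table().to_csv(paths["darkness"], index=False)
        self.validation_table().to_csv(paths["validation"], index=False)
        self.percentiles.to_csv(paths["percentiles"], index=False)
        (out / "run.log").write_text("\n".join(self.log) + "\n")
        return paths


def _load_timecourses(config: PipelineConfig) -> tuple[list[TimeCourse], list[str]]:
    log: list[str] = []
    if config.censuses is not None:
        tcs = read_census_table(config.censuses)
        log.append(f"read {len(tcs)} time courses from {config.censuses}")
        return tcs, log
    presets = published_presets()
    names = list(config.presets) if config.presets else sorted(presets)
    tcs = []
    for i, name in enumerate(names):
        params = presets[name]
        # derived per-preset seed; kept well below 2**31
        params = dataclasses.replace(
            params, seed=(params.seed + 7919 * config.seed) % (2**31 - 1)
        )
        tcs.extend(generate(params))
        log.append(f"generated preset {name} (seed {params.seed})")
    return tcs, log


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and return fitted models, regressions and scores."""
    tcs, log = _load_timecourses(config)
    result = analyse_timecourses(tcs, config, log=log)
    if config.out_dir is not None:
        result.write_tables(config.out_dir)
    return result


def analyse_timecourses(
    tcs: Sequence[TimeCourse],
    config: PipelineConfig | None = None,
    log: list[str] | None = None,
) -> PipelineResult:
    """Analyse in-memory time courses (percentiles → cardinal temps → fits)."""
    config = config or PipelineConfig()
    log = list(log) if log is not None else []
    holdout = [
        tc for tc in tcs if tc.treatment.population == config.holdout_population
    ]
    training = [
        tc for tc in tcs if tc.treatment.population != config.holdout_population
    ]
    if not training:
        raise InsufficientDataError("pipeline: no training censuses after holdout split")
    grouped = group_by_treatment(training)
    ptable = percentile_table(grouped, config.g_cardinal, basis=config.basis)
    if ptable.empty:
        raise InsufficientDataError("pipeline: no percentile reached anywhere (stage: percentiles)")

    # --- optimum temperature per (population, regime class), from DT0d profiles
    optima: dict[tuple[str, str], OptimumTemp] = {}
    for (pop, cls), sub in ptable[ptable.darkness_days == 0].groupby(
        ["population", "regime_class"]
    ):
        profiles = {
            float(g): list(zip(gsub.t_mean, gsub.gr_g))
            for g, gsub in sub.groupby("g")
        }
        try:
            optima[(pop, cls)] = estimate_optimum_temperature(profiles)
        except InsufficientDataError as exc:
            log.append(f"{pop}{cls}: optimum temperature not estimable ({exc})")

    # --- base temperature: one regression per (population, regime class, DT)
    base_fits: dict[tuple[str, str, int], BaseTempFit] = {}
    for (pop, cls, dt), sub in ptable.groupby(
        ["population", "regime_class", "darkness_days"]
    ):
        if (pop, cls) not in optima:
            continue
        t_o = optima[(pop, cls)].t_o
        gr50 = sub[sub.g == 50.0]
        pts = list(zip(gr50.t_mean, gr50.gr_g, gr50.final_fraction))
        kept = suboptimal_points(pts, t_o)
        dropped = sorted(set(gr50.t_mean) - {p[0] for p in kept})
        if dropped:
            log.append(f"{pop}{cls}DT{dt}d: supra-optimal T_m excluded: {dropped}")
        try:
            base = fit_base_temperature([(p[0], p[1]) for p in kept])
        except (InsufficientDataError, DegenerateFitError, OrientationError) as exc:
            log.append(f"{pop}{cls}DT{dt}d: base-temperature fit skipped ({exc})")
            continue
        base_fits[(pop, cls, int(dt))] = base

    # --- shared T_b per (population, regime class): mean of the per-DT fits
    # (the base temperature is treated as a population property; its spread
    # across darkness levels is reported as the SD)
    group_tb: dict[tuple[str, str], tuple[float, float]] = {}
    for pop, cls in sorted({(p, c) for (p, c, _) in base_fits}):
        fits = [f for (p, c, _), f in base_fits.items() if (p, c) == (pop, cls)]
        tbs = np.array([f.t_b for f in fits])
        sd = float(tbs.std(ddof=1)) if len(tbs) > 1 else fits[0].se_t_b
        group_tb[(pop, cls)] = (float(tbs.mean()), sd)
        log.append(
            f"{pop}{cls}: T_b = {tbs.mean():.2f} ± {sd:.2f} "
            f"(mean of {len(tbs)} darkness-level fits)"
        )

    # --- thermal-time distribution fit per (population, regime class, DT);
    # the shared group T_b also covers DT levels whose own T_b regression had
    # too few sub-optimal points
    models: list[ThermalModel] = []
    fit_groups = sorted(
        {
            (pop, cls, int(dt))
            for (pop, cls, dt), _ in ptable.groupby(
                ["population", "regime_class", "darkness_days"]
            )
            if (pop, cls) in group_tb
        }
    )
    for pop, cls, dt in fit_groups:
        t_b, se_t_b = group_tb[(pop, cls)]
        t_o = optima[(pop, cls)].t_o
        group_treatments = []
        for code, group_tcs in grouped.items():
            spec = group_tcs[0].treatment
            if spec.group != (pop, cls, dt) or spec.t_mean > t_o:
                continue
            try:
                days, fractions = cumulative_fraction(
                    group_tcs, basis=config.fit_basis
                )
            except ThermalTimeError as exc:
                log.append(f"{code}: excluded from thermal fit ({exc})")
                continue
            group_treatments.append((spec.t_mean, days, fractions))
        obs = thermal_observations(
            group_treatments, t_b=t_b, max_fraction=config.max_fraction
        )
        try:
            model = fit_thermal_model(
                population=pop,
                regime_class=cls,
                darkness_days=int(dt),
                t_b=t_b,
                se_t_b=se_t_b,
                t_o=t_o,
                observations=obs,
                method=config.method,
            )
        except (InsufficientDataError, DegenerateFitError, OrientationError) as exc:
            log.append(f"{pop}{cls}DT{dt}d: thermal fit skipped ({exc})")
            continue
        models.append(model)
        log.append(
            f"{pop}{cls}DT{dt}d: T_b={t_b:.2f}±{se_t_b:.2f} "
            f"ln_theta50={model.ln_theta50:.3f} sigma={model.sigma_theta:.3f} "
            f"({len(obs)} obs)"
        )

    # --- darkness regressions per (population, regime class)
    darkness: list[DarknessRegression] = []
    by_group: dict[tuple[str, str], list[ThermalModel]] = {}
    for m in models:
        by_group.setdefault((m.population, m.regime_class), []).append(m)
    for (pop, cls), ms in sorted(by_group.items()):
        pts = [(float(m.darkness_days), m.ln_theta50) for m in ms]
        try:
            darkness.append(fit_darkness_regression(pts, pop, cls))
        except InsufficientDataError as exc:
            log.append(f"{pop}{cls}: darkness regression skipped ({exc})")

    # --- holdout validation
    validations: list[ValidationResult] = []
    if holdout:
        for m in models:
            try:
                validations.append(
                    validate_model(m, holdout, g_grid=config.g_validation,
                                   basis=config.fit_basis)
                )
            except (InsufficientDataError, ThermalTimeError) as exc:
                log.append(f"{m.code}: validation skipped ({exc})")
    else:
        log.append(f"no holdout censuses for population {config.holdout_population!r}")

    return PipelineResult(
        models=models,
        base_fits=base_fits,
        optima=optima,
        darkness=darkness,
        validations=validations,
        percentiles=ptable,
        log=log,
    )
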