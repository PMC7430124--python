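
import numpy as np
import pytest

from thermaltime.io_data import group_by_treatment
from thermaltime.percentiles import cumulative_fraction
from thermaltime.synthetic_data import (
    ALTERNATING_REGIMES,
    CONSTANT_REGIMES,
    GeneratorParams,
    generate,
    published_presets,
    preset,
)


def small_params(**overrides):
    defaults = dict(
        population="Syn", t_b=16.4, t_o=22.5, ln_theta50_dt0=2.41,
        darkness_slope_b=0.044, sigma_theta=0.4, viability=0.97,
        seed=7, regimes=((17.5, 17.5), (22.5, 22.5)), darkness_days=(0, 20),
    )
    defaults.update(overrides)
    return GeneratorParams(**defaults)


class TestGenerate:
    def test_deterministic_given_seed(self):
        a = generate(small_params())
        b = generate(small_params())
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.treatment == y.treatment and x.replicate_id == y.replicate_id
            assert np.array_equal(x.cumulative_germinated, y.cumulative_germinated)

    def test_different_seed_changes_censuses(self):
        a = generate(small_params())
        b = generate(small_params(seed=8))
        assert any(
            not np.array_equal(x.cumulative_germinated, y.cumulative_germinated)
            for x, y in zip(a, b)
        )

    def test_design_shape(self):
        tcs = generate(small_params())
        assert len(tcs) == 2 * 2 * 3  # regimes × darkness × replicates
        assert all(tc.census_days[-1] == 20 for tc in tcs)

    def test_invariants_hold_by_construction(self):
        for tc in generate(preset("CuC", seed=5)):
            assert np.all(np.diff(tc.cumulative_germinated) >= 0)
            assert tc.cumulative_germinated[-1] <= tc.seeds_sown

    def test_sub_base_temperature_never_germinates(self):
        tcs = generate(small_params(regimes=((15.0, 15.0),), t_b=16.4,
                                    darkness_days=(0,)))
        assert all(tc.final_count == 0 for tc in tcs)

    def test_total_darkness_never_germinates(self):
        tcs = generate(preset("CuC", seed=9))
        dark = [tc for tc in tcs if tc.treatment.darkness_days == 20]
        assert dark and all(tc.final_count == 0 for tc in dark)

    def test_final_germination_drops_toward_base_temperature(self):
        """With fixed 20-day censoring, expected final germination falls as
        T_m approaches T_b (slow thermal accumulation leaves the slowest
        seeds censored); checked where censoring binds (DT10d) over seeds."""
        finals = {17.5: [], 22.5: []}
        for seed in (10, 11, 12):
            tcs = generate(preset("CuC", seed=seed))
            by_code = group_by_treatment(
                [tc for tc in tcs if tc.treatment.darkness_days == 10]
            )
            for group in by_code.values():
                t_m = group[0].treatment.t_mean
                if t_m in finals:
                    finals[t_m].append(cumulative_fraction(group)[1][-1])
        assert np.mean(finals[17.5]) < np.mean(finals[22.5])

    def test_supra_optimal_decline_reduces_rate_not_viability(self):
        p = preset("MaC", seed=11)  # t_o = 25, ceiling-anchored decline
        tcs = [tc for tc in generate(p) if tc.treatment.darkness_days == 0]
        by_tm = {}
        for code, group in group_by_treatment(tcs).items():
            days, frac = cumulative_fraction(group)
            by_tm[group[0].treatment.t_mean] = frac
        # germination still occurs at 30 °C, but later than at the optimum
        assert by_tm[30.0][-1] > 0.8
        assert by_tm[25.0][4] > by_tm[30.0][4]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            small_params(viability=0.0)
        with pytest.raises(ValueError):
            small_params(sigma_theta=-0.1)


class TestPresets:
    def test_all_presets_generate_valid_designs(self):
        presets = published_presets()
        assert set(presets) == {
            "BaC", "BaA", "CuC", "CuA", "MaC", "MaA", "SeC", "SeA", "ToC", "ToA",
        }
        for name, p in presets.items():
            assert 0 < p.viability <= 1 and p.sigma_theta > 0
            expected = CONSTANT_REGIMES if name.endswith("C") else ALTERNATING_REGIMES
            assert p.regimes == expected

    def test_population_mean_base_temperature(self):
        presets = published_presets()
        tbs = [presets[k].t_b for k in ("BaC", "CuC", "MaC", "SeC")]
        assert np.mean(tbs) == pytest.approx(16.4, abs=0.05)

    def test_cu_constant_parameters(self):
        p = preset("CuC")
        assert p.t_o == 22.5
        assert p.ln_theta50_dt0 == pytest.approx(2.41)
        assert p.sigma_theta == pytest.approx(0.4)
        assert 16.1 <= p.t_b <= 16.7

    def test_preset_reseeding_and_lookup_error(self):
        assert preset("CuC", seed=123).seed == 123
        with pytest.raises(KeyError):
            preset("XxQ")
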