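import math

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from thermaltime.errors import (
    DegenerateFitError,
    InsufficientDataError,
    OrientationError,
    SubBaseTemperatureError,
)
from thermaltime.thermal_fit import (
    LOGIT_SIGMA_FACTOR,
    ThermalModel,
    derive_sigma_logit,
    fit_logit,
    fit_probit,
    fit_thermal_model,
    theta50_from_rate,
    thermal_observations,
    thermal_time,
)


class TestThermalTime:
    def test_degree_day_product(self):
        assert thermal_time(22.5, 16.4, 1.82) == pytest.approx(11.1, abs=0.01)

    def test_zero_time(self):
        assert thermal_time(22.5, 16.4, 0.0) == 0.0

    def test_sub_base_rejected(self):
        with pytest.raises(SubBaseTemperatureError):
            thermal_time(16.0, 16.4, 1.0)

    def test_covell_normalization_consistency(self):
        # (T_m - T_b)/GR50 equals (T_m - T_b) * t50 with t50 = 1/GR50
        t_m, t_b, gr = 22.5, 16.4, 0.548
        assert theta50_from_rate(t_m, t_b, gr) == pytest.approx(
            thermal_time(t_m, t_b, 1.0 / gr), rel=1e-12
        )
        assert theta50_from_rate(22.5, 16.4, 0.548) == pytest.approx(11.13, abs=0.01)

    def test_theta50_from_rate_identity(self):
        assert theta50_from_rate(17.4, 16.4, 1.0) == pytest.approx(1.0)


class TestLogitFit:
    def test_exact_logistic_inversion(self):
        """Noiseless logistic data in ln θ is inverted exactly."""
        alpha, beta = 4.0, -9.64
        ln_theta = np.linspace(1.8, 3.0, 9)
        obs = list(zip(np.exp(ln_theta), expit(alpha * ln_theta + beta)))
        a, b = fit_logit(obs)
        assert a == pytest.approx(alpha, rel=1e-9)
        assert b == pytest.approx(beta, rel=1e-9)
        assert -b / a == pytest.approx(2.41, abs=1e-9)

    def test_symmetric_data_midpoint(self):
        """Symmetric fractions straddling 0.5 put ln θ50 at the centre."""
        centre = 2.6
        offsets = np.array([-0.3, -0.1, 0.1, 0.3])
        fracs = np.array([0.2, 0.4, 0.6, 0.8])
        obs = list(zip(np.exp(centre + offsets), fracs))
        a, b = fit_logit(obs)
        assert -b / a == pytest.approx(centre, rel=1e-9)

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_logit([(5.0, 0.5), (10.0, 0.5), (20.0, 0.5)])

    def test_decreasing_fractions_rejected(self):
        with pytest.raises(OrientationError):
            fit_logit([(5.0, 0.8), (10.0, 0.5), (20.0, 0.2)])

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            fit_logit([(5.0, 0.0), (10.0, 0.5), (20.0, 0.9)])

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            fit_logit([(5.0, 0.2), (10.0, 0.8)])


class TestProbitFit:
    def test_normal_cdf_inversion(self):
        """Fractions from a Normal(2.41, 0.4) CDF in ln θ are inverted exactly."""
        ln50, sigma = 2.41, 0.4
        z = np.linspace(-1.8, 1.8, 9)
        obs = list(zip(np.exp(ln50 + sigma * z), norm.cdf(z)))
        slope, intercept = fit_probit(obs)
        assert 1.0 / slope == pytest.approx(sigma, rel=1e-9)
        assert -intercept / slope == pytest.approx(ln50, rel=1e-9)
        assert slope == pytest.approx(2.5, rel=1e-9)  # reciprocal of σ = 0.4

    def test_midpoint_agrees_with_logit_on_symmetric_data(self):
        ln50, sigma = 2.41, 0.4
        z = np.linspace(-2.0, 2.0, 11)
        obs = list(zip(np.exp(ln50 + sigma * z), norm.cdf(z)))
        a_l, b_l = fit_logit(obs)
        a_p, b_p = fit_probit(obs)
        assert -b_l / a_l == pytest.approx(-b_p / a_p, abs=1e-6)


class TestSigmaRelation:
    def test_identity_alpha(self):
        assert derive_sigma_logit(LOGIT_SIGMA_FACTOR) == pytest.approx(1.0)

    def test_printed_value(self):
        assert derive_sigma_logit(4.534) == pytest.approx(0.4, abs=1e-3)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.7, 4.534, 10.0])
    def test_product_is_constant(self, alpha):
        assert derive_sigma_logit(alpha) * alpha == pytest.approx(
            math.pi / math.sqrt(3), rel=1e-15
        )

    def test_domain(self):
        with pytest.raises(ValueError):
            derive_sigma_logit(0.0)


class TestThermalModel:
    @pytest.fixture
    def model(self):
        alpha = LOGIT_SIGMA_FACTOR / 0.4  # σ = 0.4
        return ThermalModel(
            population="Cu", regime_class="C", darkness_days=0,
            t_b=16.1, se_t_b=0.2, t_o=22.5,
            alpha=alpha, beta=-alpha * 2.41,
        )

    def test_median_and_units(self, model):
        assert model.ln_theta50 == pytest.approx(2.41)
        assert model.sigma_theta == pytest.approx(0.4)
        assert model.theta50_deghour == pytest.approx(24.0 * model.theta50_degday)
        assert model.predict_fraction(model.theta50_degday) == pytest.approx(0.5)

    def test_limits_and_monotonicity(self, model):
        theta = np.logspace(-3, 4, 50)
        p = model.predict_fraction(theta)
        assert p[0] < 1e-6 and p[-1] > 1 - 1e-6
        assert np.all(np.diff(p) > 0)

    def test_median_round_trip(self, model):
        assert model.expected_log_theta(50.0) == pytest.approx(
            math.log(model.theta50_degday), rel=1e-12
        )

    def test_quantiles_bracket_median(self, model):
        lo, hi = model.expected_log_theta([30.0, 70.0])
        assert lo < model.ln_theta50 < hi


class TestObservationPooling:
    def test_inclusion_rule_and_sub_base_exclusion(self):
        days = np.arange(1, 6, dtype=float)
        fractions = np.array([0.0, 0.2, 0.5, 0.95, 1.0])
        obs = thermal_observations(
            [(20.0, days, fractions), (16.0, days, fractions)], t_b=16.4
        )
        # the 16.0 °C treatment is below T_b; fractions 0, 0.95, 1.0 excluded
        assert len(obs) == 2
        assert all(f in (0.2, 0.5) for _, f in obs)
        assert obs[0][0] == pytest.approx((20.0 - 16.4) * 2)

    def test_fit_thermal_model_end_to_end(self):
        alpha_true, ln50 = 4.0, 2.41
        days = np.arange(1, 21, dtype=float)
        t_b, t_m = 16.1, 20.0
        theta = (t_m - t_b) * days
        frac = expit(alpha_true * (np.log(theta) - ln50))
        model = fit_thermal_model(
            population="Syn", regime_class="C", darkness_days=0,
            t_b=t_b, se_t_b=0.0, t_o=22.5,
            observations=thermal_observations([(t_m, days, frac)], t_b=t_b),
        )
        assert model.ln_theta50 == pytest.approx(ln50, abs=1e-6)
        assert model.alpha == pytest.approx(alpha_true, rel=1e-6)
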