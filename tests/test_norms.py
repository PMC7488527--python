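"""Reaction norms: durations, rates, thresholds, thermal constants."""

import numpy as np
import pandas as pd
import pytest

from thermodev import refdata
from thermodev.norms import (
    durations_from_transitions,
    fit_linear_norm,
    fit_quadratic_norm,
    ltt,
    ltt_se,
    quadratic_lower_root,
    rates_from_durations,
    thermal_constant,
)


@pytest.fixture(scope="module")
def ref():
    return refdata.make_fixture_tables()


class TestDurations:
    def test_differencing_matches_published_values(self, ref):
        dur = durations_from_transitions(ref.transitions_h)
        # germ band retraction at the coolest regime: 107.90 - 54.63
        assert dur.loc["germ_band_retraction", 20] == pytest.approx(53.27)
        # first stage duration equals its transition time
        assert dur.loc["early_cleavages", 20] == pytest.approx(14.10)
        # published duration table is the differenced transition table
        assert np.allclose(dur.to_numpy(), ref.durations_h.to_numpy(), atol=0.011)

    def test_durations_sum_to_final_transition(self, ref):
        dur = durations_from_transitions(ref.transitions_h)
        assert np.allclose(dur.sum(axis=0), ref.transitions_h.iloc[-1])

    def test_non_monotone_transitions_rejected(self):
        bad = pd.DataFrame({"20": [10.0, 10.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="non-monotone"):
            durations_from_transitions(bad)


class TestRates:
    def test_hatching_time_in_days(self, ref):
        # oviposition -> hatching takes 269.90 h = 11.2 d at the coolest regime
        t_hatch = ref.transitions_h.loc["hatching", 20]
        assert round(t_hatch / 24.0, 1) == 11.2

    @pytest.mark.parametrize(
        "d_h,out_units,expected",
        [(24.0, "per_day", 1.0), (10.0, "per_hour", 0.1), (10.0, "per_day", 2.4)],
    )
    def test_unit_conversions(self, d_h, out_units, expected):
        r = rates_from_durations(pd.Series([d_h]), out_units=out_units)
        assert r.iloc[0] == pytest.approx(expected)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rates_from_durations(pd.Series([0.0]))


class TestLinearNorm:
    def test_exact_line_recovered(self):
        T = np.array([18.0, 22.0, 26.0, 30.0])
        fit = fit_linear_norm(T, 0.01 * (T - 10.0), stage="synthetic")
        assert fit.a == pytest.approx(-0.1, abs=1e-12)
        assert fit.b == pytest.approx(0.01, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.model == "linear"
        assert fit.ltt_c == pytest.approx(10.0, abs=1e-9)

    def test_germ_band_extension_threshold(self, ref):
        temps = refdata.actual_temperatures("germ_band_extension")
        rates = rates_from_durations(ref.durations_h.loc["germ_band_extension"])
        fit = fit_linear_norm(temps, rates.to_numpy())
        assert round(fit.ltt_c, 1) == 16.7

    def test_final_morphogenesis_fails_linearity_gate(self, ref):
        temps = refdata.actual_temperatures("final_morphogenesis")
        rates = rates_from_durations(ref.durations_h.loc["final_morphogenesis"])
        fit = fit_linear_norm(temps, rates.to_numpy())
        assert round(fit.r2, 2) == 0.86
        assert fit.model == "nonlinear"

    def test_matches_normal_equations_oracle(self, ref):
        temps = np.asarray(refdata.actual_temperatures("hatching"))
        rates = rates_from_durations(ref.durations_h.loc["hatching"]).to_numpy()
        fit = fit_linear_norm(temps, rates)
        # closed-form normal equations
        b = np.sum((temps - temps.mean()) * (rates - rates.mean())) / np.sum(
            (temps - temps.mean()) ** 2
        )
        a = rates.mean() - b * temps.mean()
        assert fit.a == pytest.approx(a, rel=1e-10)
        assert fit.b == pytest.approx(b, rel=1e-10)

    def test_strong_curvature_is_gated_to_quadratic_path(self):
        T = np.linspace(18, 32, 6)
        R = -0.002 * T**2 + 0.12 * T - 1.4  # strongly curved over the range
        fit = fit_linear_norm(T, R)
        assert fit.model == "nonlinear"
        assert fit.r2 < 0.97

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_linear_norm([20.0, 25.0], [0.1, 0.2])


class TestThresholdAlgebra:
    def test_pupal_threshold_and_constant(self):
        assert round(ltt(-0.1607, 0.01295), 1) == 12.4
        assert round(thermal_constant(0.01295, "per_day")["degree_days"], 1) == 77.2

    def test_early_cleavage_threshold(self):
        assert round(ltt(-0.2269, 0.01479), 1) == 15.3

    def test_zero_intercept(self):
        assert ltt(0.0, 0.01) == 0.0

    def test_larval_degree_days(self):
        assert round(thermal_constant(0.00527, "per_day")["degree_days"], 1) == 189.8

    def test_degree_hours_to_degree_days(self):
        k = thermal_constant(0.00067, "per_hour")
        assert k["degree_hours"] == pytest.approx(1492.5, abs=0.1)
        assert round(k["degree_days"], 1) == 62.2

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            ltt(-0.1, 0.0)
        with pytest.raises(ValueError):
            thermal_constant(-0.01, "per_day")

    def test_ltt_invariant_to_rate_units(self, ref):
        temps = np.asarray(refdata.actual_temperatures("hatching"))
        dur = ref.durations_h.loc["hatching"]
        fit_h = fit_linear_norm(temps, rates_from_durations(dur, "per_hour"))
        fit_d = fit_linear_norm(
            temps, rates_from_durations(dur, "per_day"), rate_units="per_day"
        )
        assert fit_h.ltt_c == pytest.approx(fit_d.ltt_c, abs=1e-9)
        assert fit_h.k_degree_days == pytest.approx(fit_d.k_degree_days, rel=1e-9)


class TestThresholdSE:
    def _noisy_fit(self, seed=7):
        rng = np.random.default_rng(seed)
        T = np.array([19.8, 22.7, 25.6, 28.6, 31.7])
        R = 0.012 * (T - 15.0) + rng.normal(0, 0.004, len(T))
        return fit_linear_norm(T, R)

    def test_perfect_line_gives_zero_se(self):
        T = np.array([20.0, 24.0, 28.0, 32.0])
        fit = fit_linear_norm(T, 0.01 * (T - 12.0))
        for method in ("campbell", "delta", "bootstrap"):
            assert ltt_se(fit, method=method) == pytest.approx(0.0, abs=1e-9)

    def test_delta_close_to_parametric_bootstrap(self):
        fit = self._noisy_fit()
        se_delta = ltt_se(fit, method="delta")
        se_boot = ltt_se(fit, method="bootstrap", n_boot=10_000, seed=0)
        assert se_delta == pytest.approx(se_boot, rel=0.15)

    def test_se_invariant_to_rate_units(self):
        rng = np.random.default_rng(3)
        T = np.array([19.8, 22.7, 25.6, 28.6, 31.7])
        R_h = 0.012 * (T - 15.0) + rng.normal(0, 0.003, len(T))
        fit_h = fit_linear_norm(T, R_h, rate_units="per_hour")
        fit_d = fit_linear_norm(T, R_h * 24.0, rate_units="per_day")
        for method in ("campbell", "delta"):
            assert ltt_se(fit_h, method=method) == pytest.approx(
                ltt_se(fit_d, method=method), rel=1e-9
            )


class TestQuadraticNorm:
    def test_teneral_lower_crossing(self, ref):
        c2, c1, c0 = ref.quadratic["teneral"]
        assert round(quadratic_lower_root(c2, c1, c0), 1) == 16.6

    def test_degenerate_quadratic_reduces_to_linear_root(self):
        assert quadratic_lower_root(0.0, 0.01, -0.1) == pytest.approx(10.0)

    def test_root_satisfies_polynomial(self, ref):
        c2, c1, c0 = ref.quadratic["teneral"]
        r = quadratic_lower_root(c2, c1, c0)
        assert abs(c2 * r**2 + c1 * r + c0) < 1e-10

    def test_no_real_crossing_reported_absent(self):
        assert quadratic_lower_root(-0.001, 0.0, -1.0) is None

    def test_fit_recovers_exact_quadratic(self):
        T = np.linspace(18, 34, 9)
        c2, c1, c0 = -0.0021, 0.1219, -1.443
        fit = fit_quadratic_norm(T, c2 * T**2 + c1 * T + c0)
        assert fit.quad_coef == pytest.approx((c2, c1, c0), abs=1e-10)
        assert round(fit.quad_lower_root_c, 1) == 16.6
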