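"""Exponential, power-law and log-log estimation, and the scalar statistics.

Derived expectations were frozen from independent closed-form oracles:
log-OLS slopes through the reported group means, a 90001-point grid
search over the power-law exponent with the closed-form prefactor, and
the textbook product-moment formula.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xylokinetics import (ExponentialGrowthModel, PowerLawModel,
                          fit_exponential, fit_power_law, loglog_fit,
                          pearson_r, propagate_error, r_squared)

# frozen closed-form oracle values on the printed group means
K_AREA_OLSLOG = 0.3951594
X0_AREA_OLSLOG_UM2 = 126.45345
K_CELLS_OLSLOG = 0.3221277
LOGLOG_SLOPE = 0.5849134
PEARSON_MEANS = 0.9612373
POWER_P_GRID = 0.45461       # argmin of linear-space SSE, grid step 1e-5

TIMES4 = np.array([7.0, 11.0, 15.0, 21.0])


class TestFitExponential:
    @pytest.mark.parametrize("method", ["odr", "lm", "ols_log"])
    def test_noiseless_roundtrip_all_methods(self, method):
        X0, k = 8.8e-4, 0.32
        values = X0 * np.exp(k * TIMES4)
        res = fit_exponential(TIMES4, values, method=method)
        assert res.converged
        assert res.estimates["X0"] == pytest.approx(X0, rel=1e-6)
        assert res.estimates["k"] == pytest.approx(k, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(X0=st.floats(1e-4, 1e3), k=st.floats(-0.5, 0.8))
    def test_roundtrip_property(self, X0, k):
        values = X0 * np.exp(k * TIMES4)
        for method in ("odr", "lm", "ols_log"):
            res = fit_exponential(TIMES4, values, method=method)
            assert res.estimates["X0"] == pytest.approx(X0, rel=1e-6)
            assert res.estimates["k"] == pytest.approx(k, abs=1e-6)

    def test_constant_series_gives_zero_rate(self):
        res = fit_exponential(TIMES4, np.full(4, 5.0), method="ols_log")
        assert res.estimates["k"] == pytest.approx(0.0, abs=1e-14)
        assert res.estimates["X0"] == pytest.approx(5.0)

    def test_printed_area_means_log_slope(self, times, printed_means):
        res = fit_exponential(times, printed_means["area_um2"], method="ols_log")
        assert res.estimates["k"] == pytest.approx(K_AREA_OLSLOG, abs=1e-6)
        assert res.estimates["X0"] == pytest.approx(X0_AREA_OLSLOG_UM2, rel=1e-6)

    def test_printed_cell_means_log_slope(self, times, printed_means):
        res = fit_exponential(times, printed_means["cells"], method="ols_log")
        assert res.estimates["k"] == pytest.approx(K_CELLS_OLSLOG, abs=1e-6)

    def test_odr_equals_lm_when_time_errors_vanish(self):
        rng = np.random.default_rng(7)
        values = 3.0 * np.exp(0.25 * TIMES4) * rng.lognormal(0, 0.05, 4)
        a = fit_exponential(TIMES4, values, time_errors=np.zeros(4), method="odr")
        b = fit_exponential(TIMES4, values, method="lm")
        assert a.estimates["k"] == pytest.approx(b.estimates["k"], rel=1e-6)
        assert a.estimates["X0"] == pytest.approx(b.estimates["X0"], rel=1e-6)

    def test_odr_uses_time_errors(self):
        # with genuine abscissa error the orthogonal fit must differ from
        # the vertical one on scattered data
        rng = np.random.default_rng(11)
        values = 3.0 * np.exp(0.25 * TIMES4) * rng.lognormal(0, 0.2, 4)
        a = fit_exponential(TIMES4, values, time_errors=np.full(4, 1.0),
                            value_errors=0.2 * values, method="odr")
        b = fit_exponential(TIMES4, values, method="lm")
        assert a.estimates["k"] != pytest.approx(b.estimates["k"], rel=1e-9)

    def test_ols_log_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_exponential(TIMES4, np.array([1.0, -2.0, 3.0, 4.0]),
                            method="ols_log")

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0, 2.0], [1.0, 2.0])

    def test_summary_mentions_estimates(self):
        res = fit_exponential(TIMES4, 2.0 * np.exp(0.1 * TIMES4),
                              quantity="area")
        text = res.summary()
        assert "X0" in text and "k" in text and "area" in text

    def test_from_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({"t": TIMES4, "v": 2.0 * np.exp(0.1 * TIMES4)})
        res = ExponentialGrowthModel.from_dataframe(df, "t", "v").fit("ols_log")
        assert res.estimates["k"] == pytest.approx(0.1, abs=1e-9)


class TestFitPowerLaw:
    def test_exact_roundtrip(self):
        x = np.array([1.0, 4.0, 9.0, 25.0])
        y = 0.05 * x ** 0.4
        res = fit_power_law(x, y)
        assert res.converged
        assert res.estimates["c"] == pytest.approx(0.05, rel=1e-6)
        assert res.estimates["p"] == pytest.approx(0.4, rel=1e-6)

    def test_fixed_exponent_closed_form(self):
        x = np.array([1.0, 2.0, 3.0])
        res = fit_power_law(x, 2.0 * x, fixed_p=1.0)
        assert res.estimates["c"] == pytest.approx(2.0, rel=1e-12)
        assert res.estimates["p"] == 1.0

    def test_printed_means_free_exponent(self, printed_means):
        res = fit_power_law(printed_means["area_um2"],
                            printed_means["extension_cm"])
        assert res.converged
        assert res.estimates["p"] == pytest.approx(POWER_P_GRID, abs=1e-3)

    def test_exponent_unit_invariant(self, printed_means):
        in_um_cm = fit_power_law(printed_means["area_um2"],
                                 printed_means["extension_cm"])
        in_mm = fit_power_law(printed_means["area_um2"] / 1e6,
                              printed_means["extension_cm"] * 10.0)
        assert in_um_cm.estimates["p"] == pytest.approx(
            in_mm.estimates["p"], abs=1e-6)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([2.0, 2.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            PowerLawModel(np.array([1.0, -1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestLogLogFit:
    def test_exact_power_law_slope(self):
        x = np.array([1.0, 3.0, 7.0, 20.0])
        res = loglog_fit(x, 2.0 * x ** 0.37)
        assert res.estimates["p"] == pytest.approx(0.37, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_printed_means_slope(self, printed_means):
        res = loglog_fit(printed_means["area_um2"], printed_means["extension_cm"])
        assert res.estimates["p"] == pytest.approx(LOGLOG_SLOPE, abs=1e-6)

    def test_two_point_slope_is_log_ratio(self):
        x = np.array([2.0, 8.0])
        y = np.array([3.0, 11.0])
        expect = np.log(11.0 / 3.0) / np.log(4.0)
        assert loglog_fit(x, y).estimates["p"] == pytest.approx(expect)

    def test_slope_equals_rate_ratio_on_exact_exponentials(self):
        t = TIMES4
        a = 2e-4 * np.exp(0.3951594 * t)
        h = 0.96 * np.exp(0.2276335 * t)
        res = loglog_fit(a, h)
        assert res.estimates["p"] == pytest.approx(0.2276335 / 0.3951594,
                                                   rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            loglog_fit(np.array([1.0, 0.0]), np.array([1.0, 2.0]))


class TestPearson:
    def test_perfect_affine(self):
        x = np.array([1.0, 2.0, 5.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_printed_means(self, printed_means):
        r = pearson_r(printed_means["area_um2"], printed_means["extension_cm"])
        assert r == pytest.approx(PEARSON_MEANS, abs=1e-6)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_bounded_and_affine_invariant(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r = pearson_r(x, y)
        assert -1.0 <= r <= 1.0
        assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))


class TestRSquared:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, obs) == 1.0

    def test_mean_prediction_is_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_computed_half(self):
        assert r_squared(np.array([1.0, 2.0, 3.0]),
                         np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.array([2.0, 2.0]), np.array([1.0, 2.0]))


class TestPropagateError:
    def test_three_four_five(self):
        value, err = propagate_error([(10.0, 0.3), (2.0, 0.08)], "product")
        assert value == pytest.approx(20.0)
        assert err == pytest.approx(1.0)

    def test_exact_component_keeps_relative_error(self):
        value, err = propagate_error([(10.0, 0.3), (2.0, 0.0)], "product")
        assert err / value == pytest.approx(0.03)

    def test_constant_scales_absolute_error_only(self):
        value, err = propagate_error([(6.0, 0.6), (2.0, 0.0)], "product",
                                     scale=1.0 / 3.0)
        assert value == pytest.approx(4.0)
        assert err / value == pytest.approx(0.1)

    def test_quotient(self):
        value, err = propagate_error([(10.0, 0.3), (2.0, 0.08)], "quotient")
        assert value == pytest.approx(5.0)
        assert err / value == pytest.approx(0.05)

    def test_zero_value_with_error_rejected(self):
        with pytest.raises(ValueError):
            propagate_error([(0.0, 0.1)], "scaled")
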