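import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from lymphbench import (
    ExponentialPressureModel,
    ValveFit,
    ValveResistanceModel,
    coefficient_of_determination,
    eval_valve_resistance,
    fit_pressure_map,
    fit_valve_model,
    predict_flow,
    threshold_summary,
    valve_opening_threshold,
)
from lymphbench.errors import (
    DroppedPointsWarning,
    InsufficientDataError,
    InvalidModelError,
)

TD1 = ValveResistanceModel(r_vl=0.088, r_vh=1.54e4, s=25.4)


def threshold_bisection_oracle(model: ValveResistanceModel) -> float:
    """Exact inversion of the sigmoid at 1.05 r_vl, solved numerically."""
    f = lambda dp: eval_valve_resistance(model, dp) - 1.05 * model.r_vl
    return brentq(f, 1e-12, 1e4, xtol=1e-12)


class TestEvalValveResistance:
    def test_midpoint(self):
        assert eval_valve_resistance(TD1, 0.0) == pytest.approx(TD1.r_vl + TD1.r_vh / 2, rel=1e-12)

    def test_open_limit_no_overflow(self):
        dp = 800.0 / TD1.s  # s*dp = 800, would overflow a naive exp
        assert eval_valve_resistance(TD1, dp) == pytest.approx(TD1.r_vl, rel=1e-12)

    def test_closed_limit(self):
        assert eval_valve_resistance(TD1, -800.0 / TD1.s) == pytest.approx(
            TD1.r_vl + TD1.r_vh, rel=1e-12
        )

    def test_value_at_threshold_within_5pct_of_plateau(self):
        thr = valve_opening_threshold(TD1)
        assert eval_valve_resistance(TD1, thr) == pytest.approx(TD1.r_vl, rel=0.05)

    @given(
        r_vl=st.floats(1e-3, 1.0),
        r_vh=st.floats(1e-2, 1e10),
        s=st.floats(0.5, 100),
        dp=st.floats(-50, 50),
        delta=st.floats(1e-3, 10),
    )
    def test_strictly_decreasing_and_bounded(self, r_vl, r_vh, s, dp, delta):
        m = ValveResistanceModel(r_vl, r_vh, s)
        lo, hi = eval_valve_resistance(m, dp + delta), eval_valve_resistance(m, dp)
        assert lo <= hi
        # open bounds mathematically; closed here because the logistic term
        # underflows to 0/1 at extreme arguments
        assert r_vl <= hi <= r_vl + r_vh

    def test_invalid_model(self):
        with pytest.raises(InvalidModelError):
            ValveResistanceModel(-0.1, 1.0, 1.0)
        with pytest.raises(InvalidModelError):
            ValveResistanceModel(0.1, 0.0, 1.0)


class TestCoefficientOfDetermination:
    def test_perfect(self):
        assert coefficient_of_determination([1, 2, 3], [1, 2, 3]) == 1.0

    def test_constant_mean_model(self):
        assert coefficient_of_determination([2, 2, 2], [1, 2, 3]) == pytest.approx(0.0)

    def test_hand_example(self):
        # SS_res = (4-3)^2 = 1; SS_tot = (1-2)^2 + (2-2)^2 + (3-2)^2 = 2
        assert coefficient_of_determination([1, 2, 4], [1, 2, 3]) == pytest.approx(0.5)

    def test_identical_data_undefined(self):
        with pytest.raises(InvalidModelError):
            coefficient_of_determination([1, 2], [5, 5])

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            coefficient_of_determination([1], [1])


class TestFitPressureMap:
    def test_exact_recovery(self):
        dp = np.arange(1.0, 11.0)
        pmap = fit_pressure_map(dp, 0.5 * np.exp(0.2 * dp))
        assert pmap.p0 == pytest.approx(0.5, rel=1e-6)
        assert pmap.a == pytest.approx(0.2, rel=1e-6)

    def test_constant_data(self):
        dp = np.arange(1.0, 11.0)
        pmap = fit_pressure_map(dp, np.full(10, 3.0))
        assert pmap.p0 == pytest.approx(3.0, rel=1e-4)
        assert pmap.a == pytest.approx(0.0, abs=1e-5)

    def test_evaluates_to_p0_at_zero(self):
        pmap = ExponentialPressureModel(p0=0.7, a=0.3)
        assert pmap(0.0) == pytest.approx(0.7)

    def test_non_positive_points_dropped_with_warning(self):
        dp = np.arange(0.0, 6.0)
        dpv = 0.5 * np.exp(0.2 * dp)
        dpv[0] = -0.1
        with pytest.warns(DroppedPointsWarning):
            pmap = fit_pressure_map(dp, dpv)
        assert pmap.p0 == pytest.approx(0.5, rel=1e-5)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_pressure_map([1.0, 2.0], [-1.0, 0.5])


class TestFitValveModel:
    def test_td1_recovery(self):
        dp = np.linspace(0.05, 2.0, 15)  # spans the TD1 transition (threshold 0.593)
        r = eval_valve_resistance(TD1, dp)
        model, r2 = fit_valve_model(dp, r)
        assert model.r_vl == pytest.approx(TD1.r_vl, rel=0.01)
        assert model.r_vh == pytest.approx(TD1.r_vh, rel=0.01)
        assert model.s == pytest.approx(TD1.s, rel=0.01)
        assert r2 >= 0.999

    def test_perfect_fit_r2(self):
        dp = np.linspace(0.05, 2.0, 15)
        _, r2 = fit_valve_model(dp, eval_valve_resistance(TD1, dp))
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_plateau_identification(self):
        dp = np.linspace(5.0, 10.0, 8)  # far beyond any transition
        model, _ = fit_valve_model(dp, np.full(8, 0.25) + np.array([1e-6, 0, 0, 0, 0, 0, 0, 0]))
        assert model.r_vl == pytest.approx(0.25, rel=0.01)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_valve_model([1.0, 2.0], [1.0, 0.5])

    def test_log_objective_recovery(self):
        dp = np.linspace(0.05, 2.0, 15)
        r = eval_valve_resistance(TD1, dp)
        model, r2 = fit_valve_model(dp, r, objective="log")
        assert model.r_vl == pytest.approx(TD1.r_vl, rel=0.01)
        assert r2 >= 0.999

    def test_log_objective_drops_non_positive(self):
        dp = np.linspace(0.05, 2.0, 15)
        r = eval_valve_resistance(TD1, dp).copy()
        r[-1] = -0.01
        with pytest.warns(DroppedPointsWarning):
            fit_valve_model(dp, r, objective="log")

    def test_unknown_objective(self):
        with pytest.raises(ValueError):
            fit_valve_model([1, 2, 3], [3, 2, 1], objective="huber")


class TestPredictFlow:
    def _fit(self, model=TD1, p0=0.5, a=0.2):
        return ValveFit(
            segment_id="x",
            model=model,
            pressure_map=ExponentialPressureModel(p0, a),
            r_squared_resistance=1.0,
            r_squared_flow=float("nan"),
            threshold=valve_opening_threshold(model),
        )

    def test_zero_pressure_zero_flow(self):
        q = predict_flow(np.array([0.0]), self._fit(), r_conn=0.393, r_vessel=np.array([0.01]))
        assert q[0] == 0.0

    def test_constant_valve_closed_form(self):
        # r_vh -> 0 limit: flow = dp / (r_conn + r_vessel + r_vl)
        tiny = ValveResistanceModel(r_vl=0.1, r_vh=1e-15, s=10.0)
        dp = np.array([1.0, 5.0, 10.0])
        rv = np.array([0.01, 0.02, 0.03])
        q = predict_flow(dp, self._fit(model=tiny), r_conn=0.393, r_vessel=rv)
        np.testing.assert_allclose(q, dp / (0.393 + rv + 0.1), rtol=1e-12)

    def test_explicit_dp_valve_override(self):
        dp = np.array([1.0, 2.0])
        dpv = np.array([0.3, 0.9])
        q = predict_flow(dp, self._fit(), r_conn=0.393, r_vessel=0.01, dp_valve=dpv)
        expected = dp / (0.393 + 0.01 + eval_valve_resistance(TD1, dpv))
        np.testing.assert_allclose(q, expected, rtol=1e-12)


class TestOpeningThreshold:
    def test_td1_value(self):
        # high-precision evaluation: ln(1.54e4 / (0.05*0.088)) / 25.4 = 0.59324...
        assert valve_opening_threshold(TD1) == pytest.approx(0.593, abs=5e-4)

    def test_doubling_s_halves_threshold(self):
        double_s = ValveResistanceModel(TD1.r_vl, TD1.r_vh, 2 * TD1.s)
        assert valve_opening_threshold(double_s) == pytest.approx(
            valve_opening_threshold(TD1) / 2, rel=1e-12
        )

    def test_reference_mean(self, reference_models):
        thr = [valve_opening_threshold(m) for m in reference_models.values()]
        assert round(float(np.mean(thr)), 2) == 0.84

    def test_closed_form_vs_bisection_oracle(self, reference_models):
        for m in reference_models.values():
            assert valve_opening_threshold(m) == pytest.approx(
                threshold_bisection_oracle(m), abs=1e-4
            )


class TestThresholdSummary:
    def test_reference_mean_sd(self, reference_models):
        summary = threshold_summary(reference_models.values())
        assert round(summary.mean, 2) == 0.84
        assert round(summary.sd, 2) == 0.42

    def test_single_segment(self):
        summary = threshold_summary([TD1])
        assert summary.sd == 0.0
        assert summary.mean == pytest.approx(valve_opening_threshold(TD1))

    def test_identical_segments(self):
        summary = threshold_summary([TD1, TD1, TD1])
        assert summary.sd == 0.0
        assert summary.mean == pytest.approx(valve_opening_threshold(TD1))

    def test_accepts_raw_values(self):
        summary = threshold_summary([1.0, 2.0, 3.0])
        assert summary.mean == 2.0
        assert summary.sd == pytest.approx(math.sqrt(2 / 3))

    def test_empty_error(self):
        with pytest.raises(InsufficientDataError):
            threshold_summary([])

    def test_population_not_sample_convention(self, reference_models):
        thr = np.array([valve_opening_threshold(m) for m in reference_models.values()])
        summary = threshold_summary(reference_models.values())
        assert summary.sd == pytest.approx(thr.std(ddof=0))
        assert summary.sd != pytest.approx(thr.std(ddof=1))
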