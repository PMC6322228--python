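"""Cohort engine: schedules, life table, calibration, conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

import nimargin as nm
from nimargin.cohort_model import build_schedule


class TestSchedule:
    @pytest.mark.parametrize(
        "interval,stop,expected",
        [
            (10.0, 75.0, (60.0, 70.0)),
            (5.0, 75.0, (55.0, 60.0, 65.0, 70.0, 75.0)),
            (5.0, 52.0, ()),
        ],
    )
    def test_exam_ages(self, interval, stop, expected):
        s = nm.SurveillanceStrategy(start_age=50, interval=interval, stop_age=stop)
        assert build_schedule(s) == expected

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValidationError, match="interval"):
            nm.SurveillanceStrategy(interval=-5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        start=st.floats(30, 70),
        interval=st.floats(0.5, 15),
        extra=st.floats(0, 40),
    )
    def test_schedule_properties(self, start, interval, extra):
        s = nm.SurveillanceStrategy(start_age=start, interval=interval, stop_age=start + extra)
        ages = build_schedule(s)
        assert list(ages) == sorted(set(ages))
        for a in ages:
            assert start < a <= s.stop_age + 1e-9
        if ages:
            diffs = np.diff(ages)
            assert np.allclose(diffs, interval)


class TestLifeTable:
    def test_zero_hazard_gives_zero_probabilities(self):
        lt = nm.build_life_table(nm.LifeTableParams(gompertz_a=0.0))
        assert (lt == 0).all()

    def test_gompertz_probabilities_nondecreasing(self):
        lt = nm.build_life_table(nm.LifeTableParams())
        assert (np.diff(lt.to_numpy()) >= 0).all()
        assert ((lt >= 0) & (lt < 1)).all()

    def test_negative_hazard_rejected(self):
        with pytest.raises(ValidationError):
            nm.LifeTableParams(gompertz_a=-0.01)

    def test_life_expectancy_matches_quadrature(self):
        """Table-based LE vs fine-grid quadrature of exp(-cumulative hazard)."""
        params = nm.LifeTableParams()
        table = nm.build_life_table(params, max_age=140)
        le_table = nm.life_expectancy_from_table(table, 50)
        # independent oracle: weekly trapezoid on the continuous survival curve
        a0, b, ref = params.gompertz_a, params.gompertz_b, params.reference_age
        t = np.linspace(0.0, 90.0, 90 * 52 + 1)
        cumhaz = a0 / b * (np.exp(b * (50 + t - ref)) - np.exp(b * (50 - ref)))
        surv = np.exp(-cumhaz)
        le_oracle = np.trapezoid(surv, t)
        assert abs(le_table - le_oracle) < 0.1

    def test_tabulated_model_roundtrip(self):
        base = nm.build_life_table(nm.LifeTableParams(), min_age=50, max_age=110)
        tab = nm.LifeTableParams(
            model="tabulated",
            table=tuple((float(a), float(q)) for a, q in base.items()),
        )
        le_g = nm.life_expectancy_from_table(base, 50)
        le_t = nm.life_expectancy_from_table(nm.build_life_table(tab, 50, 110), 50)
        assert abs(le_g - le_t) < 1e-9


def _oracle_cumulative_incidence(psi, strategy, nh, life, fatal_per_exam, horizon_years):
    """Independent scalar-loop cohort recursion (no shared code with the
    vectorised engine): cumulative diagnoses among competing mortality."""
    delta = nh.cycle_length
    n = int(round(horizon_years / delta))
    exam_ages = []
    k = 1
    while strategy.start_age + k * strategy.interval <= strategy.stop_age + 1e-9:
        exam_ages.append(strategy.start_age + k * strategy.interval)
        k += 1
    exam_idx = {int(round((e - strategy.start_age) / delta)) for e in exam_ages}
    s, cum = 1.0, 0.0
    for i in range(n):
        age0 = strategy.start_age + i * delta
        mid = age0 + delta / 2.0
        if i in exam_idx:
            s *= 1.0 - fatal_per_exam
        factor = 1.0
        for j, e in enumerate(exam_ages):
            until = exam_ages[j + 1] if j + 1 < len(exam_ages) else e + strategy.interval
            if e - 1e-9 <= age0 < until - 1e-9:
                factor = 1.0 - nh.per_exam_protection * nh.sensitivity_multiplier
        mu_b = life.gompertz_a * math.exp(life.gompertz_b * (mid - life.reference_age))
        h = psi * factor * nh.baseline_hazard_at_ref * 2.0 ** ((mid - nh.reference_age) / nh.baseline_doubling_years)
        lam = h + mu_b
        surv = math.exp(-lam * delta)
        if lam > 0:
            cum += s * (1.0 - surv) * h / lam
        s *= surv
    return cum


class TestCalibration:
    def test_fixed_point_is_one(self, scenario):
        """Target set to the un-multiplied model's own incidence gives psi = 1."""
        nh, life, strat = scenario.nh, scenario.life, scenario.standard
        own = nm.run_arm(strat, nh, life, 0.0, psi=1.0).cumulative_incidence(nh.horizon_years)
        psi = nm.calibrate_hazard_multiplier(nh, life, strat, own)
        assert psi == pytest.approx(1.0, abs=1e-8)

    def test_target_zero_gives_zero(self, scenario):
        assert nm.calibrate_hazard_multiplier(scenario.nh, scenario.life,
                                              scenario.standard, 0.0) == 0.0

    def test_against_independent_recursion(self, scenario):
        """Calibrated multiplier reproduces 0.015 in an independent
        scalar-loop cohort recursion to 1e-6."""
        nh, life, strat = scenario.nh, scenario.life, scenario.alternative
        fatal = scenario.burden.fatal_per_exam
        psi = nm.calibrate_hazard_multiplier(nh, life, strat, 0.015, fatal)
        achieved = _oracle_cumulative_incidence(psi, strat, nh, life, fatal, nh.horizon_years)
        assert achieved == pytest.approx(0.015, abs=1e-6)

    @pytest.mark.parametrize("target", [0.005, 0.010, 0.015, 0.020])
    def test_achieved_incidence_matches_target(self, scenario, target):
        trace = nm.run_arm(scenario.alternative, scenario.nh, scenario.life, target,
                           fatal_complication_per_exam=scenario.burden.fatal_per_exam)
        assert abs(trace.cumulative_incidence(scenario.nh.horizon_years) - target) < 1e-6

    def test_unreachable_target_reports_range(self, scenario):
        nh = scenario.nh.model_copy(update={"baseline_hazard_at_ref": 0.0})
        with pytest.raises(nm.CalibrationError, match="achievable"):
            nm.calibrate_hazard_multiplier(nh, scenario.life, scenario.standard, 0.01)


class TestRunArm:
    def test_conservation(self, std_trace):
        assert np.max(np.abs(std_trace.state_sums() - 1.0)) < 1e-12

    def test_no_cancer_matches_pure_life_table(self, scenario):
        """target_p = 0 with zero background CRC hazard: person-years
        equal the bare life-table expectancy over the model horizon."""
        nh = scenario.nh.model_copy(update={"baseline_hazard_at_ref": 0.0})
        trace = nm.run_arm(scenario.standard, nh, scenario.life, 0.0)
        a0, b, ref = (scenario.life.gompertz_a, scenario.life.gompertz_b,
                      scenario.life.reference_age)
        t = np.linspace(0.0, nh.horizon_age - 50.0, 50 * 52 + 1)
        cumhaz = a0 / b * (np.exp(b * (50 + t - ref)) - np.exp(b * (50 - ref)))
        le = np.trapezoid(np.exp(-cumhaz), t)
        assert trace.life_years == pytest.approx(le, abs=0.01)

    def test_life_years_nonincreasing_in_target(self, scenario):
        lys = []
        for p in [0.005, 0.010, 0.015, 0.020]:
            tr = nm.run_arm(scenario.alternative, scenario.nh, scenario.life, p,
                            fatal_complication_per_exam=scenario.burden.fatal_per_exam)
            lys.append(tr.life_years)
        assert all(a >= b for a, b in zip(lys, lys[1:]))

    def test_no_protection_no_fatality_gives_identical_event_streams(self, scenario):
        """With rho*eps = 0 and no fatal complications the arms share the
        same cancer dynamics; exams differ only in burden."""
        nh = scenario.nh.model_copy(update={"per_exam_protection": 0.0})
        tr_s = nm.run_arm(scenario.standard, nh, scenario.life, 0.01)
        tr_a = nm.run_arm(scenario.alternative, nh, scenario.life, 0.01)
        np.testing.assert_allclose(tr_s.new_diagnoses, tr_a.new_diagnoses, atol=1e-12)
        assert tr_s.life_years == pytest.approx(tr_a.life_years, abs=1e-10)

    def test_fatal_complications_separate_life_years(self, scenario):
        """Same calibrated incidence, but the arm with more exams loses
        life-years through fatal complications."""
        nh = scenario.nh.model_copy(update={"per_exam_protection": 0.0})
        fatal = 1e-3  # exaggerated to make the effect visible
        tr_s = nm.run_arm(scenario.standard, nh, scenario.life, 0.01,
                          fatal_complication_per_exam=fatal)
        tr_a = nm.run_arm(scenario.alternative, nh, scenario.life, 0.01,
                          fatal_complication_per_exam=fatal)
        assert tr_s.cumulative_incidence(10) == pytest.approx(
            tr_a.cumulative_incidence(10), abs=1e-8)
        assert tr_s.life_years < tr_a.life_years
        assert tr_s.dead_complication[-1] > tr_a.dead_complication[-1]

    def test_misaligned_exam_age_raises(self, scenario):
        strat = nm.SurveillanceStrategy(start_age=50, interval=5.03, stop_age=75)
        with pytest.raises(nm.ConfigurationError, match="align"):
            nm.run_arm(strat, scenario.nh, scenario.life, 0.01)

    def test_trace_export_is_tidy(self, std_trace):
        df = std_trace.to_frame(tidy=True)
        assert set(df.columns) == {"cycle", "age", "compartment", "value"}
        assert len(df) == 13 * std_trace.n_cycles
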