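"""Pump duty-flow map, bucket-test calibration, OLS correction fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mockloop.errors import DegenerateDesignError, DomainError, RangeError
from mockloop.pump import (
    CalibrationTrial,
    PumpModel,
    bucket_test,
    duty_for_flow,
    exact_duty_for_flow,
    fit_linear_calibration,
    flow_for_duty,
    pump_max_flow,
    schedule_duties,
    verify_constant_flow,
)
from mockloop.waveforms import StepSchedule, time_weighted_average


class TestFlowForDuty:
    def test_deadband_gives_zero(self, pump):
        assert flow_for_duty(pump, pump.deadband_duty) == 0.0
        assert flow_for_duty(pump, 0) == 0.0

    def test_full_duty_reaches_six_lpm(self, calibrated_pump):
        assert flow_for_duty(calibrated_pump, 255) == pytest.approx(6.0)

    def test_paper_style_correction_applied(self):
        pump = PumpModel(correction_slope=1.012, correction_intercept=-0.0423)
        # raw flow 3.0 at duty 155
        assert flow_for_duty(pump, 155) == pytest.approx(1.012 * 3.0 - 0.0423)

    @pytest.mark.parametrize("bad", [-1, 256, 1000])
    def test_out_of_range_duty_rejected(self, pump, bad):
        with pytest.raises(DomainError):
            flow_for_duty(pump, bad)

    def test_negative_corrected_flow_floored(self):
        pump = PumpModel(correction_slope=1.0, correction_intercept=-10.0)
        assert flow_for_duty(pump, 100) == 0.0


class TestDutyForFlow:
    def test_zero_flow_maps_to_zero_duty(self, pump):
        assert duty_for_flow(pump, 0.0) == 0

    def test_six_lpm_maps_to_full_duty(self, calibrated_pump):
        assert duty_for_flow(calibrated_pump, 6.0) == 255

    def test_unreachable_flow_names_maximum(self, calibrated_pump):
        with pytest.raises(RangeError, match="6"):
            duty_for_flow(calibrated_pump, 7.5)

    def test_negative_flow_rejected(self, pump):
        with pytest.raises(DomainError):
            duty_for_flow(pump, -0.1)

    @given(flow=st.floats(min_value=0.05, max_value=6.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_within_half_gain(self, flow):
        pump = PumpModel()
        recovered = flow_for_duty(pump, duty_for_flow(pump, flow))
        assert abs(recovered - flow) <= pump.gain / 2 + 1e-12

    @given(duty=st.integers(min_value=56, max_value=255))
    @settings(max_examples=100, deadline=None)
    def test_inverse_composition_within_one_count(self, duty):
        pump = PumpModel()
        assert abs(duty_for_flow(pump, flow_for_duty(pump, duty)) - duty) <= 1


class TestBucketTest:
    def test_noiseless_returns_true_flow(self, calibrated_pump):
        duty = exact_duty_for_flow(calibrated_pump, 3.0)
        assert bucket_test(calibrated_pump, duty, timing_sd=0.0) == pytest.approx(3.0)

    def test_deadband_duty_raises_no_flow(self, pump):
        with pytest.raises(DomainError, match="no flow"):
            bucket_test(pump, pump.deadband_duty)

    def test_seed_reproducibility(self, calibrated_pump):
        duty = exact_duty_for_flow(calibrated_pump, 4.0)
        a = bucket_test(calibrated_pump, duty, timing_sd=0.2, seed=7)
        b = bucket_test(calibrated_pump, duty, timing_sd=0.2, seed=7)
        c = bucket_test(calibrated_pump, duty, timing_sd=0.2, seed=8)
        assert a == b
        assert a != c

    def test_invalid_parameters_rejected(self, pump):
        with pytest.raises(DomainError):
            bucket_test(pump, 200, mark_volume=0.0)
        with pytest.raises(DomainError):
            bucket_test(pump, 200, timing_sd=-0.1)


class TestFitLinearCalibration:
    def test_identity_line(self):
        trials = [CalibrationTrial(set_flow=x, measured_flow=x) for x in (3, 4, 5, 6)]
        fit = fit_linear_calibration(trials)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_recovers_constructed_affine_line(self):
        # points built exactly on measured = 1.012*set - 0.0423
        trials = [
            CalibrationTrial(set_flow=x, measured_flow=1.012 * x - 0.0423)
            for x in (3.0, 4.0, 5.0, 6.0)
        ]
        fit = fit_linear_calibration(trials)
        assert fit.slope == pytest.approx(1.012, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.0423, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_always_perfect_fit(self):
        trials = [
            CalibrationTrial(set_flow=3, measured_flow=2.8),
            CalibrationTrial(set_flow=6, measured_flow=6.4),
        ]
        assert fit_linear_calibration(trials).r_squared == pytest.approx(1.0)

    def test_degenerate_design_rejected(self):
        same = [CalibrationTrial(set_flow=3, measured_flow=3.1)] * 3
        with pytest.raises(DegenerateDesignError):
            fit_linear_calibration(same)
        with pytest.raises(DegenerateDesignError):
            fit_linear_calibration(same[:1])

    @given(
        slope=st.floats(min_value=0.5, max_value=1.5),
        intercept=st.floats(min_value=-0.5, max_value=0.5),
    )
    @settings(max_examples=60, deadline=None)
    def test_parameter_recovery_from_noiseless_trials(self, slope, intercept):
        """OLS recovers a known (a, b) exactly from noiseless trials."""
        trials = [
            CalibrationTrial(set_flow=x, measured_flow=slope * x + intercept)
            for x in (3.0, 4.0, 5.0, 6.0)
            if slope * x + intercept > 0
        ]
        if len({t.set_flow for t in trials}) < 2:
            return
        fit = fit_linear_calibration(trials)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)


class TestVerifyConstantFlow:
    def test_noiseless_calibrated_pump_is_identity(self, calibrated_pump):
        res = verify_constant_flow(
            calibrated_pump, [3.0, 4.0, 5.0, 6.0], timing_sd=0.0
        )
        assert res.summary.slope == pytest.approx(1.0, abs=1e-12)
        assert res.summary.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.summary.r_squared == pytest.approx(1.0)
        assert len(res.trials) == 12

    def test_noisy_slope_stays_near_unity(self, calibrated_pump):
        res = verify_constant_flow(
            calibrated_pump, [3.0, 4.0, 5.0, 6.0], trials_per_point=3,
            timing_sd=0.1, seed=42,
        )
        assert 0.95 <= res.summary.slope <= 1.05

    def test_noise_convergence_with_more_trials(self, calibrated_pump):
        few = verify_constant_flow(
            calibrated_pump, [3.0, 4.0, 5.0, 6.0], trials_per_point=3,
            timing_sd=0.3, seed=5,
        )
        many = verify_constant_flow(
            calibrated_pump, [3.0, 4.0, 5.0, 6.0], trials_per_point=30,
            timing_sd=0.3, seed=5,
        )
        assert abs(many.summary.slope - 1.0) <= abs(few.summary.slope - 1.0) + 0.02

    def test_single_setpoint_degenerate(self, calibrated_pump):
        with pytest.raises(DegenerateDesignError):
            verify_constant_flow(calibrated_pump, [3.0], timing_sd=0.0)

    def test_empty_setpoints_rejected(self, calibrated_pump):
        with pytest.raises(DomainError):
            verify_constant_flow(calibrated_pump, [])

    def test_seed_changes_results(self, calibrated_pump):
        a = verify_constant_flow(calibrated_pump, [3.0, 6.0], seed=1)
        b = verify_constant_flow(calibrated_pump, [3.0, 6.0], seed=1)
        c = verify_constant_flow(calibrated_pump, [3.0, 6.0], seed=2)
        assert a.summary == b.summary
        assert a.summary != c.summary


class TestScheduleDuties:
    def test_constant_schedule_constant_duty(self, calibrated_pump):
        sched = StepSchedule(durations=np.full(4, 0.25), flows=np.full(4, 3.0))
        duties = schedule_duties(calibrated_pump, sched)
        assert all(d == duty_for_flow(calibrated_pump, 3.0) for _, d in duties)

    def test_zero_schedule_zero_duties(self, calibrated_pump):
        sched = StepSchedule(durations=np.full(4, 0.25), flows=np.zeros(4))
        assert all(d == 0 for _, d in schedule_duties(calibrated_pump, sched))

    def test_reconstructed_twa_within_half_gain(self, calibrated_pump, default_schedule):
        duties = schedule_duties(calibrated_pump, default_schedule)
        flows = np.array([flow_for_duty(calibrated_pump, d) for _, d in duties])
        recon = StepSchedule(durations=default_schedule.durations, flows=flows)
        assert abs(
            time_weighted_average(recon) - time_weighted_average(default_schedule)
        ) <= calibrated_pump.gain / 2

    def test_unreachable_step_rejected(self, calibrated_pump):
        sched = StepSchedule(durations=np.array([1.0]), flows=np.array([9.0]))
        with pytest.raises(RangeError):
            schedule_duties(calibrated_pump, sched)


def test_pump_max_flow(calibrated_pump):
    assert pump_max_flow(calibrated_pump) == pytest.approx(6.0)
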