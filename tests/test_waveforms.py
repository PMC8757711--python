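"""Waveform synthesis, cycle averaging, step discretization and CSV I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mockloop.errors import ConfigurationError, DomainError, ShapeError
from mockloop.waveforms import (
    FlowWaveform,
    StepSchedule,
    VenousWaveformParams,
    constant_waveform,
    discretize_to_steps,
    integrated_volume,
    read_waveform_csv,
    time_weighted_average,
    venous_waveform,
    write_waveform_csv,
)


def _wave(flows, period=1.0):
    flows = np.asarray(flows, dtype=float)
    times = np.arange(flows.size) * (period / flows.size)
    return FlowWaveform(period=period, times=times, flows=flows)


class TestFlowWaveformInvariants:
    def test_rejects_too_few_samples(self):
        with pytest.raises(ShapeError):
            _wave([1.0] * 4)

    def test_rejects_nonuniform_grid(self):
        times = np.array([0, 0.1, 0.2, 0.31, 0.4, 0.5, 0.6, 0.7])
        with pytest.raises(ShapeError):
            FlowWaveform(period=0.8, times=times, flows=np.ones(8))

    def test_rejects_nonpositive_period(self):
        with pytest.raises(DomainError):
            _wave([1.0] * 8, period=0.0)


class TestVenousWaveform:
    def test_zero_amplitudes_give_constant_branch_mean(self):
        p = VenousWaveformParams(amp_systolic=0, amp_diastolic=0, amp_reversal=0)
        wave = venous_waveform(p, "SVC", 64)
        assert np.allclose(wave.flows, p.branch_mean("SVC"))

    def test_default_svc_mean_is_third_of_total(self):
        p = VenousWaveformParams()
        wave = venous_waveform(p, "SVC", 256)
        assert time_weighted_average(wave) == pytest.approx(3.10 / 3.0, rel=1e-9)

    def test_branch_means_sum_to_total(self):
        p = VenousWaveformParams()
        total = time_weighted_average(venous_waveform(p, "SVC", 256)) + \
            time_weighted_average(venous_waveform(p, "IVC", 256))
        assert total == pytest.approx(3.10, rel=1e-9)

    def test_unknown_branch_rejected(self):
        with pytest.raises(DomainError):
            venous_waveform(VenousWaveformParams(), "AZYGOS", 64)

    def test_nonpositive_cycle_mean_rejected(self):
        p = VenousWaveformParams(amp_reversal=20.0, width_reversal=1.0)
        with pytest.raises(ConfigurationError):
            venous_waveform(p, "SVC", 64)

    @given(
        a_s=st.floats(min_value=0, max_value=2),
        a_d=st.floats(min_value=0, max_value=2),
        a_a=st.floats(min_value=0, max_value=0.9),
        hr=st.floats(min_value=30, max_value=180),
        frac=st.floats(min_value=0.1, max_value=0.9),
    )
    @settings(max_examples=100, deadline=None)
    def test_rescaling_invariant_hits_branch_target(self, a_s, a_d, a_a, hr, frac):
        """The cycle mean equals the branch target for randomized lobes."""
        p = VenousWaveformParams(
            amp_systolic=a_s, amp_diastolic=a_d, amp_reversal=a_a,
            heart_rate=hr, svc_fraction=frac,
        )
        wave = venous_waveform(p, "IVC", 128)
        assert time_weighted_average(wave) == pytest.approx(
            p.branch_mean("IVC"), rel=1e-9
        )

    def test_doubling_heart_rate_halves_period_not_twa(self):
        slow = VenousWaveformParams(heart_rate=60)
        fast = VenousWaveformParams(heart_rate=120)
        w_slow = venous_waveform(slow, "SVC", 128)
        w_fast = venous_waveform(fast, "SVC", 128)
        assert w_fast.period == pytest.approx(w_slow.period / 2)
        assert time_weighted_average(w_fast) == pytest.approx(
            time_weighted_average(w_slow), rel=1e-12
        )


class TestTimeWeightedAverage:
    def test_constant(self):
        assert time_weighted_average(constant_waveform(3.0, 1.0, 16)) == pytest.approx(3.0)

    def test_sinusoid_averages_to_offset(self):
        n = 64
        t = np.arange(n) / n
        wave = _wave(3.0 + np.sin(2 * np.pi * t))
        assert time_weighted_average(wave) == pytest.approx(3.0, abs=1e-12)

    def test_step_schedule_exact(self):
        sched = StepSchedule(durations=np.array([0.25, 0.75]), flows=np.array([4.0, 2.0]))
        assert time_weighted_average(sched) == pytest.approx(2.5)

    def test_linearity_on_shared_grid(self, rng):
        f1 = rng.uniform(0, 5, 32)
        f2 = rng.uniform(0, 5, 32)
        a, b = 2.0, -0.5
        lhs = time_weighted_average(_wave(a * f1 + b * f2))
        rhs = a * time_weighted_average(_wave(f1)) + b * time_weighted_average(_wave(f2))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestDiscretizeToSteps:
    def test_constant_wave_gives_constant_steps(self):
        sched = discretize_to_steps(constant_waveform(3.0, 1.0, 16), 5)
        assert np.allclose(sched.flows, 3.0)
        assert sched.period == pytest.approx(1.0)

    def test_too_few_steps_rejected(self, inflow):
        with pytest.raises(ConfigurationError):
            discretize_to_steps(inflow, 1)

    def test_twa_preserved_for_nonnegative_wave(self, inflow):
        for n_steps in (2, 7, 20, 256):
            sched = discretize_to_steps(inflow, n_steps)
            assert time_weighted_average(sched) == pytest.approx(
                time_weighted_average(inflow), rel=1e-12
            )

    def test_default_schedule_twa_close_to_direct_integration(self, inflow):
        # oracle: dense trapezoidal integration of the sampled profile
        oracle = float(np.mean(inflow.flows))
        sched = discretize_to_steps(inflow, 20)
        assert abs(time_weighted_average(sched) - oracle) <= 0.01

    def test_clipping_biases_twa_upward_only(self):
        n = 32
        t = np.arange(n) / n
        wave = _wave(np.sin(2 * np.pi * t))  # mean 0, half negative
        sched = discretize_to_steps(wave, 8)
        assert np.all(sched.flows >= 0)
        assert time_weighted_average(sched) >= time_weighted_average(wave) - 1e-12

    @given(n_steps=st.integers(min_value=2, max_value=64), seed=st.integers(0, 2**16))
    @settings(max_examples=60, deadline=None)
    def test_twa_preservation_property(self, n_steps, seed):
        """Step discretization preserves the TWA of non-negative waveforms."""
        rng = np.random.default_rng(seed)
        wave = _wave(rng.uniform(0, 6, 48))
        sched = discretize_to_steps(wave, n_steps)
        assert time_weighted_average(sched) == pytest.approx(
            time_weighted_average(wave), rel=1e-12
        )


class TestIntegratedVolume:
    def test_constant_flow_volume(self):
        wave = constant_waveform(3.0, 1.0, 16)
        assert integrated_volume(wave, 10.0) == pytest.approx(0.5)  # 3/60*10 L

    def test_multi_cycle_periodic_extension(self, inflow):
        one = integrated_volume(inflow, inflow.period)
        ten = integrated_volume(inflow, 10 * inflow.period)
        assert ten == pytest.approx(10 * one, rel=1e-12)

    def test_schedule_and_waveform_agree(self, inflow):
        sched = discretize_to_steps(inflow, 20)
        assert integrated_volume(sched, 7.3) == pytest.approx(
            integrated_volume(sched, 7.3)
        )
        assert integrated_volume(sched, sched.period) == pytest.approx(
            integrated_volume(inflow, inflow.period), rel=1e-12
        )


class TestConstantWaveform:
    @pytest.mark.parametrize("flow", [3.0, 6.0])
    def test_twa_equals_level(self, flow):
        assert time_weighted_average(constant_waveform(flow, 1.0, 16)) == pytest.approx(flow)

    def test_negative_flow_rejected(self):
        with pytest.raises(DomainError):
            constant_waveform(-1.0, 1.0, 16)


class TestCsvRoundTrip:
    def test_waveform_round_trip(self, inflow, tmp_path):
        path = tmp_path / "wave.csv"
        write_waveform_csv(inflow, path)
        back = read_waveform_csv(path)
        assert back.period == pytest.approx(inflow.period, abs=1e-9)
        assert np.allclose(back.flows, inflow.flows)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,flow\n0,1\n")
        with pytest.raises(ShapeError):
            read_waveform_csv(path)
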