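"""Hall-effect turbine flow-sensor model: pulse counting, calibration and
cycle-averaged flow measurement.

An in-line turbine emits pulses ("spins") in proportion to throughput volume.
The sensor model integrates the driving flow signal over a recording window,
converts the volume to an expected pulse count via ``pulses_per_liter``, adds
Gaussian count jitter, and rounds to an integer count. The inverse map
recovers L/min from a count; calibration estimates ``pulses_per_liter`` from
recordings at known flows, exactly the correction-factor procedure used to
commission the physical sensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import DomainError, ShapeError
from .waveforms import FlowWaveform, StepSchedule, integrated_volume

__all__ = [
    "TurbineSensor",
    "SensorRecording",
    "AverageFlowResult",
    "simulate_pulse_counts",
    "flow_from_counts",
    "calibrate_correction_factor",
    "measure_average_flow",
]


class TurbineSensor(BaseModel):
    """Turbine flow sensor: pulses per liter, recording window, count noise.

    The default 396 pulses/L corresponds to a nominal 6.6 Hz per L/min meter
    factor (6.6 * 60 pulses per liter); in practice the factor is obtained
    from :func:`calibrate_correction_factor`.
    """

    model_config = ConfigDict(extra="forbid")

    pulses_per_liter: float = 396.0
    window: float = 10.0  # s
    count_jitter_sd: float = 2.0  # pulses per window

    @model_validator(mode="after")
    def _check(self) -> "TurbineSensor":
        if self.pulses_per_liter <= 0:
            raise ValueError("pulses_per_liter must be > 0")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.count_jitter_sd < 0:
            raise ValueError("count_jitter_sd must be >= 0")
        return self


class SensorRecording(BaseModel):
    """One recording window: pulse count over ``window`` seconds.

    ``true_flow`` (L/min) is attached on calibration fixtures where the bench
    flow is known.
    """

    model_config = ConfigDict(extra="forbid")

    window: float  # s
    pulse_count: int
    true_flow: Optional[float] = None  # L/min

    @model_validator(mode="after")
    def _check(self) -> "SensorRecording":
        if self.pulse_count < 0:
            raise ValueError("pulse_count must be >= 0")
        return self


@dataclass(frozen=True)
class AverageFlowResult:
    """Mean and spread of repeated cycle-averaged flow readings."""

    mean: float  # L/min
    sd: float  # L/min; 0 with degenerate_sd=True when n_trials == 1
    readings: list[float]
    degenerate_sd: bool


def simulate_pulse_counts(
    sensor: TurbineSensor,
    wave: Union[FlowWaveform, StepSchedule],
    window: Optional[float] = None,
    seed: int = 0,
) -> SensorRecording:
    """Simulate the pulse count accumulated over one recording window.

    The flow signal is extended periodically; the throughput volume is its
    exact integral over the window. Count = round(pulses_per_liter * volume
    + jitter), floored at zero. Deterministic for a fixed seed.
    """
    window = sensor.window if window is None else window
    if window <= 0:
        raise DomainError(f"window must be > 0, got {window}")
    volume = integrated_volume(wave, window)  # liters
    expected = sensor.pulses_per_liter * volume
    if sensor.count_jitter_sd > 0:
        rng = np.random.default_rng(seed)
        expected = expected + rng.normal(0.0, sensor.count_jitter_sd)
    count = max(0, int(round(expected)))
    return SensorRecording(window=window, pulse_count=count)


def flow_from_counts(sensor: TurbineSensor, recording: SensorRecording) -> float:
    """Convert a pulse count over a window to L/min."""
    if recording.window <= 0:
        raise DomainError(f"recording window must be > 0, got {recording.window}")
    return 60.0 * (recording.pulse_count / recording.window) / sensor.pulses_per_liter


def calibrate_correction_factor(recordings: list[SensorRecording]) -> float:
    """Estimate pulses_per_liter from recordings at known bench flows.

    Each recording contributes ``count / (true_flow/60 * window)``; the
    returned factor is the mean over recordings (the 10-trial averaging
    procedure used on the physical sensors).
    """
    if not recordings:
        raise DomainError("need at least one recording with a known flow")
    factors = []
    for rec in recordings:
        if rec.true_flow is None or rec.true_flow <= 0:
            raise DomainError("every recording needs true_flow > 0")
        volume = rec.true_flow / 60.0 * rec.window  # liters through the window
        factors.append(rec.pulse_count / volume)
    return float(np.mean(factors))


def measure_average_flow(
    schedule: Union[StepSchedule, FlowWaveform],
    sensor: TurbineSensor,
    n_cycles: int = 10,
    n_trials: int = 3,
    seed: int = 0,
) -> AverageFlowResult:
    """Sensor-measured average flow over ``n_cycles`` pulsatile cycles.

    Each trial integrates the signal over a window of ``n_cycles * period``
    seconds and converts the (noisy, quantized) pulse count back to L/min.
    Returns the mean and sample SD across trials; a single trial yields SD 0
    with the degenerate flag set.
    """
    if n_cycles < 1:
        raise DomainError(f"n_cycles must be >= 1, got {n_cycles}")
    if n_trials < 1:
        raise DomainError(f"n_trials must be >= 1, got {n_trials}")
    window = n_cycles * schedule.period
    child_seeds = np.random.SeedSequence(seed).generate_state(n_trials)
    readings = []
    for s in child_seeds:
        rec = simulate_pulse_counts(sensor, schedule, window=window, seed=int(s))
        readings.append(flow_from_counts(sensor, rec))
    degenerate = n_trials == 1
    sd = 0.0 if degenerate else float(np.std(readings, ddof=1))
    return AverageFlowResult(
        mean=float(np.mean(readings)), sd=sd, readings=readings, degenerate_sd=degenerate
    )
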