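"""Impeller pump model, bucket-test calibration and PWM duty scheduling.

The pump is driven by an 8-bit PWM command (0-255 counts). Its physical law
is affine above a deadband: no flow up to ``deadband_duty``, then
``gain * (duty - deadband_duty)`` L/min. On top of the physical curve sits
the software *correction* — an affine map ``a * raw + b`` fitted from bench
calibration — so a perfectly calibrated pump has ``a = 1, b = 0``.

Calibration follows the bucket-test procedure: run the pump at a commanded
duty, time how long it takes to fill a marked volume, and regress measured
flow on set flow (ordinary least squares). Timing noise is Gaussian jitter on
the fill time, mirroring a hand-held stopwatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats

from .errors import DegenerateDesignError, DomainError, RangeError
from .waveforms import StepSchedule

__all__ = [
    "PumpModel",
    "CalibrationTrial",
    "RegressionSummary",
    "ConstantFlowResult",
    "flow_for_duty",
    "duty_for_flow",
    "exact_duty_for_flow",
    "pump_max_flow",
    "bucket_test",
    "fit_linear_calibration",
    "verify_constant_flow",
    "schedule_duties",
    "read_calibration_csv",
    "write_calibration_csv",
    "write_duty_schedule_csv",
]


class PumpModel(BaseModel):
    """Duty-to-flow map with deadband plus affine correction."""

    model_config = ConfigDict(extra="forbid")

    deadband_duty: int = 55
    gain: float = 0.03  # L/min per duty count
    correction_slope: float = 1.0
    correction_intercept: float = 0.0  # L/min
    max_duty: int = 255

    @model_validator(mode="after")
    def _check(self) -> "PumpModel":
        if not 0 <= self.deadband_duty < self.max_duty:
            raise ValueError("deadband_duty must lie in [0, max_duty)")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.correction_slope <= 0:
            raise ValueError("correction_slope must be > 0")
        return self


class CalibrationTrial(BaseModel):
    """One bucket-test trial: commanded set flow vs measured flow (L/min)."""

    model_config = ConfigDict(extra="forbid")

    set_flow: float
    measured_flow: float

    @model_validator(mode="after")
    def _check(self) -> "CalibrationTrial":
        if self.set_flow <= 0 or self.measured_flow <= 0:
            raise ValueError("set_flow and measured_flow must be > 0")
        return self


class RegressionSummary(BaseModel):
    """OLS fit of measured on set flow. r_squared is None when SS_tot = 0."""

    slope: float
    intercept: float  # L/min
    r_squared: float | None

    @model_validator(mode="after")
    def _check(self) -> "RegressionSummary":
        if self.r_squared is not None and self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")
        return self


@dataclass(frozen=True)
class ConstantFlowResult:
    """Outcome of the constant-flow verification battery."""

    summary: RegressionSummary
    trials: list[CalibrationTrial]


def flow_for_duty(pump: PumpModel, duty: float) -> float:
    """Delivered flow (L/min) at a PWM duty command.

    Zero at or below the deadband; otherwise the affine physical curve
    followed by the software correction, floored at zero.
    """
    if not 0 <= duty <= pump.max_duty:
        raise DomainError(f"duty must lie in [0, {pump.max_duty}], got {duty}")
    raw = 0.0 if duty <= pump.deadband_duty else pump.gain * (duty - pump.deadband_duty)
    corrected = pump.correction_slope * raw + pump.correction_intercept
    return max(0.0, corrected) if raw > 0 else 0.0


def pump_max_flow(pump: PumpModel) -> float:
    """Largest flow (L/min) the pump can deliver (duty = max_duty)."""
    return flow_for_duty(pump, pump.max_duty)


def exact_duty_for_flow(pump: PumpModel, flow: float) -> float:
    """Continuous (unquantized) duty command achieving ``flow`` exactly.

    Used by the calibration-verification path, which applies the correction
    before PWM rounding; :func:`duty_for_flow` quantizes this to a count.
    """
    if flow < 0:
        raise DomainError(f"flow must be >= 0, got {flow}")
    if flow == 0:
        return 0.0
    max_flow = pump_max_flow(pump)
    if flow > max_flow + 1e-12:
        raise RangeError(
            f"flow {flow} L/min exceeds pump maximum {max_flow:.4g} L/min"
        )
    raw = (flow - pump.correction_intercept) / pump.correction_slope
    if raw <= 0:
        return float(pump.deadband_duty)
    return min(pump.deadband_duty + raw / pump.gain, float(pump.max_duty))


def duty_for_flow(pump: PumpModel, flow: float) -> int:
    """Integer PWM duty for a target flow; inverse of :func:`flow_for_duty`
    up to rounding (within gain/2 in flow for reachable targets)."""
    if flow == 0:
        return 0
    exact = exact_duty_for_flow(pump, flow)
    return int(np.clip(round(exact), pump.deadband_duty, pump.max_duty))


def bucket_test(
    pump: PumpModel,
    duty: float,
    mark_volume: float = 1.0,
    timing_sd: float = 0.1,
    seed: int = 0,
) -> float:
    """Measure the pump's flow at a duty by timing a marked-volume fill.

    Fill time is ``mark_volume / true_flow`` plus Gaussian jitter (seconds),
    truncated to stay positive; the returned flow is ``mark_volume / time``
    in L/min. Deterministic for a fixed seed.
    """
    if mark_volume <= 0:
        raise DomainError(f"mark_volume must be > 0, got {mark_volume}")
    if timing_sd < 0:
        raise DomainError(f"timing_sd must be >= 0, got {timing_sd}")
    true_flow = flow_for_duty(pump, duty)
    if true_flow <= 0:
        raise DomainError(f"no flow at this duty ({duty}, within deadband)")
    t_true = mark_volume / true_flow * 60.0  # seconds
    if timing_sd == 0:
        return true_flow
    rng = np.random.default_rng(seed)
    t = t_true + rng.normal(0.0, timing_sd)
    while t <= 0:  # truncate: a fill time cannot be negative
        t = t_true + rng.normal(0.0, timing_sd)
    return mark_volume / t * 60.0


def fit_linear_calibration(trials: list[CalibrationTrial]) -> RegressionSummary:
    """OLS regression of measured flow on set flow across calibration trials.

    Needs at least two trials at two distinct set flows; with all set flows
    identical the design is degenerate and no line is identifiable.
    """
    if len(trials) < 2:
        raise DegenerateDesignError("need >= 2 calibration trials")
    x = np.array([t.set_flow for t in trials])
    y = np.array([t.measured_flow for t in trials])
    if np.all(x == x[0]):
        raise DegenerateDesignError(
            "all set flows identical: slope is not identifiable"
        )
    fit = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = None
    else:
        resid = y - (fit.slope * x + fit.intercept)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return RegressionSummary(slope=float(fit.slope), intercept=float(fit.intercept), r_squared=r2)


def verify_constant_flow(
    pump: PumpModel,
    setpoints: list[float],
    trials_per_point: int = 3,
    timing_sd: float = 0.1,
    seed: int = 0,
    mark_volume: float = 1.0,
) -> ConstantFlowResult:
    """Constant-flow verification: bucket-test each setpoint repeatedly and
    regress measured on set flow.

    With a calibrated pump (slope 1, intercept 0) and zero timing noise the
    fit is exactly the identity line with r^2 = 1.
    """
    if not setpoints:
        raise DomainError("setpoints must be non-empty")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(setpoints) * trials_per_point
    )
    trials: list[CalibrationTrial] = []
    i = 0
    for sp in setpoints:
        duty = exact_duty_for_flow(pump, sp)  # raises RangeError if unreachable
        for _ in range(trials_per_point):
            measured = bucket_test(
                pump, duty, mark_volume=mark_volume, timing_sd=timing_sd,
                seed=int(child_seeds[i]),
            )
            trials.append(CalibrationTrial(set_flow=sp, measured_flow=measured))
            i += 1
    return ConstantFlowResult(summary=fit_linear_calibration(trials), trials=trials)


def schedule_duties(pump: PumpModel, schedule: StepSchedule) -> list[tuple[float, int]]:
    """Map a flow step schedule to (duration s, integer PWM duty) pairs."""
    return [
        (float(d), duty_for_flow(pump, float(f)))
        for d, f in zip(schedule.durations, schedule.flows)
    ]


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def write_calibration_csv(trials: list[CalibrationTrial], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "set_flow_lpm": [t.set_flow for t in trials],
            "measured_flow_lpm": [t.measured_flow for t in trials],
        }
    ).to_csv(path, index=False)


def read_calibration_csv(path) -> list[CalibrationTrial]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        CalibrationTrial(set_flow=row.set_flow_lpm, measured_flow=row.measured_flow_lpm)
        for row in df.itertuples()
    ]


def write_duty_schedule_csv(duties: list[tuple[float, int]], path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"duration_s": [d for d, _ in duties], "duty": [u for _, u in duties]}
    ).to_csv(path, index=False)
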