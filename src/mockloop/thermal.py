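"""Lumped reservoir heating dynamics with bang-bang (sous-vide) control.

The heated reservoir is modelled as a single well-mixed thermal mass:

    m c dT/dt = P u(t) - k (T - T_ambient)

with heater power P (W), loss coefficient k (W/degC) and heater state
u in {0, 1} switched by a hysteresis controller about the 37 degC setpoint
(half the deadband above and below). Integration is explicit Euler; the step
must resolve the thermal time constant m c / k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConvergenceError, DomainError, StabilityError

__all__ = [
    "ThermalModel",
    "ThermostatController",
    "TemperatureTrace",
    "simulate_heating",
    "steady_state_temperature",
    "time_to_reach",
    "write_trace_csv",
]


class ThermalModel(BaseModel):
    """Lumped thermal parameters of the heated reservoir.

    Defaults describe the 3 L heating-test tank: a 1000 W immersion heater,
    5 W/degC ambient losses, water properties.
    """

    model_config = ConfigDict(extra="forbid")

    volume: float = 3.0  # L
    heater_power: float = 1000.0  # W
    loss_coefficient: float = 5.0  # W/degC
    ambient: float = 20.0  # degC
    specific_heat: float = 4186.0  # J/(kg degC)
    density: float = 1.0  # kg/L

    @model_validator(mode="after")
    def _check(self) -> "ThermalModel":
        for name in ("volume", "heater_power", "specific_heat", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.loss_coefficient < 0:
            raise ValueError("loss_coefficient must be >= 0")
        return self

    @property
    def heat_capacity(self) -> float:
        """Total heat capacity m*c in J/degC."""
        return self.volume * self.density * self.specific_heat

    @property
    def time_constant(self) -> float:
        """Thermal relaxation time m*c/k in seconds (inf for a lossless tank)."""
        if self.loss_coefficient == 0:
            return float("inf")
        return self.heat_capacity / self.loss_coefficient


class ThermostatController(BaseModel):
    """Bang-bang controller: heater on below setpoint - deadband/2, off above
    setpoint + deadband/2, unchanged in between (hysteresis)."""

    model_config = ConfigDict(extra="forbid")

    setpoint: float = 37.0  # degC
    deadband: float = 1.0  # degC

    @model_validator(mode="after")
    def _check(self) -> "ThermostatController":
        if self.deadband <= 0:
            raise ValueError("deadband must be > 0")
        return self


@dataclass(frozen=True)
class TemperatureTrace:
    """Sampled temperature trajectory with the heater state at each sample."""

    times: np.ndarray  # s
    temps: np.ndarray  # degC
    heater_on: np.ndarray  # bool

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.temps) == len(self.heater_on)):
            raise DomainError("trace arrays must have equal length")


def simulate_heating(
    model: ThermalModel,
    controller: ThermostatController,
    t_initial: float = 20.0,
    duration: float = 2400.0,
    dt: float = 1.0,
) -> TemperatureTrace:
    """Integrate the controlled reservoir from ``t_initial`` for ``duration``.

    Explicit Euler at step ``dt``; raises :class:`StabilityError` when ``dt``
    is not at least ten times smaller than the thermal time constant.
    """
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    if duration < dt:
        raise DomainError("duration must be >= dt")
    tau = model.time_constant
    if np.isfinite(tau) and dt >= tau / 10.0:
        raise StabilityError(
            f"dt = {dt} s too coarse for thermal time constant {tau:.1f} s"
        )
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    temps = np.empty(n + 1)
    heater = np.empty(n + 1, dtype=bool)
    temps[0] = t_initial
    lo = controller.setpoint - controller.deadband / 2.0
    hi = controller.setpoint + controller.deadband / 2.0
    u = t_initial < controller.setpoint
    mc = model.heat_capacity
    for i in range(n + 1):
        t_now = temps[i]
        if t_now < lo:
            u = True
        elif t_now > hi:
            u = False
        heater[i] = u
        if i < n:
            power = model.heater_power if u else 0.0
            dTdt = (power - model.loss_coefficient * (t_now - model.ambient)) / mc
            temps[i + 1] = t_now + dt * dTdt
    return TemperatureTrace(times=times, temps=temps, heater_on=heater)


def steady_state_temperature(
    trace: TemperatureTrace, tail_fraction: float = 0.5, flat_tol: float = 0.1
) -> float:
    """Time-averaged temperature over the final ``tail_fraction`` of a trace.

    The tail must show a settled regime: either at least two heater switch
    events (the thermostat limit cycle) or an essentially flat temperature
    (peak-to-peak <= ``flat_tol`` degC, e.g. a heater-off tank at ambient).
    Otherwise a :class:`ConvergenceError` is raised.
    """
    if not 0 < tail_fraction <= 1:
        raise DomainError("tail_fraction must lie in (0, 1]")
    n = len(trace.times)
    start = max(0, n - max(2, int(round(tail_fraction * n))))
    temps = trace.temps[start:]
    times = trace.times[start:]
    switches = int(np.sum(np.diff(trace.heater_on[start:].astype(int)) != 0))
    flat = float(np.ptp(temps)) <= flat_tol
    if switches < 2 and not flat:
        raise ConvergenceError(
            f"tail shows {switches} switch events and is not flat: "
            "no limit cycle reached; extend the simulation"
        )
    return float(np.trapezoid(temps, times) / (times[-1] - times[0]))


def time_to_reach(trace: TemperatureTrace, threshold: float) -> float:
    """First time (s) the trace reaches ``threshold`` degC, by linear
    interpolation between samples; raises if never reached."""
    above = np.nonzero(trace.temps >= threshold)[0]
    if above.size == 0:
        raise ConvergenceError(f"trace never reaches {threshold} degC")
    i = int(above[0])
    if i == 0:
        return float(trace.times[0])
    t0, t1 = trace.times[i - 1], trace.times[i]
    y0, y1 = trace.temps[i - 1], trace.temps[i]
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def write_trace_csv(trace: TemperatureTrace, path) -> None:
    """Write a temperature trace as ``time_s,temp_c`` CSV."""
    pd.DataFrame({"time_s": trace.times, "temp_c": trace.temps}).to_csv(
        path, index=False
    )
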