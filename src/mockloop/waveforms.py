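"""Pulsatile venous waveform synthesis, cycle averaging and step discretization.

The loop drives its pump from one period of a venous flow profile. This module
owns the two exchange types — :class:`FlowWaveform` (a uniformly sampled
period of flow in L/min) and :class:`StepSchedule` (the piecewise-constant
command sequence actually sent to the pump) — together with the parametric
superior/inferior vena cava (SVC/IVC) waveform family, the time-weighted
average (TWA) statistic used to validate pulsatile flow, and the exact
periodic integrator that links them.

The venous waveform family is a biphasic pattern built from raised-cosine
lobes: a systolic lobe, a diastolic lobe and an atrial-reversal dip riding on
a constant base. The profile is rescaled multiplicatively so that its cycle
mean hits the branch target exactly — the SVC carries ``svc_fraction`` of the
total venous return and the IVC the remainder, so the two branch means always
sum to the configured total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError, DomainError, ShapeError

__all__ = [
    "FlowWaveform",
    "StepSchedule",
    "VenousWaveformParams",
    "Branch",
    "venous_waveform",
    "constant_waveform",
    "time_weighted_average",
    "discretize_to_steps",
    "integrated_volume",
    "read_waveform_csv",
    "write_waveform_csv",
    "write_schedule_csv",
]

Branch = Literal["SVC", "IVC"]

_GRID_TOL = 1e-9  # uniform-spacing tolerance, seconds


@dataclass(frozen=True)
class FlowWaveform:
    """One period of a flow signal on a uniform time grid.

    Parameters
    ----------
    period
        Cycle length in seconds, > 0.
    times
        Sample times in seconds, uniformly spaced on [0, period).
    flows
        Flow rate in L/min at each sample time.
    """

    period: float
    times: np.ndarray
    flows: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        flows = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "flows", flows)
        if not self.period > 0:
            raise DomainError(f"period must be > 0, got {self.period}")
        if times.ndim != 1 or flows.shape != times.shape:
            raise ShapeError("times and flows must be 1-D arrays of equal length")
        n = times.size
        if n < 8:
            raise ShapeError(f"a waveform needs >= 8 samples, got {n}")
        dt = self.period / n
        expected = np.arange(n) * dt
        if not np.allclose(times, expected, rtol=0.0, atol=_GRID_TOL):
            raise ShapeError(
                "times must be uniformly spaced on [0, period) starting at 0"
            )

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return self.period / self.n_samples

    def same_grid(self, other: "FlowWaveform") -> bool:
        return (
            self.n_samples == other.n_samples
            and abs(self.period - other.period) <= _GRID_TOL
        )


@dataclass(frozen=True)
class StepSchedule:
    """Piecewise-constant flow command: ordered (duration s, flow L/min) steps.

    Durations must be positive and flows non-negative (the impeller pump is
    unidirectional); the total duration is the schedule's period.
    """

    durations: np.ndarray
    flows: np.ndarray

    def __post_init__(self) -> None:
        durations = np.asarray(self.durations, dtype=float)
        flows = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "flows", flows)
        if durations.ndim != 1 or flows.shape != durations.shape:
            raise ShapeError("durations and flows must be 1-D arrays of equal length")
        if durations.size == 0:
            raise ShapeError("a step schedule needs at least one step")
        if np.any(durations <= 0):
            raise DomainError("all step durations must be > 0")
        if np.any(flows < 0):
            raise DomainError("step flows must be >= 0")

    @property
    def period(self) -> float:
        return float(self.durations.sum())

    @property
    def steps(self) -> list[tuple[float, float]]:
        return list(zip(self.durations.tolist(), self.flows.tolist()))


class VenousWaveformParams(BaseModel):
    """Parameters of the biphasic venous waveform family.

    Lobe centers and widths are fractions of the period; amplitudes are
    dimensionless multiples of the base flow. Defaults describe a resting
    adult: 60 bpm, 3.10 L/min total venous return, an SVC:IVC split of 1:2,
    systolic and diastolic forward lobes and a small atrial-reversal dip.
    """

    model_config = ConfigDict(extra="forbid")

    heart_rate: float = 60.0  # bpm
    mean_total: float = 3.10  # L/min, cycle-mean of SVC + IVC
    svc_fraction: float = 1.0 / 3.0
    amp_systolic: float = 0.8
    amp_diastolic: float = 0.5
    amp_reversal: float = 0.3
    center_systolic: float = 0.25
    width_systolic: float = 0.25
    center_diastolic: float = 0.65
    width_diastolic: float = 0.25
    center_reversal: float = 0.95
    width_reversal: float = 0.15

    @model_validator(mode="after")
    def _check(self) -> "VenousWaveformParams":
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")
        if self.mean_total <= 0:
            raise ValueError("mean_total must be > 0")
        if not 0.0 < self.svc_fraction < 1.0:
            raise ValueError("svc_fraction must lie in (0, 1)")
        for name in ("amp_systolic", "amp_diastolic", "amp_reversal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "width_systolic",
            "width_diastolic",
            "width_reversal",
            "center_systolic",
            "center_diastolic",
            "center_reversal",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        return self

    @property
    def period(self) -> float:
        """Cycle length in seconds."""
        return 60.0 / self.heart_rate

    def branch_mean(self, branch: Branch) -> float:
        """Target cycle-mean flow (L/min) for one branch."""
        frac = self.svc_fraction if branch == "SVC" else 1.0 - self.svc_fraction
        return frac * self.mean_total


def _raised_cosine(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    # periodic raised-cosine lobe on |phase - center| <= width/2 (phase in [0,1))
    d = np.mod(phase - center + 0.5, 1.0) - 0.5
    lobe = 0.5 * (1.0 + np.cos(2.0 * np.pi * d / width))
    return np.where(np.abs(d) <= width / 2.0, lobe, 0.0)


def venous_waveform(
    params: VenousWaveformParams, branch: Branch, n_samples: int = 256
) -> FlowWaveform:
    """Synthesize one period of the SVC or IVC flow profile.

    The raw shape is ``1 + a_S*c_S + a_D*c_D - a_A*c_A`` with raised-cosine
    lobes ``c``; it is then rescaled multiplicatively so the trapezoidal cycle
    mean equals the branch target exactly.

    Raises
    ------
    ConfigurationError
        If the lobe parameters produce a non-positive cycle mean.
    """
    if n_samples < 8:
        raise ShapeError(f"n_samples must be >= 8, got {n_samples}")
    if branch not in ("SVC", "IVC"):
        raise DomainError(f"branch must be 'SVC' or 'IVC', got {branch!r}")
    period = params.period
    times = np.arange(n_samples) * (period / n_samples)
    phase = times / period
    shape = (
        1.0
        + params.amp_systolic
        * _raised_cosine(phase, params.center_systolic, params.width_systolic)
        + params.amp_diastolic
        * _raised_cosine(phase, params.center_diastolic, params.width_diastolic)
        - params.amp_reversal
        * _raised_cosine(phase, params.center_reversal, params.width_reversal)
    )
    mean_shape = float(np.mean(shape))  # trapezoidal mean with periodic closure
    if mean_shape <= 0:
        raise ConfigurationError(
            f"lobe parameters give a non-positive cycle mean ({mean_shape:.4g})"
        )
    flows = (params.branch_mean(branch) / mean_shape) * shape
    return FlowWaveform(period=period, times=times, flows=flows)


def constant_waveform(flow: float, period: float = 1.0, n_samples: int = 16) -> FlowWaveform:
    """A flat waveform at ``flow`` L/min (constant-flow operating mode)."""
    if flow < 0:
        raise DomainError(f"constant flow must be >= 0, got {flow}")
    times = np.arange(n_samples) * (period / n_samples)
    return FlowWaveform(period=period, times=times, flows=np.full(n_samples, float(flow)))


# ---------------------------------------------------------------------------
# Exact integration of the periodic piecewise-linear interpolant
# ---------------------------------------------------------------------------

def _cumulative_lpm_seconds(wave: FlowWaveform, t: float) -> float:
    """Integral of the periodic linear interpolant over [0, t], t in [0, period].

    Units: (L/min)·s. Exact up to float rounding, so step discretization and
    sensor volumes inherit the waveform's trapezoidal TWA analytically.
    """
    n = wave.n_samples
    dt = wave.dt
    f = wave.flows
    f_closed = np.append(f, f[0])
    seg = 0.5 * (f_closed[:-1] + f_closed[1:]) * dt
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    if t >= wave.period:
        return float(cum[-1])
    k = min(int(t // dt), n - 1)
    t_loc = t - k * dt
    f_t = f_closed[k] + (f_closed[k + 1] - f_closed[k]) * (t_loc / dt)
    return float(cum[k] + 0.5 * (f_closed[k] + f_t) * t_loc)


def _schedule_cumulative(schedule: StepSchedule, t: float) -> float:
    """Integral of the step function over [0, t], t in [0, period]; (L/min)·s."""
    edges = np.concatenate(([0.0], np.cumsum(schedule.durations)))
    cum = np.concatenate(([0.0], np.cumsum(schedule.flows * schedule.durations)))
    if t >= edges[-1]:
        return float(cum[-1])
    k = int(np.searchsorted(edges, t, side="right")) - 1
    return float(cum[k] + schedule.flows[k] * (t - edges[k]))


def integrated_volume(
    wave: Union[FlowWaveform, StepSchedule], duration: float
) -> float:
    """Fluid volume (liters) delivered over ``duration`` seconds.

    The signal is extended periodically, so the window may span any number of
    cycles (this is how a turbine sensor integrating over 10 cycles sees the
    pulsatile schedule).
    """
    if duration < 0:
        raise DomainError(f"duration must be >= 0, got {duration}")
    period = wave.period
    n_full = int(duration // period)
    remainder = duration - n_full * period
    if remainder < 0:  # float guard
        remainder = 0.0
    if isinstance(wave, FlowWaveform):
        per_cycle = _cumulative_lpm_seconds(wave, period)
        partial = _cumulative_lpm_seconds(wave, remainder)
    elif isinstance(wave, StepSchedule):
        per_cycle = _schedule_cumulative(wave, period)
        partial = _schedule_cumulative(wave, remainder)
    else:
        raise ShapeError(f"unsupported signal type {type(wave).__name__}")
    return (n_full * per_cycle + partial) / 60.0


def time_weighted_average(wave: Union[FlowWaveform, StepSchedule]) -> float:
    """Time-weighted average flow (L/min) over one cycle.

    For a waveform this is the trapezoidal mean with periodic closure (on a
    uniform grid, the arithmetic mean of the samples); for a step schedule it
    is the exact duration-weighted mean.
    """
    if isinstance(wave, FlowWaveform):
        return _cumulative_lpm_seconds(wave, wave.period) / wave.period
    if isinstance(wave, StepSchedule):
        return float(np.sum(wave.flows * wave.durations) / wave.period)
    raise ShapeError(f"unsupported signal type {type(wave).__name__}")


def discretize_to_steps(wave: FlowWaveform, n_steps: int = 20) -> StepSchedule:
    """Partition one period into ``n_steps`` equal-duration steps.

    Each step's flow is the exact mean of the waveform's linear interpolant
    over its sub-interval, clipped below at zero (the pump cannot reverse).
    For non-negative waveforms the schedule's time-weighted average equals the
    waveform's to float precision.
    """
    if n_steps < 2:
        raise ConfigurationError(f"n_steps must be >= 2, got {n_steps}")
    period = wave.period
    edges = np.linspace(0.0, period, n_steps + 1)
    cum = np.array([_cumulative_lpm_seconds(wave, t) for t in edges])
    durations = np.diff(edges)
    means = np.diff(cum) / durations
    return StepSchedule(durations=durations, flows=np.clip(means, 0.0, None))


# ---------------------------------------------------------------------------
# CSV interchange: header time_s,flow_lpm, one row per sample
# ---------------------------------------------------------------------------

def write_waveform_csv(wave: FlowWaveform, path) -> None:
    """Write a waveform as ``time_s,flow_lpm`` CSV."""
    pd.DataFrame({"time_s": wave.times, "flow_lpm": wave.flows}).to_csv(
        path, index=False
    )


def read_waveform_csv(path) -> FlowWaveform:
    """Read a ``time_s,flow_lpm`` CSV written by :func:`write_waveform_csv`.

    The period is inferred from the uniform grid as ``n * dt``.
    """
    df = pd.read_csv(path)
    missing = {"time_s", "flow_lpm"} - set(df.columns)
    if missing:
        raise ShapeError(f"waveform CSV missing columns: {sorted(missing)}")
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise ShapeError("waveform CSV needs at least 2 samples")
    dt = times[1] - times[0]
    period = times.size * dt
    return FlowWaveform(period=period, times=times, flows=df["flow_lpm"].to_numpy(dtype=float))


def write_schedule_csv(schedule: StepSchedule, path) -> None:
    """Write a step schedule as ``duration_s,flow_lpm`` CSV."""
    pd.DataFrame(
        {"duration_s": schedule.durations, "flow_lpm": schedule.flows}
    ).to_csv(path, index=False)
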