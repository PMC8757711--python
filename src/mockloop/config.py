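"""Loop configuration: one validated object covering fluid, geometry,
waveform, pump, sensors, thermal model and layout, loadable from YAML/JSON.

An empty file (or ``LoopConfig()``) yields the reference build of the loop —
the defaults documented on each component model. Unknown keys are rejected
with path-qualified messages so typos surface instead of silently falling
back to defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .anatomy import (
    FrictionMeasurement,
    HeartDimensionTable,
    LoopLayout,
    VesselTable,
    default_friction_measurements,
    default_heart_table,
    default_layout,
    default_vessel_table,
)
from .errors import ConfigurationError
from .hydraulics import FluidProperties
from .pump import PumpModel
from .sensing import TurbineSensor
from .thermal import ThermalModel, ThermostatController
from .waveforms import VenousWaveformParams

__all__ = ["LoopConfig", "load_config", "save_config"]


class LoopConfig(BaseModel):
    """Complete, validated description of the loop digital twin."""

    model_config = ConfigDict(extra="forbid")

    fluid: FluidProperties = Field(default_factory=FluidProperties)
    heart: HeartDimensionTable = Field(default_factory=default_heart_table)
    vessels: VesselTable = Field(default_factory=default_vessel_table)
    layout: LoopLayout = Field(default_factory=default_layout)
    waveform: VenousWaveformParams = Field(default_factory=VenousWaveformParams)
    pump: PumpModel = Field(default_factory=PumpModel)
    #: two in-line sensors: pump outlet and reservoir return
    sensors: List[TurbineSensor] = Field(
        default_factory=lambda: [TurbineSensor(), TurbineSensor()]
    )
    thermal: ThermalModel = Field(default_factory=ThermalModel)
    thermostat: ThermostatController = Field(default_factory=ThermostatController)
    friction_measurements: List[FrictionMeasurement] = Field(
        default_factory=default_friction_measurements
    )
    #: pump-side inlet bore feeding the SVC/IVC bifurcation (cm); results
    #: downstream of the junction are independent of it by continuity
    inlet_diameter: float = 2.0
    #: steps per cycle in the pump command schedule
    n_steps: int = 20
    #: expected access-path length, port to heart (cm)
    access_path_length: float = 80.0
    #: master seed for every stochastic section of the verification battery
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "LoopConfig":
        if len(self.sensors) != 2:
            raise ValueError(
                f"exactly two flow sensors are required (pump outlet and "
                f"reservoir return), got {len(self.sensors)}"
            )
        if self.inlet_diameter <= 0:
            raise ValueError("inlet_diameter must be > 0")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.access_path_length <= 0:
            raise ValueError("access_path_length must be > 0")
        return self

    @property
    def svc_diameter(self) -> float:
        return self.vessels.vessels["superior_vena_cava"].system_diameter

    @property
    def ivc_diameter(self) -> float:
        return self.vessels.vessels["inferior_vena_cava"].system_diameter


def load_config(path) -> LoopConfig:
    """Load and validate a YAML or JSON loop configuration.

    An empty file yields the all-defaults config; any parse failure,
    invariant violation or unknown key raises :class:`ConfigurationError`
    with the offending field path.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config {path} must be a mapping at top level")
    try:
        return LoopConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigurationError(
            f"invalid config {path}:\n  " + "\n  ".join(lines)
        ) from exc


def save_config(config: LoopConfig, path) -> None:
    """Write a config as YAML; ``load_config`` of the result is identity."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
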