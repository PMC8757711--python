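"""Tube-flow fluid dynamics: continuity across the split venous return and
Poiseuille wall shear quantities.

The loop's reservoir feeds a single pump whose outlet bifurcates into the SVC
and IVC lines; conversely, the pump command needed to realise prescribed
branch profiles follows from continuity. With cross-section ``A = pi d^2/4``,
branch velocities ``v = F/A`` combine at the junction as

    v_in = (v_svc d_svc^2 + v_ivc d_ivc^2) / d_in^2

and the inlet flow is ``F_in = v_in A_in``, which algebraically equals
``F_svc + F_ivc`` for any inlet diameter — mass conservation holds exactly
and downstream results do not depend on the (unmeasured) inlet bore.

Wall shear stress and shear rate are the straight-tube Poiseuille values
``tau_w = 4 mu F / (pi r^3)`` and ``gamma_w = 4 F / (pi r^3)``, evaluated for
a Newtonian working fluid (water by default, mu = 1.0 cP).
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import DomainError, ShapeError
from .units import cm3s_to_lpm, cp_to_poise, lpm_to_cm3s
from .waveforms import FlowWaveform

__all__ = [
    "VesselSegment",
    "FluidProperties",
    "cross_section_area",
    "velocity_from_flow",
    "flow_from_velocity",
    "combine_branch_velocities",
    "pump_inflow_profile",
    "wall_shear_stress",
    "wall_shear_rate",
]


class VesselSegment(BaseModel):
    """A straight vessel (tube) segment of the loop.

    ``anatomical_mean``/``anatomical_sd`` carry the literature diameter for
    vessels that are checked against anatomy; purely structural segments
    leave them unset.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    internal_diameter: float  # cm
    length: float = 0.0  # cm
    anatomical_mean: Optional[float] = None  # cm
    anatomical_sd: Optional[float] = None  # cm

    @model_validator(mode="after")
    def _check(self) -> "VesselSegment":
        if self.internal_diameter <= 0:
            raise ValueError(
                f"internal_diameter must be > 0, got {self.internal_diameter}"
            )
        if self.length < 0:
            raise ValueError(f"length must be >= 0, got {self.length}")
        if self.anatomical_sd is not None and self.anatomical_sd < 0:
            raise ValueError("anatomical_sd must be >= 0")
        return self

    @property
    def radius(self) -> float:
        return self.internal_diameter / 2.0

    @property
    def area(self) -> float:
        return cross_section_area(self.internal_diameter)


class FluidProperties(BaseModel):
    """Newtonian working fluid. Defaults are water at room temperature."""

    model_config = ConfigDict(extra="forbid")

    dynamic_viscosity: float = 1.0  # cP
    density: float = 1.0  # g/cm^3

    @model_validator(mode="after")
    def _check(self) -> "FluidProperties":
        if self.dynamic_viscosity <= 0:
            raise ValueError("dynamic_viscosity must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        return self


WATER = FluidProperties(dynamic_viscosity=1.0, density=1.0)


def cross_section_area(diameter: float) -> float:
    """Circular cross-section area (cm^2) from internal diameter (cm)."""
    if diameter <= 0:
        raise DomainError(f"diameter must be > 0, got {diameter}")
    return math.pi * (diameter / 2.0) ** 2


def velocity_from_flow(flow: float, area: float):
    """Mean velocity (cm/s) from volumetric flow (cm^3/s) and area (cm^2)."""
    if area <= 0:
        raise DomainError(f"area must be > 0, got {area}")
    return flow / area


def flow_from_velocity(velocity: float, area: float):
    """Volumetric flow (cm^3/s) from mean velocity (cm/s) and area (cm^2)."""
    if area <= 0:
        raise DomainError(f"area must be > 0, got {area}")
    return velocity * area


def combine_branch_velocities(
    v_svc: float, d_svc: float, v_ivc: float, d_ivc: float, d_in: float
):
    """Inlet velocity (cm/s) required to feed both venous branches.

    Continuity across the bifurcation: velocities weighted by diameter
    squared, referred to the inlet bore.
    """
    for label, d in (("d_svc", d_svc), ("d_ivc", d_ivc), ("d_in", d_in)):
        if d <= 0:
            raise DomainError(f"{label} must be > 0, got {d}")
    return (v_svc * d_svc**2 + v_ivc * d_ivc**2) / d_in**2


def pump_inflow_profile(
    svc_wave: FlowWaveform,
    ivc_wave: FlowWaveform,
    d_svc: float,
    d_ivc: float,
    d_in: float = 2.0,
) -> FlowWaveform:
    """Pump inflow waveform (L/min) feeding the given SVC/IVC branch profiles.

    Applies area/velocity continuity sample-wise on the shared grid. By
    construction every output sample equals the sum of the branch flows, so
    the result is independent of ``d_in``; the default 2.0 cm matches the
    largest loop tubing.
    """
    if not svc_wave.same_grid(ivc_wave):
        raise ShapeError("SVC and IVC waveforms must share period and grid")
    a_svc = cross_section_area(d_svc)
    a_ivc = cross_section_area(d_ivc)
    a_in = cross_section_area(d_in)
    v_svc = velocity_from_flow(lpm_to_cm3s(svc_wave.flows), a_svc)
    v_ivc = velocity_from_flow(lpm_to_cm3s(ivc_wave.flows), a_ivc)
    v_in = combine_branch_velocities(v_svc, d_svc, v_ivc, d_ivc, d_in)
    f_in = flow_from_velocity(v_in, a_in)
    return FlowWaveform(
        period=svc_wave.period, times=svc_wave.times.copy(), flows=cm3s_to_lpm(f_in)
    )


def wall_shear_stress(flow: float, radius: float, fluid: FluidProperties = WATER):
    """Poiseuille wall shear stress (dyn/cm^2) in a straight tube.

    ``flow`` in cm^3/s, ``radius`` in cm; the fluid's viscosity (cP) is
    converted to poise internally. Divide by 10 for Pa.
    """
    if radius <= 0:
        raise DomainError(f"radius must be > 0, got {radius}")
    mu = cp_to_poise(fluid.dynamic_viscosity)
    return 4.0 * mu * flow / (math.pi * radius**3)


def wall_shear_rate(flow: float, radius: float):
    """Poiseuille wall shear rate (1/s): ``4 F / (pi r^3)``."""
    if radius <= 0:
        raise DomainError(f"radius must be > 0, got {radius}")
    return 4.0 * flow / (math.pi * radius**3)
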