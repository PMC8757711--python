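"""Unit conversions.

Internally the hydraulics run in cm-g-s units (flow cm^3/s, stress dyn/cm^2,
viscosity poise); every user-facing flow is L/min. Conversions happen at
module boundaries only.
"""

#: cm^3/s per L/min (1 L = 1000 cm^3, 1 min = 60 s)
LPM_TO_CM3S: float = 1000.0 / 60.0

#: poise per centipoise
CP_TO_POISE: float = 0.01

#: Pa per dyn/cm^2
DYN_CM2_TO_PA: float = 0.1


def lpm_to_cm3s(flow_lpm: float) -> float:
    """Convert a flow rate from L/min to cm^3/s."""
    return flow_lpm * LPM_TO_CM3S


def cm3s_to_lpm(flow_cm3s: float) -> float:
    """Convert a flow rate from cm^3/s to L/min."""
    return flow_cm3s / LPM_TO_CM3S


def cp_to_poise(viscosity_cp: float) -> float:
    """Convert a dynamic viscosity from centipoise to poise."""
    return viscosity_cp * CP_TO_POISE
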