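"""End-to-end verification battery and report generation.

``run_report`` replays, in software, every check used to commission the
physical loop: constant-flow calibration regression at 3-6 L/min, pulsatile
time-weighted-average validation against a simulated 10-cycle sensor
measurement, thermostat convergence to 37 degC, heart and vessel dimension
verification, the friction-coefficient check, and the wall shear table at
the pulsatile mean flow. The report is a validated pydantic model, so its
JSON schema is published mechanically and the prose rendering is generated
from the same numbers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import anatomy, hydraulics, pump as pump_mod, sensing, thermal, waveforms
from .config import LoopConfig
from .units import DYN_CM2_TO_PA, lpm_to_cm3s

__all__ = [
    "ValidationReport",
    "run_report",
    "render_text",
    "report_json_schema",
    "export_waveforms",
]

log = logging.getLogger("mockloop")

_SETPOINTS = [3.0, 4.0, 5.0, 6.0]  # constant-flow verification points, L/min


class ConstantFlowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    slope: float
    intercept: float
    r_squared: Optional[float]
    setpoints: List[float]
    trials: List[Dict[str, float]]
    passed: bool


class PulsatileTrialRow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    trial: int
    theoretical: float
    measured: float


class PulsatileSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    theoretical_twa: float
    measured_mean: float
    measured_sd: float
    sd_degenerate: bool
    trials: List[PulsatileTrialRow]
    tolerance: float
    passed: bool


class TemperatureSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    steady_temperature: float
    setpoint: float
    band: float
    time_to_band_s: float
    passed: bool


class DimensionRow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    value: float
    low: float
    high: float
    passed: bool
    alternate_value: Optional[float] = None


class VesselRow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    system: float
    low: float
    high: float
    status: str
    note: Optional[str] = None


class GeometrySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    heart: Dict[str, DimensionRow]
    vessels: Dict[str, VesselRow]
    radial_path_cm: float
    femoral_path_cm: float
    expected_path_cm: float
    warnings: List[str]
    passed: bool


class FrictionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean: float
    sd: float
    sd_degenerate: bool
    physiological_pass: bool
    design_pass: bool


class ShearRow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    diameter_cm: float
    shear_stress_dyn_cm2: float
    shear_stress_pa: float
    shear_rate_per_s: float


class ValidationReport(BaseModel):
    """Machine-readable verification battery outcome."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    constant_flow: ConstantFlowSection
    pulsatile: PulsatileSection
    temperature: TemperatureSection
    geometry: GeometrySection
    friction: FrictionSection
    shear: Dict[str, ShearRow]
    overall_pass: bool


def report_json_schema() -> dict:
    """JSON schema of :class:`ValidationReport` (draft 2020-12)."""
    return ValidationReport.model_json_schema()


def _theoretical_profile(config: LoopConfig, n_samples: int = 256):
    svc = waveforms.venous_waveform(config.waveform, "SVC", n_samples)
    ivc = waveforms.venous_waveform(config.waveform, "IVC", n_samples)
    inflow = hydraulics.pump_inflow_profile(
        svc, ivc, config.svc_diameter, config.ivc_diameter, config.inlet_diameter
    )
    return svc, ivc, inflow


def run_report(config: LoopConfig) -> ValidationReport:
    """Execute the full verification battery; deterministic for a fixed
    ``config.seed`` (only stochastic sections depend on it)."""
    seed_cf, seed_puls = (
        int(s) for s in np.random.SeedSequence(config.seed).generate_state(2)
    )

    # --- constant-flow calibration regression -----------------------------
    log.info("verifying constant flow at %s L/min", _SETPOINTS)
    cf = pump_mod.verify_constant_flow(
        config.pump, _SETPOINTS, trials_per_point=3, timing_sd=0.1, seed=seed_cf
    )
    cf_section = ConstantFlowSection(
        slope=cf.summary.slope,
        intercept=cf.summary.intercept,
        r_squared=cf.summary.r_squared,
        setpoints=_SETPOINTS,
        trials=[
            {"set_flow": t.set_flow, "measured_flow": t.measured_flow}
            for t in cf.trials
        ],
        passed=(
            abs(cf.summary.slope - 1.0) <= 0.05
            and (cf.summary.r_squared is None or cf.summary.r_squared >= 0.99)
        ),
    )

    # --- pulsatile TWA validation -----------------------------------------
    log.info("validating pulsatile flow (theoretical vs sensor-measured TWA)")
    _, _, inflow = _theoretical_profile(config)
    theoretical = waveforms.time_weighted_average(inflow)
    schedule = waveforms.discretize_to_steps(inflow, config.n_steps)
    outlet_sensor = config.sensors[0]
    meas = sensing.measure_average_flow(
        schedule, outlet_sensor, n_cycles=10, n_trials=3, seed=seed_puls
    )
    if meas.degenerate_sd:
        log.warning("pulsatile SD is degenerate (single trial); reported as 0")
    tolerance = 0.13  # acceptance band on the measured mean, L/min
    puls_section = PulsatileSection(
        theoretical_twa=theoretical,
        measured_mean=meas.mean,
        measured_sd=meas.sd,
        sd_degenerate=meas.degenerate_sd,
        trials=[
            PulsatileTrialRow(trial=i + 1, theoretical=theoretical, measured=r)
            for i, r in enumerate(meas.readings)
        ],
        tolerance=tolerance,
        passed=abs(meas.mean - theoretical) <= tolerance,
    )

    # --- thermostat convergence -------------------------------------------
    log.info("simulating reservoir heating to %s degC", config.thermostat.setpoint)
    trace = thermal.simulate_heating(
        config.thermal, config.thermostat, t_initial=config.thermal.ambient,
        duration=2400.0, dt=1.0,
    )
    steady = thermal.steady_state_temperature(trace, tail_fraction=0.5)
    t_band = thermal.time_to_reach(
        trace, config.thermostat.setpoint - config.thermostat.deadband / 2.0
    )
    temp_section = TemperatureSection(
        steady_temperature=steady,
        setpoint=config.thermostat.setpoint,
        band=1.0,
        time_to_band_s=t_band,
        passed=abs(steady - config.thermostat.setpoint) <= 1.0,
    )

    # --- geometry ----------------------------------------------------------
    log.info("verifying heart and vessel dimensions")
    warnings: List[str] = []
    heart_checks = anatomy.verify_heart_dimensions(config.heart)
    heart_rows: Dict[str, DimensionRow] = {}
    for axis, res in heart_checks.items():
        lo, hi = res["range"]
        heart_rows[axis] = DimensionRow(
            value=res["value"], low=lo, high=hi, passed=res["passed"],
            alternate_value=res["alternate_value"],
        )
        if res["alternate_value"] is not None:
            msg = (
                f"{axis}: conflicting as-measured values "
                f"{res['value']} cm (table, used) vs "
                f"{res['alternate_value']} cm (narrative)"
            )
            warnings.append(msg)
            log.warning(msg)
    vessel_checks = anatomy.verify_vessel_diameters(config.vessels)
    vessel_rows = {
        name: VesselRow(
            system=res["system"], low=res["range"][0], high=res["range"][1],
            status=res["status"], note=res["note"],
        )
        for name, res in vessel_checks.items()
    }
    radial = anatomy.access_path_length(config.layout, "radial")
    femoral = anatomy.access_path_length(config.layout, "femoral")
    geometry_pass = (
        all(r.passed for r in heart_rows.values())
        and all(r.status != "fail" for r in vessel_rows.values())
        and abs(radial - config.access_path_length) <= 1e-9
        and abs(femoral - config.access_path_length) <= 1e-9
    )
    geom_section = GeometrySection(
        heart=heart_rows, vessels=vessel_rows,
        radial_path_cm=radial, femoral_path_cm=femoral,
        expected_path_cm=config.access_path_length,
        warnings=warnings, passed=geometry_pass,
    )

    # --- friction -----------------------------------------------------------
    log.info("checking cast-material friction coefficient")
    fr = anatomy.friction_coefficient(config.friction_measurements)
    fr_check = anatomy.verify_friction(fr.mean)
    fr_section = FrictionSection(
        mean=fr.mean, sd=fr.sd, sd_degenerate=fr.degenerate_sd, **fr_check
    )

    # --- wall shear table at the pulsatile mean flow ------------------------
    log.info("computing wall shear table at %.2f L/min", theoretical)
    flow_cgs = lpm_to_cm3s(theoretical)
    shear_rows: Dict[str, ShearRow] = {}
    for name, entry in config.vessels.vessels.items():
        r = entry.system_diameter / 2.0
        tau = hydraulics.wall_shear_stress(flow_cgs, r, config.fluid)
        gamma = hydraulics.wall_shear_rate(flow_cgs, r)
        shear_rows[name] = ShearRow(
            diameter_cm=entry.system_diameter,
            shear_stress_dyn_cm2=tau,
            shear_stress_pa=tau * DYN_CM2_TO_PA,
            shear_rate_per_s=gamma,
        )

    overall = (
        cf_section.passed and puls_section.passed and temp_section.passed
        and geom_section.passed
        and fr_section.physiological_pass and fr_section.design_pass
    )
    return ValidationReport(
        seed=config.seed,
        constant_flow=cf_section,
        pulsatile=puls_section,
        temperature=temp_section,
        geometry=geom_section,
        friction=fr_section,
        shear=shear_rows,
        overall_pass=overall,
    )


def render_text(report: ValidationReport) -> str:
    """Human-readable rendering; carries every number the JSON carries,
    printed at 2 decimal places for flows/lengths, full values elsewhere."""
    ok = lambda b: "PASS" if b else "FAIL"  # noqa: E731
    lines: List[str] = []
    lines.append("Mock circulatory loop verification report")
    lines.append(f"seed: {report.seed}")
    lines.append("")
    cf = report.constant_flow
    lines.append(f"[{ok(cf.passed)}] Constant-flow calibration regression")
    r2 = "undefined" if cf.r_squared is None else f"{cf.r_squared:.4f}"
    lines.append(
        f"  measured = {cf.slope:.4f} x set {cf.intercept:+.4f}, r^2 = {r2}"
    )
    lines.append(f"  setpoints (L/min): {', '.join(f'{s:.2f}' for s in cf.setpoints)}")
    for t in cf.trials:
        lines.append(
            f"    set {t['set_flow']:.2f} L/min -> measured {t['measured_flow']:.4f} L/min"
        )
    p = report.pulsatile
    lines.append(f"[{ok(p.passed)}] Pulsatile time-weighted average flow")
    lines.append(f"  theoretical TWA: {p.theoretical_twa:.2f} L/min")
    sd_note = " (degenerate: single trial)" if p.sd_degenerate else ""
    lines.append(
        f"  measured over 10 cycles x {len(p.trials)} trials: "
        f"{p.measured_mean:.2f} +/- {p.measured_sd:.2f} L/min{sd_note}"
    )
    for row in p.trials:
        lines.append(
            f"    trial {row.trial}: theoretical {row.theoretical:.2f}, "
            f"measured {row.measured:.2f} L/min"
        )
    lines.append(f"  acceptance band: +/- {p.tolerance:.2f} L/min")
    t = report.temperature
    lines.append(f"[{ok(t.passed)}] Reservoir temperature")
    lines.append(
        f"  steady-state average {t.steady_temperature:.2f} degC "
        f"(target {t.setpoint:.2f} +/- {t.band:.2f} degC), "
        f"reached the band after {t.time_to_band_s:.0f} s"
    )
    g = report.geometry
    lines.append(f"[{ok(g.passed)}] Geometry verification")
    for axis, row in g.heart.items():
        alt = (
            f" (alternate reported value {row.alternate_value:.2f} cm)"
            if row.alternate_value is not None
            else ""
        )
        lines.append(
            f"  heart {axis}: {row.value:.2f} cm in [{row.low:.2f}, {row.high:.2f}] "
            f"-> {ok(row.passed)}{alt}"
        )
    for name, row in g.vessels.items():
        note = f" ({row.note})" if row.note else ""
        lines.append(
            f"  vessel {name}: {row.system:.2f} cm vs [{row.low:.2f}, {row.high:.2f}] "
            f"-> {row.status.upper()}{note}"
        )
    lines.append(
        f"  access paths: radial {g.radial_path_cm:.2f} cm, femoral "
        f"{g.femoral_path_cm:.2f} cm (expected {g.expected_path_cm:.2f} cm)"
    )
    for w in g.warnings:
        lines.append(f"  warning: {w}")
    f = report.friction
    both = f.physiological_pass and f.design_pass
    sd_note = " (degenerate: single trial)" if f.sd_degenerate else ""
    lines.append(f"[{ok(both)}] Friction coefficient")
    lines.append(
        f"  mu = {f.mean:.2f} +/- {f.sd:.2f}{sd_note}; physiological band "
        f"{ok(f.physiological_pass)}, design band {ok(f.design_pass)}"
    )
    lines.append("[INFO] Wall shear at the pulsatile mean flow")
    for name, row in report.shear.items():
        lines.append(
            f"  {name} (d = {row.diameter_cm:.2f} cm): tau_w = "
            f"{row.shear_stress_dyn_cm2:.3f} dyn/cm^2 = {row.shear_stress_pa:.4f} Pa, "
            f"gamma_w = {row.shear_rate_per_s:.1f} 1/s"
        )
    lines.append("")
    lines.append(f"OVERALL: {ok(report.overall_pass)}")
    return "\n".join(lines)


def export_waveforms(config: LoopConfig, out_dir) -> List[Path]:
    """Write the SVC, IVC and combined-inflow waveform CSVs plus the PWM duty
    schedule CSV for the configured loop; returns the paths written."""
    if str(out_dir) == "":
        raise OSError("output directory path is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    svc, ivc, inflow = _theoretical_profile(config)
    schedule = waveforms.discretize_to_steps(inflow, config.n_steps)
    duties = pump_mod.schedule_duties(config.pump, schedule)
    paths = [
        out / "svc_waveform.csv",
        out / "ivc_waveform.csv",
        out / "inflow_waveform.csv",
        out / "duty_schedule.csv",
    ]
    waveforms.write_waveform_csv(svc, paths[0])
    waveforms.write_waveform_csv(ivc, paths[1])
    waveforms.write_waveform_csv(inflow, paths[2])
    pump_mod.write_duty_schedule_csv(duties, paths[3])
    return paths
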