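# Methods

This note documents the models behind the loop digital twin, the defaults
and why they were chosen, the numerical choices, and what the synthetic
components do and do not capture about the physical bench.

## Units

Hydraulics run internally in cm–g–s (flow cm³/s, stress dyn/cm², viscosity
poise); all user-facing flows are L/min, converted only at module boundaries
(1 L/min = 1000/60 cm³/s; 1 cP = 0.01 poise; 1 dyn/cm² = 0.1 Pa). The mix is
deliberate: shear formulas are cgs-natural while bench instrumentation reads
L/min.

## Venous waveform family

The physical loop drives its pump from literature vena-cava flow profiles
that are not available in tabulated form, so the twin uses an analytic
stand-in with the same qualitative structure: the biphasic venous pattern
with a systolic forward lobe, a diastolic forward lobe and a small
atrial-reversal dip. One period of the raw shape is

    s(t) = 1 + a_S c(t; 0.25T, 0.25T) + a_D c(t; 0.65T, 0.25T) − a_A c(t; 0.95T, 0.15T)

with raised-cosine lobes c(t; t₀, w) = ½(1 + cos 2π(t−t₀)/w) on
|t − t₀| ≤ w/2 (periodically wrapped), zero elsewhere, and default amplitudes
a_S = 0.8, a_D = 0.5, a_A = 0.3. The branch profile is s(t) rescaled
multiplicatively so its cycle mean equals the branch target exactly —
svc_fraction (default ⅓) of the 3.10 L/min total for the SVC, the remainder
for the IVC. Defaults: 60 bpm (T = 1 s), all parameters configurable.
Because the default shape never drops below 0.7 of base, branch flows stay
positive; negative flows are permitted analytically and clipped only at the
step-schedule stage, since the impeller pump cannot reverse.

A closed-form consequence used throughout: on a uniform grid with periodic
closure, the trapezoidal cycle mean equals the arithmetic sample mean, so the
rescaling is exact rather than approximate.

## Continuity and shear

Cross-section A = πd²/4, velocity v = F/A, junction velocity
v_IN = (v_SVC d_SVC² + v_IVC d_IVC²)/d_IN², inlet flow F_IN = v_IN A_IN.
Algebraically F_IN = F_SVC + F_IVC for any d_IN, so the unmeasured pump-side
inlet bore (default 2.0 cm, the largest loop tubing) cannot affect downstream
results; the property-test suite checks this to 10⁻¹² relative. Wall shear
uses the straight-tube Poiseuille values τ_w = 4μF/(πr³), γ_w = 4F/(πr³); the
working fluid is Newtonian (water, μ = 1.0 cP, ρ = 1 g/cm³ by default;
viscosity is a scalar parameter, non-Newtonian rheology is out of scope).

## Exact periodic integration

Step discretization and sensor volumes both need integrals of a sampled
waveform. Rather than quadrature on a refined grid, the package integrates
the periodic piecewise-linear interpolant in closed form (per-segment
trapezoids plus an exact partial segment). Consequences: a step schedule's
duration-weighted mean equals the waveform's trapezoidal TWA to float
precision whenever no negative-flow clipping occurs, and a sensor window of
n cycles sees exactly n times the per-cycle volume. These identities are the
backbone of the cross-module invariant tests.

## Pump

The pump's duty→flow law is not documented for the physical unit beyond "PWM
creates different flow rates", so the twin adopts the simplest law consistent
with an impeller pump on a MOSFET: zero flow up to a deadband duty, affine
above it. Defaults deadband 55 counts, gain 0.03 L/min per count, spanning
0–6 L/min over the 8-bit range. The software correction is the affine pair
(a, b) applied to the raw curve — a pure correction *factor* is the special
case b = 0.

Bucket tests time the fill of a marked volume (default 1 L) and jitter the
fill time with Gaussian noise (default SD 0.1 s, truncated positive), which
mirrors a stopwatch procedure rather than noise on flow itself. Calibration
regression is ordinary least squares (scipy.stats.linregress) of measured on
set flow; r² is reported as None when the response has zero variance.

One design subtlety: constant-flow verification drives the pump through the
continuous command path — the exact duty implied by the inverse correction,
before PWM rounding — so that a calibrated pump with zero timing noise
reproduces the identity line exactly. Integer quantization applies where it
physically lives, in `schedule_duties`, whose reconstruction error is bounded
by half the gain per step.

## Turbine sensors

Pulse count over a window = round(pulses_per_liter × volume + ε), floored at
zero, ε Gaussian with default SD 2 pulses per window — the simplest noise
model that gives repeated trials a realistic spread. The nominal factor 396
pulses/L corresponds to a 6.6 Hz-per-(L/min) meter constant (6.6 × 60); in
practice the factor comes from `calibrate_correction_factor`, which averages
count/(volume) over recordings at known flows. The inverse map is
60·count/(window·pulses_per_liter), so a noiseless round trip is exact up to
one pulse quantum (60/(pulses_per_liter·window) L/min). Cycle-averaged
measurement integrates 10 cycles per reading and reports mean and sample SD
over 3 readings by default; a single reading reports SD 0 with an explicit
degenerate flag instead of failing, so report generation never aborts.

## Reservoir thermal model

Lumped well-mixed mass: mc dT/dt = P·u − k(T − T_amb), explicit Euler.
Defaults describe the 3 L heating-test tank: P = 1000 W, k = 5 W/°C, ambient
20 °C, c = 4186 J/(kg·°C), ρ = 1 kg/L, dt = 1 s. The heater wattage and loss
coefficient of the physical bench were never published; these values give a
realistic ~4 min warm-up and a slow (~2.5 × 10³ s) ambient relaxation. The
thermostat is bang-bang with hysteresis: on below setpoint − deadband/2, off
above setpoint + deadband/2 (setpoint 37 °C, deadband 1 °C — the loop's
37 ± 1 °C operating criterion). Euler stability is enforced by requiring
dt < (mc/k)/10. The closed-form heat-up time
t = (mc/k)·ln[(P/k − ΔT₀)/(P/k − ΔT)] serves as the test oracle (≈216 s from
20 °C to 36.5 °C at defaults).

Steady state is the time-average of the trace tail (default: final 50%). The
tail must show either ≥ 2 heater switch events (the limit cycle) or an
essentially flat profile (peak-to-peak ≤ 0.1 °C, covering heater-off
relaxation and constant traces); otherwise a convergence error asks for a
longer run. A single bench thermometer reading near 36.6 °C is treated as a
plausibility band only, never a target.

## Anatomy verification

Heart axes are accepted when the as-built value lies within the
average-heart literature mean ± 1 SD, bounds inclusive — the only rule
consistent with all five published range pairs (e.g. 4.51 ± 0.47 →
4.04–4.98 cm). Vessel bores use the same mean ± k·SD rule (k = 1 default,
configurable), with the femoral insertion port on a structural exclusion
list: it is a short Tuohy-Borst entry stub whose bore is inconsequential, so
it reports "excluded", never "fail". Chamber areas are stored for reference
but carry no rule (they were never measured on the cast). Two as-measured
figures exist for the right-ventricular midway axis (3.81 and 4.81 cm); the
build table's 3.81 cm is primary — it is the only one inside its range — and
the conflict is surfaced as a report warning rather than silently resolved.
Access paths (radial, femoral) are verified by summing segment lengths
against the 80 cm design figure. Friction: μ = F/N per trial, mean and sample
SD, checked against the physiological band [0.015, 0.13] (inclusive) and the
design band (0, 0.5) (exclusive). The bundled friction trials are synthetic,
constructed to the cast material's reported statistics (0.12 ± 0.05).

## Verification battery and problem sizes

`run_report` executes: constant-flow regression at {3,4,5,6} L/min × 3 trials
(pass: |slope − 1| ≤ 0.05 and r² ≥ 0.99); pulsatile TWA with a 256-sample
waveform grid, 20-step schedule, 10-cycle windows × 3 trials (pass: measured
mean within 0.13 L/min of theory); heating from ambient for 2400 s at
dt = 1 s; geometry, friction and the shear table at the pulsatile mean flow.
These sizes keep the whole battery under a second while leaving
discretization error orders of magnitude below every acceptance band. The
master seed fans out to per-section seeds via numpy's SeedSequence, so the
report is bit-reproducible for a fixed config and only stochastic sections
move when the seed changes.

## What the synthetic models do and do not show

The generators emulate the *statistics* of the bench procedures — stopwatch
jitter, pulse-count noise, thermostat cycling — under idealized physics:
perfectly affine pump response, exactly periodic waveforms, a well-mixed
reservoir, no compliance, no bubbles, no valve dynamics, no catheter–wall
mechanics, no real microcontroller timing. Passing tests therefore
demonstrate internal consistency of the method chain (waveform → continuity
→ schedule → sensor → statistics) and correctness of the verification rules,
not fidelity of any particular physical pump or sensor. Published
hardware-derived figures (the bench regression slope/intercept/r², the
single thermometer reading, the friction trials) depend on unpublished bench
data; the twin treats them as parameterizations or plausibility bands and
substitutes property-based checks — OLS parameter recovery, mass
conservation, sensor round-trip identity, τ = μγ, TWA preservation, seed
reproducibility — for desk-reproducible verification.

## Known limitations

- The analytic waveform family matches the qualitative biphasic venous
  pattern, not any patient-specific or published numeric profile.
- The true step count and cycle timing of the physical pump controller are
  unknown; 20 steps per 1 s cycle is a coarse but representative choice.
- Thermal parameters (heater power, loss coefficient) are plausible
  engineering values, not measurements.
- No pressure modelling anywhere: the loop is flow-controlled and the twin
  follows suit.
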