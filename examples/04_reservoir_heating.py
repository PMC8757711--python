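"""Heat the reservoir to body temperature under bang-bang control.

Simulates the 3 L reservoir with its 1000 W immersion heater from 20 degC.
The thermostat switches the heater about 37 degC with a 1 degC hysteresis
deadband, producing a limit cycle whose time-average is the loop's operating
temperature.
"""

from mockloop import ThermalModel, ThermostatController
from mockloop.thermal import simulate_heating, steady_state_temperature, time_to_reach

model = ThermalModel()
controller = ThermostatController()
trace = simulate_heating(model, controller, t_initial=20.0, duration=2400.0, dt=1.0)

t_warm = time_to_reach(trace, controller.setpoint - controller.deadband / 2)
steady = steady_state_temperature(trace, tail_fraction=0.5)
print(f"time to reach {controller.setpoint - controller.deadband/2:.1f} degC: "
      f"{t_warm:.0f} s")
print(f"steady-state average: {steady:.2f} degC "
      f"(target {controller.setpoint:.0f} +/- 1 degC)")
# The warm-up time follows the first-order heating law; the steady average
# sits at the setpoint because the hysteresis band is symmetric about it.
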