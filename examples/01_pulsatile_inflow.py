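"""Synthesize the venous branch waveforms and the pump inflow that feeds them.

Builds the default superior/inferior vena cava profiles (60 bpm, 3.10 L/min
total venous return split 1:2 between SVC and IVC), combines them through
split-tube continuity into the single pump inflow profile, and reports cycle
averages. The combined cycle average equals the sum of the branch means —
mass is conserved exactly through the bifurcation.
"""

from mockloop import VenousWaveformParams, pump_inflow_profile
from mockloop.waveforms import time_weighted_average, venous_waveform

params = VenousWaveformParams()
svc = venous_waveform(params, "SVC", n_samples=256)
ivc = venous_waveform(params, "IVC", n_samples=256)
inflow = pump_inflow_profile(svc, ivc, d_svc=1.27, d_ivc=2.0, d_in=2.0)

print(f"SVC cycle mean:      {time_weighted_average(svc):.4f} L/min")
print(f"IVC cycle mean:      {time_weighted_average(ivc):.4f} L/min")
print(f"pump inflow average: {time_weighted_average(inflow):.4f} L/min")
print(f"pump inflow peak:    {inflow.flows.max():.2f} L/min at "
      f"{inflow.times[inflow.flows.argmax()]:.2f} s of a {inflow.period:.0f} s cycle")
# The inflow average is the theoretical time-weighted average the physical
# loop is validated against; the peak shows the systolic lobe of the cycle.
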