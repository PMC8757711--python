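"""Run the complete verification battery on the default loop configuration.

Replays every commissioning check in one deterministic pass: constant-flow
regression, pulsatile time-weighted-average validation, thermostat
convergence, geometry verification, friction band checks and the wall shear
table. The same report is available as JSON for machine consumption.
"""

from mockloop import LoopConfig, render_text, run_report

report = run_report(LoopConfig(seed=0))
print(render_text(report))
# Every section carries pass/fail; overall_pass requires all of them. Pipe
# report.model_dump_json() into a file for the machine-readable form.
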