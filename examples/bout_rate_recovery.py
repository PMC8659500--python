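"""Recover a configured lying-bout rate through the whole pipeline.

The simulator is set to the day-of-calving literature rate (13.0 lying
bouts/day); each seed's accelerometer stream is classified with calibrated
thresholds and the detected stand->lie onsets are counted.  The across-seed
mean should sit on the configured rate — the pipeline neither invents nor
swallows bouts.
"""

import numpy as np

import calfwatch as cw

cal_scenario = cw.SimScenario(duration_h=24.0, seed=999)
_, cal_stream, cal_events = cw.simulate_collar_data(cal_scenario, seed=999)
params = cw.calibrate_thresholds(
    cw.trim_pre_transition(cw.synchronize(cal_stream, cal_events))).params

rate, n_seeds = 13.0, 10
detected, true = [], []
for s in range(n_seeds):
    scenario = cw.SimScenario(duration_h=24.0, baseline_bout_rate=rate,
                              seed=100 + s)
    schedule, stream, _ = cw.simulate_collar_data(scenario, seed=100 + s)
    r, n, d = cw.detected_bout_rate(stream, params)
    detected.append(r)
    true.append(len(schedule.lying_onsets_s()))
    print(f"seed {100 + s}: detected {r:5.2f} bouts/day "
          f"(true onsets {true[-1]})")

print(f"\nconfigured rate: {rate} bouts/day")
print(f"mean detected:  {np.mean(detected):.2f} "
      f"+/- {np.std(detected, ddof=1) / np.sqrt(n_seeds):.2f} (SE, "
      f"{n_seeds} seeds)")
print("The spread is renewal-process noise in the simulated behaviour; the "
      "detector itself recovers each realized bout count almost exactly.")
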