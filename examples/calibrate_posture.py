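"""Calibrate the standing/lying thresholds from observer-labelled data.

Human observers annotate standing (B1) and lying (B2) episodes; after joining
labels to the sensor stream and dropping the two minutes before each change
(observer reaction time), a grid search places an acceleration band over the
standing-conditional distribution so the 15-minute in-band count separates
the postures.
"""

import calfwatch as cw

scenario = cw.SimScenario(duration_h=24.0, seed=7)
schedule, stream, events = cw.simulate_collar_data(scenario, seed=7)
print(f"simulated day with {schedule.n_transitions} posture changes, "
      f"{len(events)} observer annotations")

labelled = cw.trim_pre_transition(cw.synchronize(stream, events))
print(f"{int(labelled.retained.sum())} of {len(stream)} records retained "
      "after the 2-min pre-transition exclusion")

result = cw.calibrate_thresholds(labelled)
p = result.params
print(f"\nband: thr_inf={p.thr_inf:+.3f} g  thr_sup={p.thr_sup:+.3f} g")
print(f"count threshold thr_standing={p.thr_standing:.1f} "
      f"(window capacity {p.window_samples} samples = 15 min at 0.27 Hz)")
print(f"posture-conditional count separation: {result.separation:.1f} samples")
print(f"balanced accuracy on calibration data: {result.balanced_accuracy:.3f}")
print("\nAccuracy below 1.0 mostly reflects the classifier's inherent "
      "~7.5-min decision latency after each posture change, not band overlap.")
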