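# calfwatch

Calving detection from neck-collar accelerometry for extensive (free-range)
cattle farming.

A cow approaching parturition becomes restless: she stands up and lies down
far more often than usual, rising from a baseline of roughly 9.3 lying bouts
per day to about 13 on the day of calving, with a sharp escalation in the
final hours.  A neck collar carrying an IMU can see this — but it has to do so
on a microcontroller, in real time, with almost no memory.  `calfwatch`
implements that detection chain as a tested Python library:

* **`calfwatch.codec`** — bit-exact reader/writer for the collar's binary
  log: 52-byte fixed-width records (millisecond timestamp, two temperatures,
  GNSS fix, 3-axis acceleration and rotation) in hourly files, decoded to
  physical units and re-encoded byte-identically.
* **`calfwatch.annotation`** — joins human-observer behaviour labels
  (standing/lying, or general behaviour mapped onto posture) to the sensor
  stream by timestamp, and excludes the two minutes before each label change
  to absorb observer reaction lag.
* **`calfwatch.posture`** — the posture classifier.  Y-axis acceleration is
  resampled from 17.6 Hz to 0.27 Hz by block averaging; a trailing 15-minute
  window counts samples inside a calibrated acceleration band,

      f_count(t) = #{ i ∈ (t−15 min, t] : thr_inf < f_ay(i) < thr_sup },

  and posture is the thresholded count,

      f_standing(t) = 1 (standing) if f_count(t) > thr_standing, else 0 (lying).

  Thresholds are fitted from labelled data by maximizing the separation of
  the posture-conditional mean counts.
* **`calfwatch.calving`** — the detector statistic.  Posture changes,

      f_lb(t) = |f_standing(t) − f_standing(t−1)|,

  are summed over a trailing five-hour window,

      f_parturition(t) = Σ_{i ∈ (t−5 h, t]} f_lb(i),

  and an alarm fires when f_parturition exceeds a per-animal trigger (the
  maximum over a calving-free calibration window, plus a margin), optionally
  gated to ±30 days around the expected calving date.  Streaming
  implementations keep only one count window plus one bout window of state —
  small enough for the collar's microcontroller.
* **`calfwatch.simulate`** — a synthetic cattle-behaviour generator
  (alternating-renewal bout process with pre-calving escalation,
  posture-conditional sensor distributions, observer lag) so every stage is
  testable without field data.

## Worked example

`examples/simulate_and_detect.py` simulates a calving week (calving at hour
132), calibrates posture thresholds from a separate labelled baseline day,
fits the per-animal trigger on the week's own pre-calving baseline, and runs
the detector:

```
posture band: (+0.053, +0.634) g, count threshold 130.2 of 243 window samples
per-animal trigger: f_parturition > 9 (baseline max + margin 1)
alarm at hour 127.65 (f_parturition = 10); true calving at hour 132.0
detection lead: 4.35 h before calving
```

Reading this: resampled Y-axis readings between 0.053 g and 0.634 g are
"standing-like"; when more than ~130 of the 243 readings in the trailing
15 minutes fall in that band the cow is classified standing.  Over the
baseline days this cow never accumulated more than 9 posture transitions in
any five-hour window, so the trigger sits at 10 — and the statistic first
exceeds it 4.35 hours before the true calving instant.  Other capabilities
(codec round trips, threshold calibration, bout-rate recovery) each have
their own script under `examples/`.

There is also a thin CLI over the same functions:

```sh
calfwatch simulate --seed 1 --duration-h 72 --calving-time-h 60 --out-dir run/
calfwatch calibrate --stream-files run/collar/*.bin --annotations run/annotations.csv --out-dir run/cal
calfwatch detect --stream-files run/collar/*.bin --params run/cal/posture_params.yaml \
    --calibration-hours 36 --expected-calving-h 60 --out-dir run/det
```

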