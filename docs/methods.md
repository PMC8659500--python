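# Methods

## The detection problem

In extensive farming, pregnant cows range freely and cannot be watched
around the clock.  The behavioural signature of imminent calving is an
increase in lying bouts — stand→lie→stand cycles — from a baseline of about
9.3 bouts/day to about 13 on the day of calving, with a pronounced
escalation in the last hours before the event.  A neck-mounted collar with a
17.6 Hz IMU can capture this, but all processing must run on the collar's
microcontroller: every statistic here is a trailing (right-aligned) window
over past samples, with state bounded by the window contents.

## Posture classification

On a neck collar the standing and lying accelerometer distributions overlap
far more than on a leg mount.  The classifier therefore works on occupancy
of an acceleration band rather than on instantaneous values:

1. **Resampling.**  Y-axis acceleration is block-averaged from 17.6 Hz onto
   a 0.27 Hz grid (non-overlapping blocks of 1/0.27 ≈ 3.70 s, stamped at
   block end).  Averaging — rather than decimation — preserves band-occupancy
   semantics under white sensor noise.  Blocks overlapping a data gap
   (inter-sample interval above 3 nominal periods) emit nothing and start a
   new segment; windows never span a gap.
2. **Banded count.**  A trailing 15-minute window counts resampled readings
   strictly inside (thr_inf, thr_sup).  Window capacity is
   floor(900 s × 0.27 Hz) = 243 samples.
3. **Thresholding.**  f_standing(t) = 1 iff f_count(t) > thr_standing
   (strict), else 0.  Samples whose window is still filling (the first 242
   of each segment) are flagged warmup and excluded from all downstream
   statistics rather than zero-filled.

**Calibration** fits the three thresholds from observer-labelled data.
Candidate band edges are quantiles (2–98%) of the labelled resampled signal,
padded slightly beyond the observed range so a strict band can still contain
an extreme mode in the degenerate zero-noise limit.  The pair maximizing the
difference between the standing- and lying-conditional mean counts wins
(signed: the band targets the standing mode, which has the larger Y-axis
mean on a neck collar), and thr_standing is the midpoint of the two
conditional means.  A resampled sample inherits a label only when the block
is unambiguous — same retained label at block start and end, no excluded
record inside.

**Decision latency.**  A trailing majority count cannot react instantly: a
posture change is classified once roughly thr_standing of the window has
flipped, i.e. after ≈ thr_standing / 0.27 Hz ≈ 7.5 minutes (exactly
floor(thr) samples for lie→stand, ceil(w−1−thr) for stand→lie).  The
latency is deterministic, so transitions are delayed but neither created nor
destroyed when bouts are longer than the count window; the balanced accuracy
reported by calibration (~0.9 at the default noise level) is dominated by
these latency samples, not band overlap.  Per-sample equality with ground
truth therefore holds exactly only after compensating this fixed lag, which
is how the noiseless end-to-end test states it.

## Calving statistic and trigger

Transitions f_lb(t) = |f_standing(t) − f_standing(t−1)| are summed over a
trailing 5-hour window to give f_parturition(t) (valid once a full window of
transition values exists after stream start or after a gap).  Restlessness
differs strongly between animals, so the trigger is per-cow: the maximum of
f_parturition over a calving-free calibration window plus a margin (default
1 count).  The rule needs only a running maximum — O(1) memory — and places
the trigger just above everything the animal has previously shown.  By
default the calibration window excludes the final 24 h before an expected
event; the margin, window and refractory period (24 h after any alarm) are
configurable.  When a service/insemination date is known, alarms are gated
to ±30 days around the expected calving date; otherwise the detector runs
ungated.

Because f_parturition is a trailing window, it necessarily remains elevated
for up to one window length (5 h) after the event before the pre-calving
transitions expire; the peak of the statistic is attained between the
escalation onset and shortly after calving.

## The synthetic-data generator

The generator emulates exactly the structure the detector assumes, no more:

* **Bout process.**  Alternating standing/lying dwells; each dwell is a
  *shifted* exponential — a hard minimum bout duration (default 10 min) plus
  an exponential tail — with means allocated so that the lying-bout onset
  rate equals the configured rate and the time fraction standing equals the
  configured standing fraction (default 0.55).  A pure exponential would put
  ~14% of bout mass below the count window's half-width; real cattle do not
  produce two-minute bouts at baseline, and such bouts are invisible to any
  15-minute smoothing by construction.  The process starts in its
  equilibrium (stationary) state, making the expected onset count exactly
  rate × duration at any horizon.
* **Escalation.**  With a calving time set, the instantaneous rate ramps
  linearly from baseline to peak_multiplier × baseline inside the 8 h → 2 h
  pre-calving window and holds the peak until calving.  The default peak
  multiplier of 6 (≈ 56 bouts/day, one stand–lie cycle per ~26 min) is a
  realistic active-labour restlessness level.  After calving the rate drops
  to 0.6 × baseline and relaxes back with a 12 h half-life (bouts gradually
  decrease postpartum).
* **Sensors.**  ay and az are Gaussian conditional on posture (standing: ay
  mean +0.35 g, the larger; az the larger spread) plus a shared AR(1) drift
  (σ = 0.06 g, τ = 120 s) emulating slow neck movement.  The drift is what
  keeps the problem honest: white noise alone would be averaged away by the
  3.7 s blocks.  GNSS and temperature channels are placeholders held
  constant within each second (their 1 Hz semantics on the device).  These
  distributions are synthetic choices with moderate overlap, not fitted to
  any herd.
* **Observers.**  One standing/lying event per posture change, delayed by a
  Gaussian reaction lag (5 ± 2 s, floored at zero); optionally a
  general-behaviour stream in which Neutral and Ruminating occur in both
  postures (the documented ambiguity that motivates the dedicated posture
  label set).

What the generator does **not** emulate: grazing/rumination kinematics,
GNSS trajectories, temperature physiology, label noise beyond reaction lag,
sensor dropouts (gaps can be injected, but are not generated by default).
Passing tests therefore demonstrate the correctness of the decoding,
classification and alarm logic under the assumed statistical structure —
not field performance on real herds.

## Numerical choices

* Little-endian on-disk byte order (natural for the collar's Cortex-M class
  CPU), exposed as a dialect option; field order as stored on the device.
* The 32-bit millisecond timestamp is interpreted as time since collar
  initialization (it would overflow a Unix-epoch reading in ~25 days); the
  absolute epoch is attached per stream at load time.
* Scaled integer fields decode by exact division (lon/lat ÷ 10⁷,
  alt/speed ÷ 10³) and re-encode by rounding, making encode∘decode the
  identity on representable values.
* Strict inequalities in the band, strict ">" in the posture threshold, and
  half-open trailing windows (t − W, t] throughout; a sample exactly one
  window old has expired.
* Non-monotonic timestamps within a file are stable-sorted with a warning;
  trailing partial records are dropped with a warning; non-finite floats are
  flagged, never raised on.

## Problem sizes

The statistical tests use 50 seeds for rate recovery (1 day at 13.0
bouts/day, 4 days at 9.3) and 20 seeded one-week calving scenarios; these
sizes put the Monte-Carlo standard error of the recovered rate near 0.25
bouts/day and of the mean lead time near 0.25 h, tight enough to detect any
systematic bias in the pipeline while keeping the suite quick on a laptop.

## Known limitations

* Thresholds are herd-level and sensor-model dependent; real deployments
  would recalibrate per collar placement.
* The trigger rule assumes a calving-free calibration window; an unnoticed
  earlier event inflates the trigger.
* Dwell-time shape, escalation shape (linear ramp + plateau) and post-calving
  relaxation are modelling choices where only rates and the escalation window
  are externally constrained; all are exposed as scenario parameters.
* Lead-time figures are with respect to the simulator's escalation profile;
  they measure the algorithm, not cattle.
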