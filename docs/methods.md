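# Models and methods

This note documents what each component of the simulator models, the
parameters that matter, the numerical conventions, and what the
synthetic signals do and do not capture of real recordings.

## Signal model

**Beat train.** Beat onsets are generated with inter-beat intervals
`60/hr + ε`, with `ε ~ N(0, σ_jitter²)` independent per beat and
truncated at ±3σ so intervals stay positive. This is the simplest
stationary variability model; it has no respiratory sinus arrhythmia,
no trends, and no ectopic beats. Defaults: resting subjects 60–100 bpm
(80 by default), after-exercise subjects 120–150 bpm (140 by default),
jitter 0–0.02 s in tests.

**Pulse shape.** One beat is a raised-cosine bump occupying the first
half of the inter-beat interval, peaking at 25% of the interval. Any
unimodal shape that starts and ends at baseline would do; the raised
cosine is smooth, has a single strict maximum, and makes the peak phase
analytic. Real PPG morphology (dicrotic notch, reflected waves,
multi-wavelength optics) is deliberately not modelled — the attack and
the pipeline only use peak positions and amplitudes.

**Scale.** All signals are in abstract A/D counts: baseline 400,
pulse amplitude 300, additive white Gaussian sensor noise with SD 0–8
counts depending on scenario. Pressure shares the same count scale
(the calibration grid runs 400 → 20). No physical unit conversion is
defined anywhere in the toolchain, so none is introduced here.

**Cuff occlusion.** The distal pulse amplitude is multiplied by a
logistic factor

    a(p) = 1 / (1 + exp((p − θ) / (s/2)))

of instantaneous cuff pressure `p`: ≈1 when vented, 1/2 at the
subject's occlusion threshold `θ`, and <0.01 beyond `θ + 3s` where
`s` is the softness parameter. The true pressure–amplitude curve of an
arm is only known qualitatively (amplitude shrinks with pressure and
vanishes above a subject-specific point), so the logistic is a
stand-in; its steepness is the `occlusion_softness` knob (default 20
counts; "sharp" test subjects use 0.5). Attenuation is applied per
sample, so a pressure step mid-beat truncates that beat's bump, and
partial pressures yield shrunken-but-present peaks. Pulse-transit
delay between cuff and sensor is taken as zero.

## Plant

Pump and valve are linear: pressure rises at `pump_rate` (default 800
counts/s, i.e. 0 → 400 in the ~0.5 s the physical rig needed) and
vents at `vent_rate` (default 800 counts/s), floored at zero, with an
optional leak. Actuators cut off within one 5 ms tick at their
setpoints. Two presets: `PlantParams.ideal()` makes transitions
complete within a single tick (used for theoretical-ratio runs), and
`PlantParams.slow_pump()` (300 counts/s) makes pressurization take
longer than a beat interval at exercise heart rates. Air
compressibility, pump back-pressure stall and cuff-to-artery transfer
are not modelled.

## Streaming detector

The controller's detector keeps a running min/max envelope and puts
its threshold at the midpoint. A peak is *confirmed* when the signal
falls back through the threshold after an upward excursion; the event
carries the excursion maximum's time, so reported peak times land
within a sample of the waveform peak while the controller acts on the
falling edge (~a quarter bump width after the peak). Design constants:

* refractory 0.25 s — caps the event rate at 240/min, above any adult
  heart rate;
* minimum envelope span 25 counts — spans below this are treated as
  noise floor (sensor noise of SD ≤ 4 counts stays well under it), so
  a suppressed channel emits no events;
* reset after 2 s without a peak — the envelope collapses to the
  current sample, which both implements the "pulse disappeared"
  verdict (resting inter-beat intervals are ≤ ~1 s, so 2 s of silence
  is decisive) and lets detection recover within two beats when the
  pulse returns.

`is_disappeared` additionally requires 2 s of observed signal before
it can ever fire, so a freshly started detector cannot report a
spurious disappearance.

## Calibration

Grid search from 400 counts downward in steps of 20: pressurize, hold
6 s, read `is_disappeared` at the end of the hold, vent 1 s, and step
down while the pulse keeps disappearing; on the first surviving trial
return `target + 20`. The 6 s hold is a choice (nothing prescribes
it): it covers at least three resting beat intervals plus the 2 s
disappearance window, so both verdicts are reliable within one trial.
The verdict is read at the end of the hold rather than anywhere inside
it, which makes a trial immune to disappearance state carried over
from the previous (occluded) trial. If the grid descends to zero
without finding a surviving pressure the procedure aborts — a subject
whose pulse vanishes at every positive grid value cannot be
calibrated. For a subject with a sharp attenuation curve the result is
exactly the smallest grid value `400 − 20k` strictly above θ; for
soft curves it is the smallest grid value at which the residual pulse
amplitude falls below the detector's noise-floor span, which is the
operationally correct notion of "disappeared".

## Control cycle and peak accounting

The cycle is PRESSURIZE → HOLD → RELEASE → WAIT. Each phase's peak
quota starts counting when its pressure condition is met: HOLD counts
`N_stop` peaks from the moment pressure reaches `x_air_max`, WAIT
counts `N_appear` peaks from the moment pressure reaches
`0.5·x_air_max`. Beats that fall inside the pressurize/release
transients belong to neither quota. With an ideal plant the transients
contain no beats and every cycle holds exactly `N_stop + N_appear`
beats, so the surviving fraction equals the theoretical
`N_appear/(N_stop+N_appear)`; with a slow plant the transients add
uncounted beats to every cycle, the occluded span covers more than
`N_stop` beats, and the released-window fraction falls strictly below
the theoretical ratio — the over-suppression failure mode at exercise
heart rates. `N_stop = 0` is the degenerate no-attack case: the cuff
is never pressurized.

The session log measures this bookkeeping directly:
`SessionLog.surviving_fraction()` is the fraction of true beats whose
waveform peak occurs during WAIT, and `occluded_beats_per_cycle()`
divides the rest over completed cycles. Note that the optical measure
can differ slightly: a beat early in a slow pressure ramp is below θ
and still visible distally even though it is outside the released
window, so the distal pipeline can count marginally more surviving
beats than the bookkeeping does.

## Heart-rate pipeline

* **Smoothing**: 41-sample centred moving average (~200 ms at 200 Hz),
  normalized by the (truncated at the edges) window length so the
  output stays on the input scale and the mean-based height threshold
  is consistent.
* **Peak picking**: strict local maxima above a height threshold
  (default: the mean of the smoothed trace over the recording) with a
  minimum spacing of 100 samples at rest / 50 after exercise (0.5 s /
  0.25 s). Conflicting candidates are resolved greedily, tallest
  first; equal heights go to the earlier peak — a deterministic
  replacement for manual inspection of ambiguous peaks.
* **Rate**: `b(t) = 60 / mean(most recent ≤10 intervals)` on a 1 s
  grid, undefined before the first interval. Averaging 10 intervals
  damps single mis-detections at the cost of ~10 beats of latency.
* **Display**: a watch model clamps to its displayable range (or
  blanks, for dropout models). The shipped models are four measured
  display ranges (54–201, 44–210, 45–189, 48–180 bpm). On-watch
  proprietary smoothing/confidence logic is not modelled.

The end-of-session value is the mean displayed reading over the final
10 s — averaging de-noises the read-out without changing the steady
state. The session verdict uses the ±15 bpm band with strict
inequalities.

## Numerical conventions

* Controller tick = sample period = 5 ms (200 Hz); one sample per tick
  for both logging and detection.
* All randomness in a session derives from one integer seed via
  separate child streams for beat jitter and the two noise channels;
  identical configurations produce bit-identical transcripts.
* Trace CSVs serialize time with 4 decimals and values with 6
  significant digits; a write→read→write cycle is byte-stable.
* Problem sizes: property suites use 20–30 s sessions (≈25–60 beats,
  enough for 4–10 complete attack cycles); ratio checks use 10-minute
  sessions where the 10-interval window's phase averages out to within
  a few percent of the theoretical fraction.

## Known limitations

* The attenuation curve's shape and the pressure unit are modelling
  choices; only the curve's qualitative form (monotone roll-off with a
  subject-specific disappearance point) is anchored.
* The linear plant cannot reproduce a pump that stalls near its target
  pressure; the slow-pump preset reproduces over-suppression through
  transition-time accounting, not pump aerodynamics.
* Displayed-value dynamics of real watches (latency, confidence
  gating, proprietary filtering) are reduced to a clamp; simulated
  display trajectories are therefore cleaner than real ones.
* Motion artefacts, contact-pressure changes and skin-tone/perfusion
  optics are outside the signal model, so passing tests say nothing
  about detector robustness under those disturbances.
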