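# cuffsim

A desk-scale, fully software simulator of a physical spoofing attack on
wrist-worn heart-rate sensing: a computer-controlled blood-pressure cuff
inflates on the upper arm in rhythm with the wearer's own heartbeat, so
that a photoplethysmogram (PPG) sensor distal to the cuff — the optical
sensor in a smartwatch — misses a chosen fraction of pulses and displays
a correspondingly lower heart rate. The package is aimed at wearable
security researchers who want to study the attack's control logic,
timing limits and countermeasures without building the pneumatic rig or
recruiting subjects.

## The attack in brief

A PPG sensor sees one pulse per cardiac cycle; squeezing the upper arm
above a subject-specific pressure θ stops distal blood flow and the
pulse peaks vanish. The attack has two phases, both driven by a
streaming peak detector:

* **Calibration** (sensing distal to the cuff) walks a pressure grid
  downward from 400 A/D counts in steps of 20, pressurizing, holding,
  and asking whether the pulse *disappeared* (no peak detected for
  2 s). It returns `x_air_max`, the smallest grid pressure that still
  stops the pulse.
* **Control** (sensing proximal to the cuff, where the signal is
  untouched) repeats: pressurize to `x_air_max` → hold until `N_stop`
  heartbeats pass → vent to `0.5·x_air_max` → idle until `N_appear`
  heartbeats pass.

The attacked sensor therefore sees only `N_appear` of every
`N_stop + N_appear` beats. A heart-rate pipeline that estimates rate
from inter-peak intervals — here: a 41-sample moving average, peak
picking with a mean-height threshold and a minimum peak distance, and

```
b(t) = 60 / mean(d_k over the most recent ≤10 intervals),   d_k = t_k − t_{k−1}
```

— converges to the fraction

```
displayed / true  →  N_appear / (N_stop + N_appear)
```

Pattern A (`N_stop = N_appear`) halves the displayed rate, Pattern B
(`(2,4)`) gives 2/3, Pattern C (`(4,2)`) gives 1/3. Commercial watch
faces clamp to a displayable range (e.g. a 45 bpm floor), which masks
deep attacks.

## Worked example

```python
from cuffsim import PatternSpec, PlantParams, SubjectProfile, run_session

subject = SubjectProfile(true_hr_bpm=80.0, hr_jitter_sd=0.0, noise_sd_counts=0.0)
res = run_session(subject, PatternSpec.A(3), plant=PlantParams.ideal(),
                  duration_s=120.0, seed=1, x_air_max=400.0)
print(res.end_of_session_true, res.end_of_session_displayed, res.verdict)
```

prints

```
80.0 40.38277511961722 decreased
```

— a 2-minute Pattern-A attack on an 80 bpm subject ends with the
attacked pipeline reading ≈40 bpm, half the true rate, and the session
classified as *decreased* under the ±15 bpm rule. The scripts in
`examples/` walk through each capability (signal synthesis, the
occlusion curve and calibration, a full session, pattern ratios with
watch clamping, and the slow-pump failure mode) and print the numbers
they compute.

There is also a thin CLI:

```bash
cuffsim calibrate --theta 310 --softness 0.5      # prints x_air_max = 320
cuffsim attack --pattern A --duration 120 --out session/
cuffsim analyze --trace trace.csv --channel distal
cuffsim report session/
```

## Layout

* `src/cuffsim/signal_model.py` — beat trains, pulse templates, cuff
  attenuation, trace rendering
* `src/cuffsim/plant.py` — pump/valve/cuff pressure dynamics
* `src/cuffsim/detector.py` — streaming adaptive-threshold peak
  detector and the 2-s disappearance rule
* `src/cuffsim/controller.py` — calibration and control state machines
* `src/cuffsim/hr_pipeline.py` — smoothing, offline peak picking,
  interval-average heart rate, watch display models
* `src/cuffsim/experiment.py` — patterns, full sessions, ±15 bpm
  verdicts
* `src/cuffsim/io.py`, `src/cuffsim/cli.py` — trace/config files and
  the command line

`docs/methods.md` documents the models, their parameters and the
simulator's known limitations.
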