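"""Over-suppression with an underpowered pump at exercise heart rates.

At 140 bpm a beat arrives every 0.43 s, but a 300 counts/s pump needs
~0.57 s to re-pressurize the cuff. Beats that land inside the pressure
transitions count toward neither phase quota, so each cycle occludes
more than N_stop beats and the surviving fraction drops below the
pattern's theoretical ratio.
"""

from cuffsim import PatternSpec, PlantParams, SubjectProfile, run_session, theoretical_ratio

pattern = PatternSpec.A(3)

for label, subject, plant in [
    ("rest, fast pump    ", SubjectProfile.rest(80.0, hr_jitter_sd=0.0), PlantParams.ideal()),
    ("exercise, slow pump", SubjectProfile.after_exercise(140.0, hr_jitter_sd=0.0), PlantParams.slow_pump()),
]:
    res = run_session(subject, pattern, plant=plant, duration_s=120.0, seed=2, x_air_max=340.0)
    print(
        f"{label}: surviving fraction {res.log.surviving_fraction():.3f} "
        f"(theory {theoretical_ratio(pattern):.3f}), "
        f"occluded beats/cycle {res.log.occluded_beats_per_cycle():.2f} "
        f"(quota {pattern.n_stop})"
    )
# The slow-pump session occludes >3 beats per cycle and its surviving
# fraction falls below 1/2 - the attack over-suppresses when the plant
# cannot keep up with the heartbeat.
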