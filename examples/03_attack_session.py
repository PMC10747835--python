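"""One full Pattern-A attack session.

The controller suppresses 3 of every 6 heartbeats at the wrist by
inflating the cuff in rhythm with the wearer's own pulse; the
heart-rate pipeline then reads the attacked (distal) and unattacked
(proximal) traces. With an ideal plant the displayed rate converges to
half the true rate.
"""

from cuffsim import PatternSpec, PlantParams, SubjectProfile, run_session, theoretical_ratio

subject = SubjectProfile(true_hr_bpm=80.0, hr_jitter_sd=0.0, noise_sd_counts=0.0)
pattern = PatternSpec.A(3)  # suppress 3, let 3 appear

res = run_session(
    subject,
    pattern,
    plant=PlantParams.ideal(),
    duration_s=120.0,
    seed=1,
    x_air_max=400.0,
)

print(f"pattern {pattern.name}: N_stop={pattern.n_stop}, N_appear={pattern.n_appear}")
print(f"theoretical displayed/true ratio: {theoretical_ratio(pattern):.3f}")
print(f"completed attack cycles: {res.log.completed_cycles()}")
print(f"surviving-beat fraction (session log): {res.log.surviving_fraction():.3f}")
print(f"end-of-session true rate:      {res.end_of_session_true:6.1f} bpm")
print(f"end-of-session displayed rate: {res.end_of_session_displayed:6.1f} bpm")
print(f"verdict (±15 bpm rule): {res.verdict}")
# The displayed value sits at ~40 bpm against a true 80 bpm: the
# attacked sensor sees only every other group of three heartbeats.
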