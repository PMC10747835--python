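"""Cuff occlusion curve and the pressure calibration search.

Shows how pulse amplitude rolls off with cuff pressure, then runs the
closed-loop grid search that finds the subject's working pressure
x_air_max: start at 400 counts, test whether the distal pulse
disappears (no peak for 2 s), step down by 20 until it survives, and
return the last disappearing grid value.
"""

from cuffsim import PlantParams, SubjectProfile, occlusion_attenuation, run_calibration
from cuffsim.controller import CalibrationConfig

subject = SubjectProfile.sharp(310.0, noise_sd_counts=2.0)

print("pressure -> relative pulse amplitude (occlusion threshold 310):")
for p in range(0, 451, 50):
    a = occlusion_attenuation(p, subject.occlusion_threshold_counts, subject.occlusion_softness)
    print(f"  {p:4d} counts: {a:6.3f}")

result = run_calibration(PlantParams(), subject, CalibrationConfig(), seed=3)
print("\ncalibration trials (target pressure, pulse disappeared?):")
for target, gone in result.trials:
    print(f"  {target:5.0f}  {'disappeared' if gone else 'still visible'}")
print(f"calibrated x_air_max = {result.x_air_max:.0f} counts")
# 320 is the smallest 400-20k grid value above this subject's 310-count
# occlusion threshold: the weakest pressure that still stops the pulse.
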