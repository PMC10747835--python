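# Pattern C: more suppressed than appearing -> displayed rate = 1/3 of
# true; at resting rates that lands below most watches' display floor.
subject:
  true_hr_bpm: 80
  hr_jitter_sd: 0.01
  noise_sd_counts: 2
  occlusion_threshold_counts: 300
  occlusion_softness: 20
plant:
  pump_rate_counts_per_s: 800
  vent_rate_counts_per_s: 800
pattern:
  name: C
  n_stop: 4
  n_appear: 2
watch: garmin
duration_s: 120
seed: 1
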