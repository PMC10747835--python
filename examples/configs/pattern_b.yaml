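# Pattern B: more appearing than suppressed -> displayed rate = 2/3 of true.
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
  name: B
  n_stop: 2
  n_appear: 4
watch: none
duration_s: 120
seed: 1
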