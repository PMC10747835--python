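# Display limits measured on commercial wearables (output shown for
# out-of-range synthetic input heart rates).
watches:
  fitbit:
    min_display: 54
    max_display: 201
  apple:
    min_display: 44
    max_display: 210
  garmin:
    min_display: 45
    max_display: 189
  paenoon:
    min_display: 48
    max_display: 180
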