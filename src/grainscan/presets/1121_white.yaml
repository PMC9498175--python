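# Illustrative preset for 1121 White. Thresholds are starting points,
# not trade standards; tune per contract.
name: 1121 White
broken_threshold_mm: 6.2
yellow_range:
  lower:
  - 20
  - 80
  - 80
  upper:
  - 35
  - 255
  - 255
chalky_range:
  lower:
  - 0
  - 0
  - 200
  upper:
  - 179
  - 40
  - 255
yellow_flag_threshold: 0.3
chalky_flag_threshold: 0.3
sanity_length_mm: 15.0
reference_diameter_mm: 22.5
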