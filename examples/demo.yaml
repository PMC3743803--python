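# Full-scale demo: 9 provinces x 6 districts x 5 municipalities (270 units),
# 2,500 adults per municipality, 27% planted hotspots at 2.2x baseline.
seed: 1
alpha: 0.05
screen_threshold: 0.10
sandwich: cr0
removal_rule: multiplicative
removal_depth: 3
generator:
  n_provinces: 9
  districts_per_province: 6
  municipalities_per_district: 5
  persons_per_municipality: 2500
  baseline_rate: 0.0145
  hotspot_fraction: 0.27
  hotspot_rate_multiplier: 2.2
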