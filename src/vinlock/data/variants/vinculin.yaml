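# Wild-type human vinculin — generator ground truth.
# Fields marked "free" are not printed anywhere and were chosen once so that
# the consumer modules reproduce the printed counts/onsets.
name: vinculin
mass_da: 117000.0            # free; consistent with envelope centered near 5,700 m/z at ~20+
charge_weights:              # relative intensities; 7 states >= 5% of base peak (17+..23+)
  16: 0.02
  17: 0.07
  18: 0.13
  19: 0.40
  20: 0.85
  21: 1.00
  22: 0.60
  23: 0.16
  24: 0.03
peak_width_mz: 8.0           # free
ciu_charge: 17
state_ccs:                   # experimental CIU state centroids (A^2); widths free
  C:  {centroid: 6266.0, width: 120.0}
  SO: {centroid: 6970.0, width: 120.0}
  O:  {centroid: 7268.0, width: 130.0}
transitions:                 # logistic gates; midpoint/sharpness place the 10%-presence
  c_so: {midpoint_v: 160.0, sharpness_v: 9.6}   # onsets at 140 V (SO) / 180 V (C gone): gradual
  so_o: {midpoint_v: 205.0, sharpness_v: 9.0}
extended_fraction: 0.0
extended_ccs_min: 7600.0
extended_ccs_max: 13200.0
fa_lognormal: {mu: -0.5, sigma: 0.6}   # free; small (<1 um^2) FAs enriched
decay: {rate_per_min: 0.02, plateau: 0.4}   # initial slope 100*rate*(1-plateau) = 1.2 %/min
bleach_rate_per_min: 0.005   # free
seed: 7
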