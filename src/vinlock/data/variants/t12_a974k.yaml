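# Vinculin-T12-A974K — T12 plus an extra positive charge at the Vt-D4 interface.
name: t12_a974k
mass_da: 116790.0            # free
charge_weights:              # 16 states >= 5% of base peak (17+..32+)
  16: 0.02
  17: 0.08
  18: 0.15
  19: 0.30
  20: 0.50
  21: 0.70
  22: 0.90
  23: 1.00
  24: 1.00
  25: 0.95
  26: 0.85
  27: 0.70
  28: 0.50
  29: 0.35
  30: 0.20
  31: 0.12
  32: 0.08
  33: 0.02
peak_width_mz: 8.0
ciu_charge: 17
state_ccs:
  C:  {centroid: 6164.0, width: 120.0}
  SO: {centroid: 6850.0, width: 120.0}
  O:  {centroid: 7279.0, width: 130.0}
transitions:
  c_so: {midpoint_v: 124.0, sharpness_v: 2.2}   # early (120 V) like T12
  so_o: {midpoint_v: 150.0, sharpness_v: 5.0}   # SO unstable: narrow dwell
extended_fraction: 0.0
extended_ccs_min: 7600.0
extended_ccs_max: 13200.0
fa_lognormal: {mu: 0.15, sigma: 0.6}
decay: {rate_per_min: 0.035, plateau: 0.4}   # destabilizes FAs; free
bleach_rate_per_min: 0.005
seed: 7
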