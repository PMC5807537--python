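# Vinculin-T12 (D974A, K975A, R976A, R978A) — weakened Vt-D4 interface.
name: t12
mass_da: 116730.0            # free; WT minus the four substituted side chains
charge_weights:              # 11 states >= 5% of base peak (17+..27+)
  16: 0.02
  17: 0.09
  18: 0.20
  19: 0.45
  20: 0.70
  21: 0.90
  22: 1.00
  23: 0.90
  24: 0.70
  25: 0.45
  26: 0.22
  27: 0.10
  28: 0.02
peak_width_mz: 8.0
ciu_charge: 17
state_ccs:
  C:  {centroid: 6108.0, width: 120.0}
  SO: {centroid: 6847.0, width: 120.0}
  O:  {centroid: 7173.0, width: 130.0}
transitions:
  c_so: {midpoint_v: 124.0, sharpness_v: 2.2}   # early (120 V) and abrupt
  so_o: {midpoint_v: 200.0, sharpness_v: 8.0}   # SO long-lived
extended_fraction: 0.0
extended_ccs_min: 7600.0
extended_ccs_max: 13200.0
fa_lognormal: {mu: 0.1, sigma: 0.6}    # larger/longer FAs
decay: {rate_per_min: 0.0, plateau: 1.0}   # completely stabilized FAs
bleach_rate_per_min: 0.005
seed: 7
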