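# Metavinculin (68-residue acidic insert between hinge and tail).
name: metavinculin
mass_da: 124400.0            # free; vinculin + ~7.4 kDa insert
charge_weights:              # compact envelope (17+-28+) plus broad extended hump (29+-55+)
  17: 0.28
  18: 0.49
  19: 0.73
  20: 0.92
  21: 1.00
  22: 0.92
  23: 0.73
  24: 0.49
  25: 0.28
  26: 0.14
  27: 0.09
  28: 0.07
  29: 0.10
  30: 0.12
  31: 0.14
  32: 0.17
  33: 0.20
  34: 0.23
  35: 0.26
  36: 0.29
  37: 0.32
  38: 0.34
  39: 0.35
  40: 0.36
  41: 0.35
  42: 0.34
  43: 0.32
  44: 0.29
  45: 0.26
  46: 0.23
  47: 0.20
  48: 0.17
  49: 0.14
  50: 0.12
  51: 0.10
  52: 0.09
  53: 0.08
  54: 0.07
  55: 0.06
peak_width_mz: 8.0
ciu_charge: 17
state_ccs:
  C:  {centroid: 6281.0, width: 120.0}
  SO: {centroid: 7056.0, width: 120.0}
  O:  {centroid: 7363.0, width: 130.0}
transitions:
  c_so: {midpoint_v: 144.0, sharpness_v: 2.2}   # abrupt at ~140 V
  so_o: {midpoint_v: 200.0, sharpness_v: 8.0}
extended_fraction: 0.40       # ~40% extended/unfolded in solution
extended_ccs_min: 7600.0      # free; clearly above the compact mode
extended_ccs_max: 13200.0     # "up to 13,200 A^2"
compact_charge_range: [19, 24]
extended_charge_range: [25, 56]
fa_lognormal: {mu: -0.3, sigma: 0.6}
decay: {rate_per_min: 0.033, plateau: 0.4}   # destabilizes FAs (steeper than WT); free
bleach_rate_per_min: 0.005
seed: 7
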