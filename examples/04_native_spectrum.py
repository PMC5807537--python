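"""Native spectra: charge-state envelopes of the four vinculin forms.

Generates each variant's synthetic native spectrum and counts the major
charge states.  A folded, compact protein holds few charges; partially
unfolded material pushes the envelope to many more charges.
"""

from vinlock import VARIANT_NAMES, load_variant, detect_charge_states
from vinlock.synthgen import gen_spectrum

for name in VARIANT_NAMES:
    v = load_variant(name)
    spectrum = gen_spectrum(v, seed=7)
    css = detect_charge_states(spectrum, min_rel_intensity=0.05)
    zs = css.major_charges
    print(f"{name:13s}: {css.n_major:2d} major charge states "
          f"({min(zs)}+..{max(zs)}+), envelope center {css.envelope_center_mz:5.0f} m/z, "
          f"inferred mass {css.inferred_mass:9.0f} Da "
          f"(err {100 * abs(css.inferred_mass - v.mass_da) / v.mass_da:.3f}%)")

print()
print("Wild-type vinculin shows a narrow 7-state envelope near 5,700 m/z —")
print("a single compact conformer.  The broad high-charge wing of")
print("metavinculin (into the 29+-55+ region) signals a large population")
print("of extended molecules already present in solution.")
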