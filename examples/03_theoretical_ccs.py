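"""Theoretical cross sections of closed and progressively opened models.

Builds a head+tail dumbbell with vinculin-like residue numbering, computes
its projection-approximation CCS, then rigidly pulls the tail away in a
tether-respecting scan and shows the CCS growing with separation — the
geometric signature behind the closed / semi-open / open assignment.
"""

import numpy as np
import biotite.structure as struc

from vinlock import DomainPartition, PaParams, pa_ccs, scan_opening, assign_state_models
from vinlock.structio import Structure

rng = np.random.default_rng(42)
head = rng.normal(0, 6, (400, 3))
tail = rng.normal(0, 4, (150, 3)) + [18.0, 0, 0]
coords = np.vstack([head, tail])
n = len(coords)
arr = struc.AtomArray(n)
arr.coord = coords.astype(np.float32)
arr.chain_id[:] = "A"
arr.res_id[:] = np.concatenate([
    np.linspace(1, 835, 400).astype(int),
    np.linspace(896, 1066, 150).astype(int),
])
arr.res_name[:] = "GLY"; arr.atom_name[:] = "CA"; arr.element[:] = "C"
arr.set_annotation("occupancy", np.ones(n, dtype=np.float32))
s = Structure(arr, "dumbbell")

p = PaParams(n_orientations=300, seed=42)
closed = pa_ccs(s, p)
print(f"closed-state CCS: {closed.value:.0f} +- {closed.sd:.0f} A^2")

part = DomainPartition.default()
scan = scan_opening(s, part, [0.0, 40.0, 80.0, 125.0], n_poses_per_sep=3,
                    seed=42, markers=(896, 835), max_tether=200, pa_params=p)
print(scan[["separation", "ccs_mean", "ccs_sd", "n_poses"]].round(0)
      .to_string(index=False))

target = closed.value * 1.18
hits = assign_state_models({"SO": target}, scan, tolerance=0.05)
print(f"\nmodels within 5% of a semi-open-like CCS ({target:.0f} A^2): "
      f"separations {hits['SO']['separation'].tolist()}")

print()
print("CCS rises monotonically as the tail leaves the head: an opened")
print("conformer is distinguishable by cross section alone, though several")
print("distinct geometries can share one CCS (the match is one-to-many).")
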