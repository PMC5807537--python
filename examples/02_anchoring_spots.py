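"""Anchoring spots: where single side chains bind a surface pocket.

Builds a concave receptor (an open bowl with an acidic glutamate pair on
its floor), detects the pocket, scatters seeded lysine/arginine probes and
reports the best binding free energy per probe type.  A planted partner
lysine shows how spots are matched back to residues of a binding partner.
"""

import numpy as np
import biotite.structure as struc

from vinlock.structio import Structure
from vinlock.anchors import (
    detect_cavities, map_anchoring_spots, match_spots_to_partner, spots_table,
)

g = np.arange(-8, 8.1, 1.8)
X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
pts = np.stack([X, Y, Z], -1).reshape(-1, 3)
r = np.linalg.norm(pts, axis=1)
bowl = pts[(r <= 8) & (r >= 4.5) & (pts[:, 2] <= 1.0)]
coords = np.vstack([bowl, [[0.9, 0, -4.4], [-0.9, 0, -4.4]]])
n = len(coords)
arr = struc.AtomArray(n)
arr.coord = coords.astype(np.float32)
arr.chain_id[:] = "A"
arr.res_id[:] = list(range(1, n - 1)) + [500, 500]
arr.res_name[:] = ["GLY"] * (n - 2) + ["GLU", "GLU"]
arr.atom_name[:] = ["CA"] * (n - 2) + ["OE1", "OE2"]
arr.element[:] = ["C"] * (n - 2) + ["O", "O"]
arr.set_annotation("occupancy", np.ones(n, dtype=np.float32))
receptor = Structure(arr, "acidic-bowl")

cavities = detect_cavities(receptor, grid_spacing=0.8)
print(f"{len(cavities)} cavity found; centroid {np.round(cavities[0].centroid, 1)}, "
      f"depth {cavities[0].depth:.1f} A")

spots = map_anchoring_spots(receptor, probe_types="KR", seed=7, n_starts=60)
print(spots_table(spots)[["probe", "delta_g", "vdw", "solvation",
                          "electrostatic", "strong"]].round(2).to_string(index=False))

# a partner chain whose lysine reaches into the pocket
best = spots[0]
nz = best.best_pose.coords[best.best_pose.atom_names.index("NZ")]
parr = struc.AtomArray(1)
parr.coord = np.asarray([nz + [0.3, 0, 0]], dtype=np.float32)
parr.chain_id[:] = "B"; parr.res_id[:] = 975
parr.res_name[:] = "LYS"; parr.atom_name[:] = "NZ"; parr.element[:] = "N"
parr.set_annotation("occupancy", np.ones(1, dtype=np.float32))
match_spots_to_partner(spots, Structure(parr, "partner"))
print(f"best spot matched to partner residue: {spots[0].matched_residue}")

print()
print("Negative dG marks a favourable single-residue anchor; spots at or")
print("below -3 kcal/mol are 'strong' — few strong anchors at an interface")
print("means it unlocks more readily.")
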