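"""Surface-cavity detection and single-residue anchoring-spot mapping.

An anchoring spot is a small concave patch on a protein surface together
with the single amino-acid side chain that binds it favourably — the
computational analogue of an interface hot-spot residue.  The mapper
scatters rigid side-chain probes (from C-beta outward; Thr and Ile keep
C-alpha) around detected cavities, locally optimises each pose and scores
it with a semi-empirical function:

    dG = vdW (Lennard-Jones)
       + electrostatic (Coulomb, distance-dependent dielectric eps(r) = 4r,
         deepened by probe burial)
       + solvation (atomic-solvation-parameter x buried-area estimate)

Absolute dG values from this lightweight force field are NOT meant to be
quantitative; the supported claims are the identities of anchor residues
and relative counts between interfaces.  Spots with dG <= strong_cutoff
(default -3 kcal/mol) are flagged "strong".  Every stochastic step is
seeded and bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structio import Structure

__all__ = [
    "Cavity",
    "ProbePose",
    "AnchoringSpot",
    "CavityParams",
    "ForceFieldParams",
    "PROBE_LIBRARY",
    "detect_cavities",
    "score_probe",
    "map_anchoring_spots",
    "match_spots_to_partner",
    "spots_table",
]


# ---------------------------------------------------------------------------
# Probe library: one canonical, rigid rotamer per type, side chain from CB
# (CA retained for Thr/Ile).  Coordinates are ideal-geometry constructs
# (1.52 A C-C, 1.47 A C-N, 1.25 A carboxylate/amide C-O, tetrahedral
# zig-zag backfall, planar guanidinium/phenyl).

def _zigzag(n: int, bond: float = 1.52) -> np.ndarray:
    """n atoms in an all-trans zig-zag chain along +x."""
    dx = bond * np.sin(np.deg2rad(54.75))
    dy = bond * np.cos(np.deg2rad(54.75))
    pts = np.zeros((n, 3))
    for i in range(n):
        pts[i] = (i * dx, dy * (i % 2), 0.0)
    return pts


def _branch(origin, direction, bond):
    d = np.asarray(direction, dtype=float)
    return origin + bond * d / np.linalg.norm(d)


def _build_probe(kind: str):
    """Return (atom names, elements, charges, coords) for one probe type."""
    if kind == "K":  # CB-CG-CD-CE-NZ, terminal ammonium +1
        xyz = _zigzag(5)
        names = ["CB", "CG", "CD", "CE", "NZ"]
        elements = ["C", "C", "C", "C", "N"]
        charges = [0, 0, 0, 0, 1.0]
    elif kind == "R":  # CB-CG-CD-NE-CZ + NH1/NH2, guanidinium +1 smeared
        base = _zigzag(5)
        nh1 = _branch(base[4], base[4] - base[3] + [0, 1.2, 0], 1.33)
        nh2 = _branch(base[4], base[4] - base[3] + [0, -1.2, 0], 1.33)
        xyz = np.vstack([base, nh1, nh2])
        names = ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"]
        elements = ["C", "C", "C", "N", "C", "N", "N"]
        charges = [0, 0, 0, 0, 0.34, 0.33, 0.33]
    elif kind == "E":  # CB-CG-CD + carboxylate -1
        base = _zigzag(3)
        oe1 = _branch(base[2], base[2] - base[1] + [0, 1.1, 0], 1.25)
        oe2 = _branch(base[2], base[2] - base[1] + [0, -1.1, 0], 1.25)
        xyz = np.vstack([base, oe1, oe2])
        names = ["CB", "CG", "CD", "OE1", "OE2"]
        elements = ["C", "C", "C", "O", "O"]
        charges = [0, 0, 0, -0.5, -0.5]
    elif kind == "N":  # CB-CG + amide dipole
        base = _zigzag(2)
        od1 = _branch(base[1], base[1] - base[0] + [0, 1.1, 0], 1.23)
        nd2 = _branch(base[1], base[1] - base[0] + [0, -1.1, 0], 1.33)
        xyz = np.vstack([base, od1, nd2])
        names = ["CB", "CG", "OD1", "ND2"]
        elements = ["C", "C", "O", "N"]
        charges = [0, 0, -0.38, 0.38]
    elif kind == "T":  # CA retained; CB + OG1/CG2
        base = _zigzag(2)  # CA, CB
        og1 = _branch(base[1], base[1] - base[0] + [0, 1.1, 0], 1.42)
        cg2 = _branch(base[1], base[1] - base[0] + [0, -1.1, 0], 1.52)
        xyz = np.vstack([base, og1, cg2])
        names = ["CA", "CB", "OG1", "CG2"]
        elements = ["C", "C", "O", "C"]
        charges = [0, 0, -0.2, 0]
    elif kind == "I":  # CA retained; branched aliphatic
        base = _zigzag(2)  # CA, CB
        cg1 = _branch(base[1], base[1] - base[0] + [0, 1.1, 0], 1.52)
        cg2 = _branch(base[1], base[1] - base[0] + [0, -1.1, 0], 1.52)
        cd1 = _branch(cg1, cg1 - base[1], 1.52)
        xyz = np.vstack([base, cg1, cg2, cd1])
        names = ["CA", "CB", "CG1", "CG2", "CD1"]
        elements = ["C"] * 5
        charges = [0] * 5
    elif kind == "P":  # pyrrolidine fragment
        xyz = _zigzag(3)
        names = ["CB", "CG", "CD"]
        elements = ["C", "C", "C"]
        charges = [0, 0, 0]
    elif kind == "F":  # CB + phenyl ring
        cb = np.zeros(3)
        cg = np.array([1.50, 0.0, 0.0])
        ring = []
        r = 1.39
        center = cg + np.array([r, 0, 0])
        for ang in (120, 240, 60, 300, 0):
            a = np.deg2rad(ang)
            ring.append(center + r * np.array([np.cos(np.pi + a), np.sin(np.pi + a), 0]))
        xyz = np.vstack([cb, cg] + ring)
        names = ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        elements = ["C"] * 7
        charges = [0] * 7
    else:
        raise KeyError(f"no probe template for type {kind!r}")
    return names, elements, np.asarray(charges, float), np.asarray(xyz, float)


PROBE_LIBRARY: dict[str, tuple] = {k: _build_probe(k) for k in "KRENTIPF"}


@dataclass
class ProbePose:
    """A rigid placement of one side-chain probe."""

    probe_type: str
    atom_names: list[str]
    elements: np.ndarray
    charges: np.ndarray
    coords: np.ndarray  # (n, 3), already transformed

    @classmethod
    def from_template(cls, kind: str, rotation: np.ndarray, translation: np.ndarray):
        names, elements, charges, xyz = PROBE_LIBRARY[kind]
        coords = xyz @ np.asarray(rotation).T + np.asarray(translation)
        return cls(kind, list(names), np.asarray(elements), charges.copy(), coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProbePose":
        center = self.coords.mean(axis=0)
        coords = (self.coords - center) @ np.asarray(rotation).T + center + translation
        return ProbePose(self.probe_type, self.atom_names, self.elements,
                         self.charges, coords)


@dataclass
class Cavity:
    centroid: np.ndarray      # A
    mouth_radius: float       # A
    depth: float              # A (buriedness-scaled heuristic, > 0)
    lining_atom_idx: np.ndarray  # indices into the receptor structure
    n_points: int = 0


@dataclass
class AnchoringSpot:
    cavity: Cavity
    best_pose: ProbePose
    delta_g: float                       # kcal/mol
    components: dict[str, float]         # vdw / solvation / electrostatic
    strong: bool
    matched_residue: str | None = None


# ---------------------------------------------------------------------------
# Cavity detection

@dataclass
class CavityParams:
    grid_spacing: float = 0.8        # A
    solvent_clearance: float = 2.6   # min distance to any atom centre
    shell_limit: float = 4.2         # max distance to the nearest atom centre
    n_ray_directions: int = 32       # buriedness ray fan (Fibonacci sphere)
    ray_length: float = 8.0          # A
    ray_step: float = 1.0            # A
    ray_hit_dist: float = 2.0        # a sample closer than this to an atom blocks
    burial_threshold: float = 0.55   # fraction of blocked rays => pocket
    min_points: int = 5              # minimum cluster size
    lining_cutoff: float = 5.0


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def detect_cavities(
    s: Structure, grid_spacing: float = 0.8, params: CavityParams | None = None
) -> list[Cavity]:
    """Grid-based surface pockets scored by ray-cast buriedness.

    Solvent-shell grid points (outside every van der Waals sphere but near
    the surface) cast a fan of rays; a point belongs to a pocket when more
    than ``burial_threshold`` of its rays hit an atom within ``ray_length``.
    A point hovering over a convex body blocks at most about half its rays,
    so convex fixtures yield no cavities.  Pocket points are clustered into
    connected components and returned sorted by depth (mean excess burial
    scaled to A, floored by the lining-extent bound).
    """
    params = params or CavityParams()
    params.grid_spacing = grid_spacing
    if s.n_atoms < 50:
        warnings.warn("structure too small for a meaningful surface; no cavities")
        return []
    coords = s.coord.astype(float)
    tree = cKDTree(coords)
    lo = coords.min(axis=0) - 2.0
    hi = coords.max(axis=0) + 2.0
    axes = [np.arange(l, h + grid_spacing, grid_spacing) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    d_near, _ = tree.query(grid, k=1)
    shell = (d_near > params.solvent_clearance) & (d_near < params.shell_limit)
    pts = grid[shell]
    if len(pts) == 0:
        return []

    dirs = _fibonacci_sphere(params.n_ray_directions)
    steps = np.arange(params.ray_step, params.ray_length + 1e-9, params.ray_step)
    # (n_pts, n_dirs, n_steps, 3) ray samples, flattened for one KD query
    samples = (pts[:, None, None, :]
               + dirs[None, :, None, :] * steps[None, None, :, None])
    d_samp, _ = tree.query(samples.reshape(-1, 3))
    blocked = (d_samp.reshape(len(pts), len(dirs), len(steps))
               < params.ray_hit_dist).any(axis=2)
    burial = blocked.mean(axis=1)
    pocket = burial >= params.burial_threshold
    pocket_pts = pts[pocket]
    pocket_burial = burial[pocket]
    if len(pocket_pts) == 0:
        return []

    # connected components on the pocket point cloud
    ptree = cKDTree(pocket_pts)
    n = len(pocket_pts)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in ptree.query_pairs(grid_spacing * 1.8):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])

    cavities: list[Cavity] = []
    for root in np.unique(roots):
        members = roots == root
        if members.sum() < params.min_points:
            continue
        cpts = pocket_pts[members]
        cbur = pocket_burial[members]
        centroid = cpts.mean(axis=0)
        mouth = float(np.max(np.linalg.norm(cpts - centroid, axis=1))) + grid_spacing
        depth = float(np.mean(cbur - params.burial_threshold + 0.05)) \
            * params.ray_length
        lining = np.unique(np.concatenate(
            tree.query_ball_point(cpts, params.lining_cutoff)
        )).astype(int)
        far = float(np.max(np.linalg.norm(coords[lining] - centroid, axis=1)))
        depth = max(depth, far - mouth, 0.1)
        cavities.append(Cavity(centroid, mouth, depth, lining, len(cpts)))
    cavities.sort(key=lambda c: -c.depth)
    return cavities


# ---------------------------------------------------------------------------
# Scoring

# united-atom Lennard-Jones (Rmin/2 in A, epsilon in kcal/mol) per element
_LJ = {
    "C": (1.95, 0.12),
    "N": (1.70, 0.17),
    "O": (1.60, 0.21),
    "S": (2.00, 0.25),
    "H": (1.00, 0.02),
    "P": (2.10, 0.20),
}
# atomic solvation parameters, kcal / (mol A^2): hydrophobic burial is
# favourable, polar burial mildly unfavourable, charged burial costly
_ASP = {"C": -0.016, "N": 0.006, "O": 0.006, "S": -0.010, "H": 0.0, "P": 0.006}
_ASP_CHARGED = 0.024

# formal charges smeared on receptor side-chain termini
_RECEPTOR_CHARGES = {
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.4, ("ARG", "NH2"): 0.4, ("ARG", "NE"): 0.2,
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
}

_COULOMB = 332.0636  # kcal mol^-1 A e^-2


@dataclass
class ForceFieldParams:
    clash_cutoff: float = 2.0
    interaction_cutoff: float = 9.0
    dielectric_slope: float = 4.0       # eps(r) = slope * r
    burial_length: float = 4.0          # A, burial counting kernel width
    burial_scale: float = 0.35          # per-neighbour occlusion weight
    solvation_probe: float = 1.4


def receptor_charges(s: Structure) -> np.ndarray:
    q = np.zeros(s.n_atoms)
    for i in range(s.n_atoms):
        q[i] = _RECEPTOR_CHARGES.get(
            (str(s.atoms.res_name[i]), str(s.atoms.atom_name[i])), 0.0
        )
    return q


def _burial(pose_coords, rec_coords, tree, p: ForceFieldParams) -> np.ndarray:
    """Smooth per-probe-atom burial fraction in [0, 1)."""
    b = np.zeros(len(pose_coords))
    for i, x in enumerate(pose_coords):
        idx = tree.query_ball_point(x, p.interaction_cutoff)
        if not idx:
            continue
        r = np.linalg.norm(rec_coords[idx] - x, axis=1)
        occl = np.sum(np.exp(-((r / p.burial_length) ** 2)))
        b[i] = 1.0 - np.exp(-p.burial_scale * occl)
    return b


def score_probe(
    s: Structure,
    pose: ProbePose,
    params: ForceFieldParams | None = None,
    _tree: cKDTree | None = None,
    _charges: np.ndarray | None = None,
) -> tuple[float, dict[str, float]]:
    """dG (kcal/mol) of one rigid probe pose with vdW/solvation/electrostatic
    components.  Clashing poses (any contact < clash_cutoff) score +inf.
    Deterministic, and invariant under joint rigid motion of receptor+pose.
    """
    p = params or ForceFieldParams()
    rec = s.coord.astype(float)
    tree = _tree if _tree is not None else cKDTree(rec)
    qrec = _charges if _charges is not None else receptor_charges(s)

    vdw = elec = solv = 0.0
    burial = _burial(pose.coords, rec, tree, p)
    for i, x in enumerate(pose.coords):
        idx = tree.query_ball_point(x, p.interaction_cutoff)
        if not idx:
            continue
        rvec = rec[idx] - x
        r = np.linalg.norm(rvec, axis=1)
        if np.any(r < p.clash_cutoff):
            return float("inf"), {"vdw": float("inf"),
                                  "solvation": 0.0, "electrostatic": 0.0}
        el_p = str(pose.elements[i])
        r0p, ep = _LJ.get(el_p, _LJ["C"])
        for j, rj in zip(idx, r):
            el_r = str(s.atoms.element[j]) or "C"
            r0r, er = _LJ.get(el_r, _LJ["C"])
            r0 = r0p + r0r
            eps = np.sqrt(ep * er)
            sr6 = (r0 / rj) ** 6
            vdw += eps * (sr6 * sr6 - 2.0 * sr6)
            qq = pose.charges[i] * qrec[j]
            if qq != 0.0:
                # eps(r)=4r, deepened as the probe buries into the receptor
                elec += _COULOMB * qq / (p.dielectric_slope * rj * rj) \
                    * (0.5 + 0.5 * burial[i])
        area_i = 4.0 * np.pi * (_LJ.get(el_p, _LJ["C"])[0] + p.solvation_probe) ** 2
        sigma = _ASP_CHARGED if abs(pose.charges[i]) >= 0.3 \
            else _ASP.get(el_p, _ASP["C"])
        solv += sigma * area_i * burial[i]
    total = vdw + elec + solv
    return float(total), {
        "vdw": float(vdw),
        "solvation": float(solv),
        "electrostatic": float(elec),
    }


# ---------------------------------------------------------------------------
# Mapping

def _optimize_pose(s, pose, params, tree, charges, maxfev=120):
    """Local rigid-body refinement (3 translations + 3 rotation-vector dof)."""
    center0 = pose.coords.mean(axis=0)

    def objective(x):
        rot = Rotation.from_rotvec(x[3:]).as_matrix()
        cand = ProbePose(pose.probe_type, pose.atom_names, pose.elements,
                         pose.charges,
                         (pose.coords - center0) @ rot.T + center0 + x[:3])
        val, _ = score_probe(s, cand, params, tree, charges)
        return val if np.isfinite(val) else 1e6

    res = minimize(objective, np.zeros(6), method="Powell",
                   options={"maxfev": maxfev, "xtol": 1e-2, "ftol": 1e-3})
    rot = Rotation.from_rotvec(res.x[3:]).as_matrix()
    best = ProbePose(pose.probe_type, pose.atom_names, pose.elements, pose.charges,
                     (pose.coords - center0) @ rot.T + center0 + res.x[:3])
    return best


def map_anchoring_spots(
    receptor: Structure,
    probe_types: str | list[str] = "KRENTIPF",
    strong_cutoff: float = -3.0,
    seed: int = 7,
    n_starts: int = 500,
    cavities: list[Cavity] | None = None,
    grid_spacing: float = 0.8,
    ff: ForceFieldParams | None = None,
) -> list[AnchoringSpot]:
    """Best probe pose per (cavity, probe type); strong iff dG <= cutoff.

    Seeded and reproducible: identical seeds give bit-identical spots.
    """
    if receptor.n_atoms == 0:
        raise ValueError("empty receptor")
    ff = ff or ForceFieldParams()
    if cavities is None:
        cavities = detect_cavities(receptor, grid_spacing)
    rng = np.random.default_rng(seed)
    tree = cKDTree(receptor.coord.astype(float))
    charges = receptor_charges(receptor)
    spots: list[AnchoringSpot] = []
    for cavity in cavities:
        for kind in probe_types:
            best_val = np.inf
            best_pose = None
            best_comp = None
            for _ in range(n_starts):
                pos = cavity.centroid + rng.normal(0.0, 2.0, 3)
                rot = Rotation.random(rng=rng).as_matrix()
                pose = ProbePose.from_template(kind, rot, pos -
                                               PROBE_LIBRARY[kind][3].mean(axis=0))
                val, comp = score_probe(receptor, pose, ff, tree, charges)
                if not np.isfinite(val):
                    continue
                if val < best_val:
                    best_val, best_pose, best_comp = val, pose, comp
            if best_pose is None:
                continue
            best_pose = _optimize_pose(receptor, best_pose, ff, tree, charges)
            best_val, best_comp = score_probe(receptor, best_pose, ff, tree, charges)
            spots.append(AnchoringSpot(
                cavity=cavity, best_pose=best_pose, delta_g=best_val,
                components=best_comp, strong=best_val <= strong_cutoff,
            ))
    spots.sort(key=lambda sp: sp.delta_g)
    return spots


_PROBE_TO_RESNAME = {"K": "LYS", "R": "ARG", "E": "GLU", "N": "ASN",
                     "T": "THR", "I": "ILE", "P": "PRO", "F": "PHE"}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def match_spots_to_partner(
    spots: list[AnchoringSpot], partner: Structure, match_radius: float = 2.0
) -> list[AnchoringSpot]:
    """Fill ``matched_residue`` with the partner residue of the same type
    whose side chain lies within ``match_radius`` of the best pose."""
    if partner.n_atoms == 0:
        for sp in spots:
            sp.matched_residue = None
        return spots
    atoms = partner.atoms
    side = ~np.isin(atoms.atom_name, list(_BACKBONE))
    for sp in spots:
        want = _PROBE_TO_RESNAME[sp.best_pose.probe_type]
        mask = side & (atoms.res_name == want)
        sp.matched_residue = None
        if not mask.any():
            continue
        coords = atoms.coord[mask].astype(float)
        d = np.linalg.norm(
            coords[:, None, :] - sp.best_pose.coords[None, :, :], axis=-1
        ).min(axis=1)
        res_ids = atoms.res_id[mask]
        chain_ids = atoms.chain_id[mask]
        per_res: dict[tuple, float] = {}
        for rid, cid, dist in zip(res_ids, chain_ids, d):
            key = (str(cid), int(rid))
            per_res[key] = min(per_res.get(key, np.inf), float(dist))
        best_key = min(per_res, key=per_res.get)
        if per_res[best_key] <= match_radius:
            sp.matched_residue = f"{want[0]}{best_key[1]}"
    return spots


def spots_table(spots: list[AnchoringSpot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe": sp.best_pose.probe_type,
                "delta_g": sp.delta_g,
                "vdw": sp.components["vdw"],
                "solvation": sp.components["solvation"],
                "electrostatic": sp.components["electrostatic"],
                "strong": sp.strong,
                "matched_residue": sp.matched_residue,
                "cavity_x": sp.cavity.centroid[0],
                "cavity_y": sp.cavity.centroid[1],
                "cavity_z": sp.cavity.centroid[2],
            }
            for sp in spots
        ]
    )
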