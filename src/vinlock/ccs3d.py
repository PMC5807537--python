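"""Theoretical collision cross sections and rigid-body opening models.

CCS is computed with the projection approximation (PA): the mean, over
uniformly random orientations, of the area of the 2-D shadow cast by the
atoms drawn as disks of radius (element vdW radius + gas radius).  The
shadow area is measured by grid rasterisation.  PA underestimates CCS for
very concave shapes but tracks relative changes well, which is what the
opening analysis needs: the closed->semi-open->open models are built by
rigid displacement of the tail domain along a tether-respecting direction,
and their PA-CCS is compared with the experimentally calibrated values.

Coordinates are canonicalised (see ``structio.canonical_coords``) before
orientation sampling, so the value is exactly invariant under rigid motion
of the input for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DomainPartition
from .structio import Structure, canonical_coords

__all__ = [
    "PaParams",
    "CcsValue",
    "OpeningModel",
    "pa_ccs",
    "displace_tail",
    "scan_opening",
    "assign_state_models",
]

_DEFAULT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80,
}


@dataclass
class PaParams:
    atom_radii: dict = field(default_factory=lambda: dict(_DEFAULT_RADII))
    gas_radius: float = 1.0          # A; He-like default
    n_orientations: int = 3000
    grid_spacing: float = 1.0        # A
    scale_factor: float = 1.0
    seed: int = 42

    def __post_init__(self):
        if self.n_orientations < 100:
            raise ValueError("n_orientations must be >= 100")
        if any(r <= 0 for r in self.atom_radii.values()):
            raise ValueError("atom radii must be positive")


@dataclass
class CcsValue:
    value: float   # A^2
    sd: float      # A^2 (standard error over orientations, or replicate sd)
    method: str    # "projection_approx" or "calibrated_experimental"

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("CCS must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3, 3) uniform rotation matrices via normalized quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
    ], axis=1)


def _disk_offsets(radius: float, h: float) -> np.ndarray:
    """Integer grid offsets whose cell centres fall inside a disk."""
    m = int(np.ceil(radius / h))
    dx, dy = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    keep = (dx * h) ** 2 + (dy * h) ** 2 <= radius**2
    return np.stack([dx[keep], dy[keep]], axis=1)


def _projected_area(xy: np.ndarray, groups: list, h: float, offsets: list) -> float:
    lo = xy.min(axis=0)
    idx = np.floor((xy - lo) / h).astype(np.int64)
    pad = max(len(o) for o in offsets)  # offsets already bounded by radii
    margin = int(np.ceil(max(np.abs(o).max() if len(o) else 0 for o in offsets))) + 1
    dims = idx.max(axis=0) + 2 * margin + 1
    grid = np.zeros(dims[0] * dims[1], dtype=bool)
    for g, offs in zip(groups, offsets):
        if not len(g):
            continue
        cells = idx[g][:, None, :] + offs[None, :, :] + margin
        flat = cells[..., 0] * dims[1] + cells[..., 1]
        grid[flat.ravel()] = True
    return float(grid.sum()) * h * h


def pa_ccs(s: Structure, params: PaParams | None = None) -> CcsValue:
    """Projection-approximation CCS (A^2) of a structure.

    Mean shadow area over ``n_orientations`` seeded uniform rotations; the
    reported sd is the orientation standard error.  ``scale_factor``
    multiplies the final value (default 1.0).
    """
    p = params or PaParams()
    if s.n_atoms == 0:
        raise ValueError("empty structure")
    coords = canonical_coords(s.coord.astype(float))
    radii = np.array([
        p.atom_radii.get(str(e), _DEFAULT_RADII.get(str(e), 1.7)) + p.gas_radius
        for e in s.atoms.element
    ])
    uniq = np.unique(np.round(radii, 3))
    groups = [np.where(np.round(radii, 3) == r)[0] for r in uniq]
    offsets = [_disk_offsets(r, p.grid_spacing) for r in uniq]
    rng = np.random.default_rng(p.seed)
    rots = _random_rotations(p.n_orientations, rng)
    areas = np.empty(p.n_orientations)
    for i in range(p.n_orientations):
        xy = coords @ rots[i].T[:, :2]
        areas[i] = _projected_area(xy, groups, p.grid_spacing, offsets)
    value = float(areas.mean()) * p.scale_factor
    se = float(areas.std(ddof=1) / np.sqrt(p.n_orientations)) * p.scale_factor
    return CcsValue(value=value, sd=se, method="projection_approx")


# ---------------------------------------------------------------------------
# Opening models

@dataclass
class OpeningModel:
    base: Structure
    structure: Structure          # with the tail displaced
    moved_domain: str
    rotation: np.ndarray
    translation: np.ndarray
    separation: float             # A between marker C-alpha atoms
    clash_count: int
    ccs: CcsValue | None
    state_label: str = ""         # C / SO1 / SO2 / O, caller-assigned


def _marker_ca(s: Structure, residue: int, chain: str) -> np.ndarray:
    mask = (s.atoms.res_id == residue) & (s.atoms.chain_id == chain)
    ca = mask & (s.atoms.atom_name == "CA")
    pick = ca if ca.any() else mask
    if not pick.any():
        raise ValueError(f"marker residue {residue} absent on chain {chain}")
    return s.coord[pick][0].astype(float)


def displace_tail(
    s: Structure,
    partition: DomainPartition,
    rotation: np.ndarray | None = None,
    translation: np.ndarray = (0.0, 0.0, 0.0),
    markers: tuple[int, int] = (875, 836),
    moved_domain: str = "Vt",
    chain: str | None = None,
    max_tether: float = 140.0,
    max_clashes: int = 20,
    clash_dist: float = 2.0,
    pa_params: PaParams | None = None,
    compute_ccs: bool = True,
) -> OpeningModel:
    """Rigidly move the tail domain; non-tail atoms stay fixed.

    ``markers`` are residue numbers whose C-alpha separation defines the
    opening coordinate (default: a tail-proximal hinge residue against the
    last D4 residue).  Raises if the pose breaks the hinge tether or piles
    up more than ``max_clashes`` heavy-atom overlaps.
    """
    chain = chain or s.chains[0]
    rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
    translation = np.asarray(translation, float)

    moved_mask = np.zeros(s.n_atoms, dtype=bool)
    for lo, hi in partition.ranges(moved_domain):
        moved_mask |= (s.atoms.res_id >= lo) & (s.atoms.res_id <= hi)
    moved_mask &= s.atoms.chain_id == chain
    if not moved_mask.any():
        raise ValueError(f"no atoms for domain {moved_domain!r} on chain {chain}")

    atoms = s.atoms.copy()
    sub = atoms.coord[moved_mask].astype(float)
    pivot = sub.mean(axis=0)
    atoms.coord[moved_mask] = ((sub - pivot) @ rotation.T + pivot + translation
                               ).astype(np.float32)
    out = Structure(atoms, s.source_id)

    # tether: the moved domain's first residue must stay reachable from the
    # last static residue through an extended hinge
    vt_lo = min(lo for lo, _ in partition.ranges(moved_domain))
    static_res = s.atoms.res_id[~moved_mask & (s.atoms.chain_id == chain)]
    if len(static_res):
        anchor_res = int(static_res.max() if static_res.max() < vt_lo
                         else static_res[static_res < vt_lo].max())
        first_moved = _marker_ca(out, vt_lo, chain)
        anchor = _marker_ca(out, anchor_res, chain)
        tether = float(np.linalg.norm(first_moved - anchor))
        if tether > max_tether:
            raise ValueError(
                f"transform stretches the hinge to {tether:.0f} A "
                f"(max_tether {max_tether:.0f} A)"
            )

    # count only overlaps the transform introduces: contacts already present
    # in the closed-state input are part of its geometry, not a defect
    def _n_close(moved_xyz, static_xyz):
        if not len(static_xyz) or not len(moved_xyz):
            return 0
        from scipy.spatial import cKDTree

        return int(sum(
            len(h) for h in
            cKDTree(static_xyz).query_ball_point(moved_xyz, clash_dist)
        ))

    static_xyz = out.coord[~moved_mask].astype(float)
    base_close = _n_close(s.coord[moved_mask].astype(float), static_xyz)
    pose_close = _n_close(out.coord[moved_mask].astype(float), static_xyz)
    clash_count = max(0, pose_close - base_close)
    if clash_count > max_clashes:
        raise ValueError(
            f"pose rejected: {clash_count} new heavy-atom overlaps "
            f"(max {max_clashes})"
        )

    sep = float(np.linalg.norm(
        _marker_ca(out, markers[0], chain) - _marker_ca(out, markers[1], chain)
    ))
    ccs = pa_ccs(out, pa_params) if compute_ccs else None
    return OpeningModel(
        base=s, structure=out, moved_domain=moved_domain,
        rotation=rotation, translation=translation,
        separation=sep, clash_count=clash_count, ccs=ccs,
    )


def scan_opening(
    s: Structure,
    partition: DomainPartition,
    separations: list[float],
    n_poses_per_sep: int = 5,
    seed: int = 42,
    markers: tuple[int, int] = (875, 836),
    moved_domain: str = "Vt",
    chain: str | None = None,
    max_tether: float = 140.0,
    max_clashes: int = 20,
    pa_params: PaParams | None = None,
    max_tries: int = 40,
) -> pd.DataFrame:
    """CCS vs marker separation over random tether-respecting poses.

    ``separations`` are target marker distances (A) and must increase.  A
    requested separation at or below the closed-state marker distance keeps
    the closed geometry (flagged ``at_closed``); separations beyond the
    hinge tether are flagged infeasible with NaN CCS.
    """
    if list(separations) != sorted(separations):
        raise ValueError("separations must be increasing")
    chain = chain or s.chains[0]
    rng = np.random.default_rng(seed)
    pos_a = _marker_ca(s, markers[0], chain)
    pos_b = _marker_ca(s, markers[1], chain)
    d_closed = float(np.linalg.norm(pos_a - pos_b))
    rows = []
    for sep in separations:
        if sep <= d_closed:
            model = displace_tail(
                s, partition, markers=markers, moved_domain=moved_domain,
                chain=chain, max_tether=max_tether, pa_params=pa_params,
            )
            rows.append({"separation": sep, "ccs_mean": model.ccs.value,
                         "ccs_sd": model.ccs.sd, "n_poses": 1,
                         "feasible": True, "at_closed": True})
            continue
        vals = []
        tries = 0
        while len(vals) < n_poses_per_sep and tries < max_tries:
            tries += 1
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            target = pos_b + u * sep
            try:
                model = displace_tail(
                    s, partition, translation=target - pos_a,
                    markers=markers, moved_domain=moved_domain, chain=chain,
                    max_tether=max_tether, max_clashes=max_clashes,
                    pa_params=pa_params,
                )
            except ValueError:
                continue
            vals.append(model.ccs.value)
        if vals:
            rows.append({"separation": sep, "ccs_mean": float(np.mean(vals)),
                         "ccs_sd": float(np.std(vals)), "n_poses": len(vals),
                         "feasible": True, "at_closed": False})
        else:
            warnings.warn(f"separation {sep} A infeasible under the hinge tether")
            rows.append({"separation": sep, "ccs_mean": np.nan, "ccs_sd": np.nan,
                         "n_poses": 0, "feasible": False, "at_closed": False})
    return pd.DataFrame(rows)


def assign_state_models(
    experimental: dict[str, float | CcsValue],
    scan: pd.DataFrame,
    tolerance: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """All scan rows whose CCS lies within ``tolerance`` (relative) of each
    experimental state value — deliberately one-to-many, because distinct
    opening geometries can share a cross section."""
    if scan.empty:
        raise ValueError("empty scan table")
    out: dict[str, pd.DataFrame] = {}
    for label, val in experimental.items():
        target = val.value if isinstance(val, CcsValue) else float(val)
        ok = scan["feasible"] & (
            (scan["ccs_mean"] - target).abs() <= tolerance * target
        )
        hits = scan[ok]
        if hits.empty:
            warnings.warn(f"no model within {tolerance:.0%} of state {label} "
                          f"({target:.0f} A^2)")
        out[label] = hits.reset_index(drop=True)
    return out
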