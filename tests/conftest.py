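"""Shared synthetic fixtures: structures are built programmatically."""

from __future__ import annotations

import numpy as np
import pytest
import biotite.structure as struc

from vinlock.structio import Structure


def make_structure(
    coords,
    elements=None,
    res_ids=None,
    chain="A",
    res_names=None,
    atom_names=None,
    occupancy=None,
    source_id="synthetic",
) -> Structure:
    """Assemble a Structure from raw arrays (synthetic test scaffold)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords.astype(np.float32)
    arr.chain_id[:] = chain if isinstance(chain, str) else "A"
    if not isinstance(chain, str):
        arr.chain_id = np.asarray(chain)
    arr.res_id[:] = res_ids if res_ids is not None else np.arange(1, n + 1)
    arr.res_name[:] = res_names if res_names is not None else "GLY"
    arr.atom_name[:] = atom_names if atom_names is not None else "CA"
    arr.element[:] = elements if elements is not None else "C"
    arr.set_annotation(
        "occupancy",
        np.asarray(occupancy, dtype=np.float32) if occupancy is not None
        else np.ones(n, dtype=np.float32),
    )
    return Structure(arr, source_id)


@pytest.fixture
def structure_factory():
    return make_structure


@pytest.fixture
def lattice_ball():
    """Solid convex ball of carbon atoms on a 1.8 A lattice (radius 8 A)."""
    g = np.arange(-8, 8.1, 1.8)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([X, Y, Z], -1).reshape(-1, 3)
    return make_structure(pts[np.linalg.norm(pts, axis=1) <= 8])


@pytest.fixture
def bowl():
    """Open hemispherical shell (pocket opening along +z, axis at x=y=0)."""
    g = np.arange(-8, 8.1, 1.8)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([X, Y, Z], -1).reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    sel = (r <= 8) & (r >= 4.5) & (pts[:, 2] <= 1.0)
    return make_structure(pts[sel])


@pytest.fixture
def two_domain_protein():
    """Two well-separated blobs with vinculin-like residue numbering:
    a 'head' blob covering D1-D4 numbering and a 'tail' blob on Vt."""
    rng = np.random.default_rng(42)
    head = rng.normal(0, 6, (400, 3))
    tail = rng.normal(0, 4, (150, 3)) + np.array([18.0, 0, 0])
    coords = np.vstack([head, tail])
    res_ids = np.concatenate([
        np.linspace(1, 835, 400).astype(int),
        np.linspace(896, 1066, 150).astype(int),
    ])
    return make_structure(coords, res_ids=res_ids)


@pytest.fixture
def tiny_pdb(tmp_path):
    """Hand-written 3-atom PDB file (K975 donor pair against E772 acceptor)."""
    text = (
        "ATOM      1  N   LYS A 975      11.000  10.000  10.000  1.00 20.00           N\n"
        "ATOM      2  NZ  LYS A 975      10.000  10.000  10.000  1.00 20.00           N\n"
        "ATOM      3  O   GLU A 772      10.000  10.000  12.350  1.00 20.00           O\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path
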