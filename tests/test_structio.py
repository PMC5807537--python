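"""Structure I/O, SASA, interface areas and hydrogen-bond census."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vinlock.config import DomainPartition
from vinlock.structio import (
    Structure, read_structure, select_domain, sasa, find_hbonds,
    interface_area, compare_interfaces, canonical_coords,
)

PART = DomainPartition.default()


class TestReadStructure:
    def test_tiny_pdb_identity(self, tiny_pdb):
        s = read_structure(tiny_pdb)
        assert s.n_atoms == 3
        np.testing.assert_allclose(
            s.coord[1], [10.0, 10.0, 10.0], atol=1e-3
        )
        assert s.chains == ["A"]

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError, match="zero polymer atoms"):
            read_structure(p)

    def test_zero_occupancy_dropped_and_altloc_resolved(self, tmp_path):
        text = (
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.70 20.00           C\n"
            "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.30 20.00           C\n"
            "ATOM      3  CB  GLY A   1       1.000   0.000   0.000  0.00 20.00           C\n"
            "ATOM      4  CA  GLY A   2       2.000   0.000   0.000  1.00 20.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        s = read_structure(p)
        # highest-occupancy altloc kept, zero-occupancy atom dropped
        assert s.n_atoms == 2
        np.testing.assert_allclose(s.coord[0], [0, 0, 0], atol=1e-3)

    def test_waters_excluded(self, tmp_path):
        text = (
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00 20.00           C\n"
            "HETATM    2  O   HOH A 101       9.000   9.000   9.000  1.00 20.00           O\n"
            "END\n"
        )
        p = tmp_path / "wat.pdb"
        p.write_text(text)
        assert read_structure(p).n_atoms == 1


class TestSelectDomain:
    def test_selects_range(self, two_domain_protein):
        vt = select_domain(two_domain_protein, PART, "Vt", "A")
        assert vt.n_atoms == 150
        assert vt.atoms.res_id.min() >= 896

    def test_unknown_chain_raises(self, two_domain_protein):
        with pytest.raises(KeyError):
            select_domain(two_domain_protein, PART, "D1", "Z")

    def test_unknown_label_raises(self, two_domain_protein):
        with pytest.raises(KeyError):
            select_domain(two_domain_protein, PART, "D9", "A")

    def test_full_range_selection_is_identity(self, structure_factory):
        s = structure_factory(np.eye(3) * 3.0, res_ids=[1, 2, 3])
        sel = select_domain(s, PART, "D1", "A")
        assert sel.n_atoms == 3
        np.testing.assert_allclose(sel.coord, s.coord)


class TestSasa:
    def test_single_atom_matches_sphere(self, structure_factory):
        s = structure_factory([[0.0, 0.0, 0.0]])
        area = sasa(s, probe_radius=1.4, n_points=960).sum()
        exact = 4 * np.pi * (1.7 + 1.4) ** 2   # carbon vdW 1.7 A
        assert abs(area - exact) / exact < 0.01

    def test_distant_atoms_additive(self, structure_factory):
        s = structure_factory([[0.0, 0, 0], [100.0, 0, 0]])
        one = sasa(structure_factory([[0.0, 0, 0]]), 1.4, 960).sum()
        assert abs(sasa(s, 1.4, 960).sum() - 2 * one) / (2 * one) < 1e-9

    def test_overlapping_spheres_vs_biopython_oracle(self, structure_factory):
        """Two fused carbon spheres against Bio.PDB's Shrake-Rupley."""
        from Bio.PDB.SASA import ShrakeRupley
        from Bio.PDB.StructureBuilder import StructureBuilder

        d = 2.0  # centre distance < 2 * r_vdw
        coords = [[0.0, 0, 0], [d, 0, 0]]
        s = structure_factory(coords)
        ours = sasa(s, 1.4, 960).sum()

        sb = StructureBuilder()
        sb.init_structure("x"); sb.init_model(0); sb.init_chain("A")
        sb.init_seg(" ")
        for i, c in enumerate(coords):
            sb.init_residue("GLY", " ", i + 1, " ")
            sb.init_atom("CA", np.array(c, dtype=float), 0.0, 1.0, " ",
                         "CA", i, element="C")
        model = sb.get_structure()[0]
        # same carbon radius as our single-atom set
        sr = ShrakeRupley(probe_radius=1.4, n_points=960,
                          radii_dict={"C": 1.7})
        sr.compute(model, level="A")
        theirs = sum(atom.sasa for atom in model.get_atoms())
        assert abs(ours - theirs) / theirs < 0.02

    def test_precondition_errors(self, structure_factory):
        s = structure_factory([[0.0, 0, 0]])
        with pytest.raises(ValueError):
            sasa(s, probe_radius=-1.0)
        with pytest.raises(ValueError):
            sasa(s, n_points=8)

    def test_coincident_atoms_well_defined(self, structure_factory):
        # exactly coincident atoms: finite, deterministic, bounded by the
        # two isolated spheres (each atom keeps its boundary points)
        s = structure_factory([[0.0, 0, 0], [0.0, 0, 0]])
        areas = sasa(s, 1.4, 240)
        assert np.all(np.isfinite(areas))
        one = sasa(structure_factory([[0.0, 0, 0]]), 1.4, 240).sum()
        assert areas.sum() <= 2 * one * 1.001
        np.testing.assert_allclose(areas, sasa(s, 1.4, 240))


class TestHbonds:
    def test_fixture_distances_and_tiers(self, tiny_pdb):
        s = read_structure(tiny_pdb)
        lys = s.select(s.atoms.res_id == 975)
        glu = s.select(s.atoms.res_id == 772)
        bonds = find_hbonds(lys, glu, 3.5, 4.0)
        by_donor = {hb.donor.atom_name: hb for hb in bonds}
        assert by_donor["NZ"].distance == pytest.approx(2.35, abs=0.005)
        assert by_donor["NZ"].tier == "short"
        assert by_donor["NZ"].acceptor.atom_name == "O"

    def test_sorted_by_distance(self, tiny_pdb):
        s = read_structure(tiny_pdb)
        bonds = find_hbonds(s.select(s.atoms.res_id == 975),
                            s.select(s.atoms.res_id == 772))
        dists = [hb.distance for hb in bonds]
        assert dists == sorted(dists)

    def test_out_of_range_pair_empty(self, structure_factory):
        a = structure_factory([[0.0, 0, 0]], elements=["N"],
                              res_names=["LYS"], atom_names=["NZ"])
        b = structure_factory([[5.0, 0, 0]], elements=["O"],
                              res_names=["GLU"], atom_names=["O"])
        assert find_hbonds(a, b, 3.5, 4.0) == []

    def test_symmetric_in_arguments(self, tiny_pdb):
        s = read_structure(tiny_pdb)
        a = s.select(s.atoms.res_id == 975)
        b = s.select(s.atoms.res_id == 772)
        ab = find_hbonds(a, b)
        ba = find_hbonds(b, a)
        key = lambda hb: (str(hb.donor), str(hb.acceptor), round(hb.distance, 6))
        assert sorted(map(key, ab)) == sorted(map(key, ba))

    def test_long_tier_window(self, structure_factory):
        a = structure_factory([[0.0, 0, 0]], elements=["N"],
                              res_names=["LYS"], atom_names=["NZ"])
        b = structure_factory([[3.7, 0, 0]], elements=["O"],
                              res_names=["GLU"], atom_names=["O"])
        (hb,) = find_hbonds(a, b, 3.5, 4.0)
        assert hb.tier == "long"

    def test_bad_cutoffs_raise(self, tiny_pdb):
        s = read_structure(tiny_pdb)
        with pytest.raises(ValueError):
            find_hbonds(s, s, 4.0, 3.5)


class TestInterfaceArea:
    def test_contacting_domains_positive_and_symmetric(self, structure_factory):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 4, (120, 3))
        b = rng.normal(0, 4, (120, 3)) + np.array([7.0, 0, 0])
        coords = np.vstack([a, b])
        res_ids = np.concatenate([
            np.linspace(1, 252, 120).astype(int),
            np.linspace(896, 1066, 120).astype(int),
        ])
        s = structure_factory(coords, res_ids=res_ids)
        r1 = interface_area(s, PART, "D1", "Vt", n_points=240)
        r2 = interface_area(s, PART, "Vt", "D1", n_points=240)
        assert r1.mean_area > 0
        assert r1.mean_area == pytest.approx(r2.mean_area, rel=1e-9)

    def test_rigid_motion_invariance(self, structure_factory):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 4, (100, 3))
        b = rng.normal(0, 4, (100, 3)) + np.array([7.0, 0, 0])
        coords = np.vstack([a, b])
        res_ids = np.concatenate([
            np.linspace(1, 252, 100).astype(int),
            np.linspace(896, 1066, 100).astype(int),
        ])
        s = structure_factory(coords, res_ids=res_ids)
        R = Rotation.random(random_state=7).as_matrix()
        s_moved = structure_factory(coords @ R.T + np.array([31.0, -12.0, 5.0]),
                                    res_ids=res_ids)
        r0 = interface_area(s, PART, "D1", "Vt", n_points=240)
        r1 = interface_area(s_moved, PART, "D1", "Vt", n_points=240)
        assert r1.mean_area == pytest.approx(r0.mean_area, rel=1e-6)

    def test_non_contacting_domains_zero(self, structure_factory):
        a = np.random.default_rng(3).normal(0, 3, (60, 3))
        coords = np.vstack([a, a + np.array([100.0, 0, 0])])
        res_ids = np.concatenate([
            np.linspace(1, 252, 60).astype(int),
            np.linspace(896, 1066, 60).astype(int),
        ])
        s = structure_factory(coords, res_ids=res_ids)
        r = interface_area(s, PART, "D1", "Vt", n_points=240)
        assert r.mean_area == pytest.approx(0.0, abs=1e-6)
        assert r.hbonds == []

    def test_empty_domains_raise(self, two_domain_protein):
        with pytest.raises(ValueError):
            interface_area(two_domain_protein, PART, "insert", "hinge")


class TestCompareInterfaces:
    def _report(self, distances, res_pairs, area=100.0):
        from vinlock.structio import InterfaceReport, HBond, AtomRef
        hbonds = [
            HBond(
                AtomRef("A", d_res, "LYS", d_atom),
                AtomRef("A", a_res, "GLU", a_atom),
                dist, "short" if dist < 3.5 else "long",
            )
            for dist, (d_res, d_atom, a_res, a_atom) in zip(distances, res_pairs)
        ]
        return InterfaceReport("Vt", "D4", {"A": area}, area, hbonds, "mixed")

    def test_identity_zero_losses(self):
        rep = self._report([2.35], [(975, "NZ", 772, "O")])
        table = compare_interfaces([rep, rep], labels=["wt", "copy"])
        assert not table["lost_in_copy"].any()
        assert table["delta_copy"].abs().max() == pytest.approx(0.0)

    def test_lost_bond_flagged(self):
        wt = self._report([2.35, 3.04],
                          [(975, "NZ", 772, "O"), (974, "OD1", 773, "ND2")])
        mut = self._report([3.10], [(974, "OD1", 773, "ND2")])
        table = compare_interfaces([wt, mut], labels=["wt", "mut"])
        lost = table[table["lost_in_mut"]]
        assert len(lost) == 1
        assert lost.iloc[0]["donor"] == "975/NZ"

    def test_metavinculin_offset_matches(self):
        wt = self._report([2.35], [(975, "NZ", 772, "O")])
        mv = self._report([3.02], [(1043, "NZ", 772, "O")])
        table = compare_interfaces([wt, mv], labels=["wt", "mv"],
                                   residue_offsets={"mv": 68})
        assert len(table) == 1            # K975 matched to K1043
        assert not table["lost_in_mv"].any()
        assert table.iloc[0]["delta_mv"] == pytest.approx(3.02 - 2.35)

    def test_mismatched_pairs_raise(self):
        from vinlock.structio import InterfaceReport
        r1 = InterfaceReport("Vt", "D4", {}, 0.0, [], "mixed")
        r2 = InterfaceReport("Vt", "D1", {}, 0.0, [], "mixed")
        with pytest.raises(ValueError):
            compare_interfaces([r1, r2])


def test_canonical_coords_rigid_invariant():
    rng = np.random.default_rng(5)
    pts = rng.normal(0, 5, (50, 3))
    R = Rotation.random(random_state=11).as_matrix()
    moved = pts @ R.T + np.array([3.0, -8.0, 12.0])
    np.testing.assert_allclose(
        canonical_coords(pts), canonical_coords(moved), atol=1e-8
    )
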