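"""Projection-approximation CCS and rigid-body opening models."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from vinlock.config import DomainPartition
from vinlock.ccs3d import (
    PaParams, CcsValue, pa_ccs, displace_tail, scan_opening,
    assign_state_models,
)

PART = DomainPartition.default()
FINE = dict(grid_spacing=0.1, n_orientations=100)


def two_disk_oracle(d, R, n_theta=4000):
    """Exact orientation-averaged union area of two disks of radius R whose
    centres project at separation d*sin(theta); lens-overlap closed form,
    integrated over the uniform-sphere polar angle."""
    thetas = np.linspace(0, np.pi / 2, n_theta)
    areas = []
    for th in thetas:
        s = d * np.sin(th)
        if s >= 2 * R:
            ov = 0.0
        else:
            ov = 2 * R**2 * np.arccos(s / (2 * R)) \
                - 0.5 * s * np.sqrt(4 * R**2 - s**2)
        areas.append(2 * np.pi * R**2 - ov)
    # weight by sin(theta): uniform orientations of the inter-atom axis
    w = np.sin(thetas)
    return float(np.sum(np.array(areas) * w) / np.sum(w))


class TestPaCcs:
    def test_single_atom_analytic_disk(self, structure_factory):
        s = structure_factory([[0.0, 0.0, 0.0]])
        v = pa_ccs(s, PaParams(**FINE))
        exact = np.pi * (1.7 + 1.0) ** 2
        assert abs(v.value - exact) / exact < 0.005

    def test_two_distant_atoms_additive(self, structure_factory):
        s = structure_factory([[0.0, 0, 0], [200.0, 0, 0]])
        v = pa_ccs(s, PaParams(**FINE))
        exact = 2 * np.pi * (1.7 + 1.0) ** 2
        assert abs(v.value - exact) / exact < 0.005

    def test_two_close_atoms_vs_overlap_oracle(self, structure_factory):
        d = 3.0
        s = structure_factory([[0.0, 0, 0], [d, 0, 0]])
        v = pa_ccs(s, PaParams(grid_spacing=0.1, n_orientations=600, seed=5))
        oracle = two_disk_oracle(d, 1.7 + 1.0)
        assert abs(v.value - oracle) / oracle < 0.01

    def test_rigid_motion_invariance(self, structure_factory):
        rng = np.random.default_rng(0)
        blob = rng.normal(0, 8, (200, 3))
        R = Rotation.random(random_state=3).as_matrix()
        p = PaParams(grid_spacing=0.5, n_orientations=200, seed=5)
        a = pa_ccs(structure_factory(blob), p).value
        b = pa_ccs(structure_factory(blob @ R.T + [40.0, -7.0, 3.0]), p).value
        assert abs(a - b) / a < 1e-3

    def test_monotone_under_atom_addition(self, structure_factory):
        rng = np.random.default_rng(1)
        blob = rng.normal(0, 6, (80, 3))
        p = PaParams(grid_spacing=0.5, n_orientations=200, seed=2)
        small = pa_ccs(structure_factory(blob), p).value
        grown = pa_ccs(
            structure_factory(np.vstack([blob, [[15.0, 0, 0]]])), p
        ).value
        assert grown >= small

    def test_orientation_convergence(self, structure_factory):
        rng = np.random.default_rng(2)
        blob = rng.normal(0, 8, (150, 3))
        s = structure_factory(blob)
        v1 = pa_ccs(s, PaParams(grid_spacing=0.5, n_orientations=400, seed=3))
        v2 = pa_ccs(s, PaParams(grid_spacing=0.5, n_orientations=800, seed=3))
        assert abs(v2.value - v1.value) < 3 * (v1.sd + v2.sd)

    def test_seed_determinism(self, structure_factory):
        s = structure_factory(np.random.default_rng(3).normal(0, 5, (50, 3)))
        p = PaParams(grid_spacing=0.5, n_orientations=150, seed=11)
        assert pa_ccs(s, p).value == pa_ccs(s, p).value

    def test_param_validation(self):
        with pytest.raises(ValueError):
            PaParams(n_orientations=10)
        with pytest.raises(ValueError):
            CcsValue(value=-5.0, sd=0.0, method="projection_approx")


class TestDisplaceTail:
    P = PaParams(grid_spacing=1.0, n_orientations=150, seed=4)

    def test_identity_keeps_geometry_and_ccs(self, two_domain_protein):
        base_ccs = pa_ccs(two_domain_protein, self.P)
        m = displace_tail(two_domain_protein, PART, markers=(896, 835),
                          pa_params=self.P)
        np.testing.assert_allclose(m.structure.coord, two_domain_protein.coord,
                                   atol=1e-5)
        assert m.ccs.value == pytest.approx(base_ccs.value, rel=1e-9)

    def test_translation_moves_only_tail(self, two_domain_protein):
        m = displace_tail(two_domain_protein, PART, translation=[30.0, 0, 0],
                          markers=(896, 835), max_tether=200, pa_params=self.P)
        moved = m.structure.atoms.res_id >= 896
        static_before = two_domain_protein.coord[~moved]
        np.testing.assert_allclose(m.structure.coord[~moved], static_before,
                                   atol=1e-5)
        assert not np.allclose(m.structure.coord[moved],
                               two_domain_protein.coord[moved])

    def test_tether_violation_rejected(self, two_domain_protein):
        with pytest.raises(ValueError, match="hinge"):
            displace_tail(two_domain_protein, PART, translation=[500.0, 0, 0],
                          markers=(896, 835), max_tether=140,
                          compute_ccs=False)

    def test_clash_rejected(self, two_domain_protein):
        # drive the tail blob straight into the head blob
        with pytest.raises(ValueError, match="overlap"):
            displace_tail(two_domain_protein, PART, translation=[-18.0, 0, 0],
                          markers=(896, 835), max_tether=200, max_clashes=5,
                          compute_ccs=False)


class TestScanOpening:
    P = PaParams(grid_spacing=1.0, n_orientations=120, seed=6)

    def test_zero_separation_equals_closed_state(self, two_domain_protein):
        scan = scan_opening(two_domain_protein, PART, [0.0], seed=1,
                            markers=(896, 835), pa_params=self.P)
        closed = pa_ccs(two_domain_protein, self.P).value
        assert scan.loc[0, "ccs_mean"] == pytest.approx(closed, rel=1e-9)
        assert bool(scan.loc[0, "at_closed"])

    def test_monotone_increase_with_separation(self, two_domain_protein):
        scan = scan_opening(two_domain_protein, PART, [0.0, 40.0, 80.0, 125.0],
                            n_poses_per_sep=3, seed=2, markers=(896, 835),
                            max_tether=200, pa_params=self.P)
        assert scan["feasible"].all()
        assert scan["ccs_mean"].is_monotonic_increasing

    def test_same_seed_identical_tables(self, two_domain_protein):
        kw = dict(n_poses_per_sep=2, seed=3, markers=(896, 835),
                  max_tether=200, pa_params=self.P)
        s1 = scan_opening(two_domain_protein, PART, [0.0, 50.0], **kw)
        s2 = scan_opening(two_domain_protein, PART, [0.0, 50.0], **kw)
        pd.testing.assert_frame_equal(s1, s2)

    def test_decreasing_separations_rejected(self, two_domain_protein):
        with pytest.raises(ValueError):
            scan_opening(two_domain_protein, PART, [50.0, 0.0], seed=1,
                         markers=(896, 835), pa_params=self.P)

    def test_infeasible_separation_flagged(self, two_domain_protein):
        with pytest.warns(UserWarning, match="infeasible"):
            scan = scan_opening(two_domain_protein, PART, [300.0], seed=4,
                                markers=(896, 835), max_tether=140,
                                pa_params=self.P)
        assert not scan.loc[0, "feasible"]
        assert np.isnan(scan.loc[0, "ccs_mean"])


class TestAssignStateModels:
    def _scan(self):
        return pd.DataFrame({
            "separation": [0.0, 40.0, 80.0, 125.0],
            "ccs_mean": [6266.0, 6900.0, 7300.0, 8325.0],
            "ccs_sd": [0.0] * 4,
            "n_poses": [1] * 4,
            "feasible": [True] * 4,
            "at_closed": [True, False, False, False],
        })

    def test_matches_within_tolerance(self):
        out = assign_state_models({"O": 7268.0}, self._scan(), tolerance=0.05)
        assert len(out["O"]) == 1
        assert out["O"].loc[0, "separation"] == 80.0

    def test_below_closed_state_empty(self):
        with pytest.warns(UserWarning, match="no model"):
            out = assign_state_models({"C": 5000.0}, self._scan(),
                                      tolerance=0.02)
        assert out["C"].empty

    def test_degenerate_exact_row(self):
        out = assign_state_models({"SO": 6900.0}, self._scan(), tolerance=1e-6)
        assert len(out["SO"]) == 1

    def test_empty_scan_raises(self):
        with pytest.raises(ValueError):
            assign_state_models({"C": 6266.0}, pd.DataFrame())


def test_state_ordering_on_opening_geometry(two_domain_protein):
    """Closed < semi-open < open CCS on the synthetic two-blob geometry."""
    p = PaParams(grid_spacing=1.0, n_orientations=150, seed=8)
    closed = pa_ccs(two_domain_protein, p).value
    semi = displace_tail(two_domain_protein, PART, translation=[25.0, 0, 0],
                         markers=(896, 835), max_tether=200, pa_params=p)
    opened = displace_tail(two_domain_protein, PART, translation=[60.0, 0, 0],
                           markers=(896, 835), max_tether=200, pa_params=p)
    assert closed < semi.ccs.value < opened.ccs.value


def test_semi_open_geometry_breaks_one_interface(structure_factory):
    """A tail pulled off one head lobe zeroes that buried area while the
    other contact survives — checked through the interface module."""
    from vinlock.structio import interface_area

    def ball(center, radius):
        g = np.arange(-radius, radius + 0.1, 1.8)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        pts = np.stack([X, Y, Z], -1).reshape(-1, 3)
        return pts[np.linalg.norm(pts, axis=1) <= radius] + np.asarray(center)

    d1 = ball([0.0, 0.0, 0.0], 5.0)
    d4 = ball([0.0, 16.0, 0.0], 5.0)
    vt = ball([5.5, 8.0, 0.0], 4.0)      # closed: the tail touches both lobes
    coords = np.vstack([d1, d4, vt])
    res_ids = np.concatenate([
        np.linspace(1, 252, len(d1)).astype(int),
        np.linspace(718, 835, len(d4)).astype(int),
        np.linspace(896, 1066, len(vt)).astype(int),
    ])
    s = structure_factory(coords, res_ids=res_ids)
    closed_d4 = interface_area(s, PART, "Vt", "D4", n_points=120)
    assert closed_d4.mean_area > 0    # sanity: both contacts exist when closed
    # pull the tail away from D4 but slide it along D1 (semi-open, SO1-like)
    m = displace_tail(s, PART, translation=[1.5, -14.0, 0.0],
                      markers=(896, 835), max_tether=200, max_clashes=2000,
                      compute_ccs=False)
    so1 = m.structure
    vt_d4 = interface_area(so1, PART, "Vt", "D4", n_points=120)
    vt_d1 = interface_area(so1, PART, "Vt", "D1", n_points=120)
    assert vt_d4.mean_area == pytest.approx(0.0, abs=1e-6)
    assert vt_d1.mean_area > 0
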