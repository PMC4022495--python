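"""Shrake-Rupley SASA against analytic, quadrature and library oracles."""

import math

import numpy as np
import pytest

from argbp.sasa import buried_area, sasa, sasa_coords, sphere_points
from argbp.structure import DomainDefinition
from argbp.synth import make_peptide


def grid_oracle(coords, radii, probe=1.4, n_theta=120):
    """Independent surface quadrature: latitude-longitude grid with
    cos(latitude) area weights (completely different point construction from
    the golden spiral)."""
    theta = (np.arange(n_theta) + 0.5) / n_theta * math.pi  # polar
    nphi = 2 * n_theta
    phi = (np.arange(nphi) + 0.5) / nphi * 2 * math.pi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    pts = np.stack([np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1)
    w = np.sin(T)  # area element sin(theta) dtheta dphi
    w = w / w.sum()
    total = 0.0
    expanded = np.asarray(radii) + probe
    for i, (c, r) in enumerate(zip(coords, expanded)):
        surf = c + r * pts.reshape(-1, 3)
        keep = np.ones(len(surf), bool)
        for j, (c2, r2) in enumerate(zip(coords, expanded)):
            if j == i:
                continue
            keep &= ((surf - c2) ** 2).sum(axis=1) > r2 * r2
        total += (w.reshape(-1)[keep]).sum() * 4 * math.pi * r * r
    return total


def two_sphere_exact(r, probe, d):
    """Closed-form SASA of two equal spheres with centre distance d."""
    R = r + probe
    if d >= 2 * R:
        return 2 * 4 * math.pi * R * R
    h = R - d / 2.0  # buried cap height on each sphere
    return 2 * (4 * math.pi * R * R - 2 * math.pi * R * h)


class TestSphereCases:
    def test_single_atom_matches_analytic_sphere(self):
        a = sasa_coords(np.zeros((1, 3)), np.array([1.70]), probe=1.4, n_points=960)
        analytic = 4 * math.pi * 3.10**2  # 120.76 A^2
        assert a[0] == pytest.approx(analytic, rel=0.005)

    def test_distant_atoms_are_additive(self):
        a = sasa_coords(np.array([[0.0, 0, 0], [100.0, 0, 0]]), np.full(2, 1.7))
        single = sasa_coords(np.zeros((1, 3)), np.array([1.7]))[0]
        assert a.sum() == pytest.approx(2 * single, rel=1e-12)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5, 5.5])
    def test_two_sphere_overlap_matches_cap_formula(self, d):
        got = sasa_coords(np.array([[0.0, 0, 0], [d, 0, 0]]), np.full(2, 1.7), n_points=960).sum()
        assert got == pytest.approx(two_sphere_exact(1.7, 1.4, d), rel=0.01)

    def test_point_count_refinement_is_stable(self):
        coarse = sasa_coords(np.zeros((1, 3)), np.array([1.7]), n_points=960)[0]
        fine = sasa_coords(np.zeros((1, 3)), np.array([1.7]), n_points=4000)[0]
        assert abs(fine - coarse) / fine < 0.002

    def test_grid_quadrature_oracle_on_small_cluster(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(scale=2.5, size=(18, 3))
        radii = rng.choice([1.52, 1.55, 1.70, 1.80], size=18)
        got = sasa_coords(coords, radii, n_points=4000).sum()
        want = grid_oracle(coords, radii)
        assert got == pytest.approx(want, rel=0.02)

    def test_sphere_points_deterministic_and_unit(self):
        p1, p2 = sphere_points(960), sphere_points(960)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(np.linalg.norm(p1, axis=1), 1.0, atol=1e-12)


class TestStructureSasa:
    def test_rigid_invariance(self):
        st = make_peptide(8)
        base = sasa(st).total
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [30, 40, 50], degrees=True).as_matrix()
        moved = st.transform(R, np.array([10.0, -5.0, 3.0]))
        assert abs(sasa(moved).total - base) / base < 0.005

    def test_total_is_sum_of_per_atom(self):
        res = sasa(make_peptide(6))
        assert res.total == pytest.approx(res.per_atom.sum(), rel=1e-9)

    def test_unknown_element_without_default_rejected(self):
        st = make_peptide(3)
        st.chains[0].residues[0].atoms[0].element = "ZZ"
        with pytest.raises(KeyError, match="ZZ"):
            sasa(st, default_radius=None)

    def test_agrees_with_mdtraj(self, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        from argbp.structure import write_pdb

        st = make_peptide(10, phi=-57.0, psi=-47.0)
        p = tmp_path / "helix.pdb"
        write_pdb(st, p)
        traj = mdtraj.load(str(p))
        ref = mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960).sum() * 100.0
        ours = sasa(st, n_points=960).total
        assert ours == pytest.approx(ref, rel=0.03)


class TestBuriedArea:
    def test_distant_chains_bury_nothing(self, monomer_and_domains):
        mono, _ = monomer_and_domains
        far = mono.copy()
        ch2 = far.chains[0]
        ch2.id = "B"
        for r in ch2.residues:
            for a in r.atoms:
                a.pos = a.pos + np.array([500.0, 0.0, 0.0])
        both = mono.copy()
        both.chains.append(ch2)
        rep = buried_area(both, ["A"], ["B"])
        assert rep.buried_total == pytest.approx(0.0, abs=1e-6)
        assert not rep.interface_residues["side1"] and not rep.interface_residues["side2"]

    def test_symmetric_in_sides_and_positive_for_dimer(self, swapped_dimer):
        dimer, _ = swapped_dimer
        ab = buried_area(dimer, ["A"], ["B"])
        ba = buried_area(dimer, ["B"], ["A"])
        assert ab.buried_total == pytest.approx(ba.buried_total, rel=1e-9)
        assert ab.buried_total > 0
        assert ab.interface_area == pytest.approx(ab.buried_total / 2.0)
        # per-side losses sum to the total
        assert sum(ab.buried_per_side.values()) == pytest.approx(ab.buried_total, rel=1e-6)

    def test_overlapping_sides_rejected(self, swapped_dimer):
        dimer, _ = swapped_dimer
        with pytest.raises(ValueError, match="overlap"):
            buried_area(dimer, ["A"], ["A"])
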