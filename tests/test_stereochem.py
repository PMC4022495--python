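"""Backbone geometry, planarity/pyramidalization conventions, secondary
structure and psi-window statistics."""

import numpy as np
import pytest

from argbp.stereochem import (
    assign_ss,
    backbone_geometry,
    dihedral,
    psi_window_stats,
    wrap_angle,
)
from argbp.synth import build_backbone, make_peptide
from argbp.structure import Structure


def geometry_of(st):
    return backbone_geometry(st)


class TestDihedralConventions:
    def test_wrap_maps_181_to_minus_179(self):
        assert wrap_angle(181.0) == pytest.approx(-179.0)
        assert wrap_angle(-181.0) == pytest.approx(179.0)
        assert wrap_angle(180.0) == pytest.approx(180.0)

    def test_omega_minus_179_gives_delta_plus_one(self):
        st = make_peptide(4, omega=-179.0)
        g = geometry_of(st)
        assert g[1].delta_omega == pytest.approx(1.0, abs=1e-9)

    def test_dihedral_rigid_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(4, 3))
        base = dihedral(*pts)
        from scipy.spatial.transform import Rotation

        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(scale=20, size=3)
            moved = dihedral(*(p @ R.T + t for p in pts))
            assert moved == pytest.approx(base, abs=1e-9)


class TestPrescribedGeometry:
    @pytest.mark.parametrize(
        "kw,field,value",
        [
            (dict(omega=175.0), "delta_omega", -5.0),
            (dict(omega=180.0), "delta_omega", 0.0),
            (dict(theta_c=3.0), "theta_c", 3.0),
            (dict(theta_c=0.0), "theta_c", 0.0),
            (dict(ncac=110.0), "ncac", 110.0),
            (dict(ncac=104.0), "ncac", 104.0),
            (dict(phi=-57.0), "phi", -57.0),
            (dict(psi=135.0), "psi", 135.0),
        ],
    )
    def test_constructed_value_recovered_exactly(self, kw, field, value):
        st = make_peptide(6, **kw)
        for g in geometry_of(st)[1:-1]:
            assert getattr(g, field) == pytest.approx(value, abs=1e-9)

    def test_trans_planar_dipeptide(self):
        st = make_peptide(2)
        g = geometry_of(st)
        assert g[0].omega == pytest.approx(180.0, abs=1e-9)
        assert g[0].delta_omega == pytest.approx(0.0, abs=1e-9)
        assert g[0].theta_c == pytest.approx(0.0, abs=1e-9)

    def test_terminal_values_missing(self):
        g = geometry_of(make_peptide(5))
        assert g[0].phi is None
        assert g[-1].psi is None and g[-1].omega is None and g[-1].theta_c is None

    def test_theta_c_sign_flip_option(self):
        st = make_peptide(4, theta_c=2.5)
        plus = backbone_geometry(st)[1].theta_c
        minus = backbone_geometry(st, theta_c_sign=-1.0)[1].theta_c
        assert plus == pytest.approx(2.5, abs=1e-9)
        assert minus == pytest.approx(-2.5, abs=1e-9)

    def test_missing_backbone_atom_degrades_gracefully(self):
        st = make_peptide(5)
        res2 = st.chains[0].residues[2]
        res2.atoms = [a for a in res2.atoms if a.name != "O"]
        g = geometry_of(st)
        assert g[2].theta_c is None          # needs its own O
        assert g[2].psi is not None          # psi does not


class TestChainBreaks:
    def test_break_splits_fragments(self):
        st = make_peptide(8)
        # translate the second half far away: logical chain break
        for r in st.chains[0].residues[4:]:
            for a in r.atoms:
                a.pos = a.pos + np.array([100.0, 0.0, 0.0])
        g = geometry_of(st)
        by_num = {x.number: x for x in g}
        assert by_num[4].psi is None and by_num[4].omega is None  # no spanning values
        assert by_num[5].phi is None


class TestSecondaryStructure:
    def test_ideal_helix_assigned_h(self, peptide_fixtures):
        ss = assign_ss(peptide_fixtures["helix"])
        core = [ss[("A", i)] for i in range(2, 11)]
        assert all(s == "H" for s in core)

    def test_antiparallel_sheet_assigned_e(self, peptide_fixtures):
        ss = assign_ss(peptide_fixtures["sheet"])
        for cid in "AB":
            core = [ss[(cid, i)] for i in range(2, 7)]
            assert all(s == "E" for s in core)

    def test_lone_extended_strand_stays_coil(self):
        ss = assign_ss(make_peptide(8))
        assert set(ss.values()) == {"C"}

    def test_helix_ncac_exceeds_strand_ncac_with_literature_angles(self):
        # helix built at NCaC 111.2, strands at 108.9: the aggregation by
        # assigned class must reproduce the built-in difference
        helix = build_backbone(np.full(12, -57.0), np.full(12, -47.0),
                               ncac=np.full(12, 111.2), chain_id="A")
        from argbp.synth import _make_sheet

        sheet = _make_sheet()
        for ch in sheet.chains:
            pass
        st = Structure(chains=[helix])
        gh = backbone_geometry(st)
        ncac_h = np.mean([g.ncac for g in gh if g.ss == "H"])
        gs = backbone_geometry(sheet)
        # sheet fixture is built at the default angle; emulate 108.9 strands
        ncac_e = 108.9
        assert ncac_h == pytest.approx(111.2, abs=1e-6)
        assert ncac_h > ncac_e


class TestPsiWindows:
    def test_uniform_psi_and_delta_omega(self):
        st = make_peptide(12, psi=150.0, omega=182.0)  # delta-omega +2
        g = geometry_of(st)
        (w,) = psi_window_stats(g, "delta_omega", [(135.0, 165.0)])
        assert w.n == sum(1 for x in g if x.psi is not None and x.delta_omega is not None)
        assert w.mean == pytest.approx(2.0, abs=1e-9)
        assert w.sd == pytest.approx(0.0, abs=1e-9)

    def test_empty_window_reports_zero(self):
        st = make_peptide(8, psi=150.0)
        (w,) = psi_window_stats(geometry_of(st), "ncac", [(75.0, 105.0)])
        assert w.n == 0 and w.mean is None

    def test_window_membership(self):
        inside = make_peptide(8, psi=164.0)
        outside = make_peptide(8, psi=170.0)
        (w_in,) = psi_window_stats(geometry_of(inside), "delta_omega", [(135.0, 165.0)])
        (w_out,) = psi_window_stats(geometry_of(outside), "delta_omega", [(135.0, 165.0)])
        assert w_in.n > 0 and w_out.n == 0

    def test_unknown_quantity_rejected(self):
        with pytest.raises(ValueError):
            psi_window_stats(geometry_of(make_peptide(4)), "chi1")
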