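"""Interaction censuses and swapped-dimer interface classification."""

import numpy as np
import pytest

from argbp.contacts import (
    SwapAnnotation,
    all_contacts,
    classify_swap_interfaces,
    hydrogen_bonds,
    hydrophobic_contacts,
    ligand_pocket_contacts,
    salt_bridges,
)
from conftest import residue_from_atoms, structure_from_residues


def asp_lys_pair(no_nz_distance):
    """Asp side-chain O and Lys side-chain N at a chosen OD1-NZ distance."""
    asp = residue_from_atoms("ASP", 56, {
        "CA": ("C", (0, 0, 0)), "CB": ("C", (1.5, 0, 0)), "CG": ("C", (2.5, 1, 0)),
        "OD1": ("O", (3.5, 1, 0)), "OD2": ("O", (2.5, 2.2, 0)),
    })
    lys = residue_from_atoms("LYS", 242, {
        "CA": ("C", (8, 5, 0)), "CB": ("C", (7, 4, 0)), "NZ": ("N", (3.5 + no_nz_distance, 1, 0)),
    })
    return structure_from_residues({"A": [asp], "B": [lys]})


class TestSaltBridges:
    def test_detected_at_three_angstrom(self):
        found = salt_bridges(asp_lys_pair(3.0))
        assert len(found) == 1
        c = found[0]
        assert c.kind == "salt_bridge" and c.distance == pytest.approx(3.0)
        assert {c.res1[2], c.res2[2]} == {"ASP", "LYS"}

    def test_not_detected_beyond_cutoff(self):
        assert salt_bridges(asp_lys_pair(6.0), cutoff=4.0) == []

    def test_minimum_distance_pair_kept(self):
        st = asp_lys_pair(3.0)  # NZ is 3.0 from OD1 but further from OD2
        (c,) = salt_bridges(st)
        assert {c.atom1, c.atom2} == {"NZ", "OD1"}

    def test_histidine_flagged_uncertain(self):
        his = residue_from_atoms("HIS", 10, {"CA": ("C", (0, 0, 0)), "NE2": ("N", (1, 0, 0))})
        glu = residue_from_atoms("GLU", 20, {"CA": ("C", (5, 0, 0)), "OE1": ("O", (2.5, 0, 0))})
        (c,) = salt_bridges(structure_from_residues({"A": [his, glu]}))
        assert "his_uncertain" in c.flags

    def test_counts_monotone_in_cutoff(self):
        st = asp_lys_pair(3.5)
        n = [len(salt_bridges(st, cutoff=c)) for c in (2.5, 3.5, 4.5, 6.0)]
        assert n == sorted(n)

    def test_scope_filtering(self):
        st = asp_lys_pair(3.0)  # residues on different chains
        assert len(salt_bridges(st, scope="inter")) == 1
        assert salt_bridges(st, scope="intra") == []


class TestHydrogenBonds:
    def _nh_oc(self, d_no, bend_deg=0.0):
        """Backbone N-H...O=C geometry: acceptor O at distance d from N,
        along the N-H direction (antecedent CA behind the donor)."""
        theta = np.radians(bend_deg)
        o_pos = np.array([d_no * np.cos(theta), d_no * np.sin(theta), 0.0])
        don = residue_from_atoms("ALA", 1, {"CA": ("C", (-1.45, 0, 0)), "N": ("N", (0, 0, 0))})
        # carbonyl C bonded to the acceptor O, perpendicular to the O...N line
        # so the O-as-donor route cannot rescue a bent N-donor geometry
        c_pos = o_pos + np.array([0.0, 0.0, 1.23])
        acc = residue_from_atoms("ALA", 9, {"O": ("O", tuple(o_pos)), "C": ("C", tuple(c_pos))})
        return structure_from_residues({"A": [don], "B": [acc]})

    def test_linear_geometry_detected(self):
        found = hydrogen_bonds(self._nh_oc(2.9))
        assert any(c.kind == "hbond" and c.distance == pytest.approx(2.9) for c in found)

    def test_long_distance_rejected(self):
        assert hydrogen_bonds(self._nh_oc(5.0), d_max=3.5) == []

    def test_bent_donor_geometry_rejected(self):
        # antecedent-donor-acceptor angle ~60 degrees: sterically impossible H-bond
        found = hydrogen_bonds(self._nh_oc(2.9, bend_deg=120.0), angle_min=120.0)
        assert all(not (c.atom1 == "N" and c.atom2 == "O") for c in found)

    def test_missing_antecedent_kept_but_flagged(self):
        don = residue_from_atoms("UNK", 1, {"N": ("N", (0, 0, 0))})
        acc = residue_from_atoms("ALA", 9, {"O": ("O", (2.9, 0, 0)), "C": ("C", (4.1, 0, 0))})
        found = hydrogen_bonds(structure_from_residues({"A": [don], "B": [acc]}))
        flagged = [c for c in found if c.atom1 == "N" or c.atom2 == "N"]
        assert flagged and all("no_angle" in c.flags for c in flagged)


class TestHydrophobic:
    def _leu_pair(self, d):
        l1 = residue_from_atoms("LEU", 1, {"CA": ("C", (0, 0, 0)), "CD1": ("C", (2, 0, 0))})
        l2 = residue_from_atoms("LEU", 2, {"CA": ("C", (d + 4, 0, 0)), "CD1": ("C", (2 + d, 0, 0))})
        return structure_from_residues({"A": [l1], "B": [l2]})

    def test_interdigitated_side_chains_detected(self):
        (c,) = hydrophobic_contacts(self._leu_pair(4.0))
        assert c.distance == pytest.approx(4.0)

    def test_far_apart_rejected(self):
        assert hydrophobic_contacts(self._leu_pair(8.0), cutoff=4.5) == []

    def test_polar_side_chains_ignored(self):
        s1 = residue_from_atoms("SER", 1, {"CA": ("C", (0, 0, 0)), "CB": ("C", (2, 0, 0))})
        s2 = residue_from_atoms("SER", 2, {"CA": ("C", (8, 0, 0)), "CB": ("C", (5, 0, 0))})
        assert hydrophobic_contacts(structure_from_residues({"A": [s1], "B": [s2]})) == []

    def test_backbone_carbons_excluded(self):
        a1 = residue_from_atoms("ALA", 1, {"CA": ("C", (0, 0, 0)), "C": ("C", (1.5, 0, 0))})
        a2 = residue_from_atoms("ALA", 2, {"CA": ("C", (4.0, 0, 0)), "C": ("C", (5.5, 0, 0))})
        assert hydrophobic_contacts(structure_from_residues({"A": [a1], "B": [a2]})) == []


class TestSwapClassification:
    def test_isolated_monomer_empty_report(self, monomer_and_domains):
        mono, _ = monomer_and_domains
        rep = classify_swap_interfaces(mono, SwapAnnotation((69, 75), (66, 68), (1, 65)))
        assert rep.c_interface == [] and rep.o_interface == []

    def test_constructed_dimer_contacts_all_closed_interface(self, swapped_dimer):
        dimer, _ = swapped_dimer
        ann = SwapAnnotation(swapped_segment=(69, 75), hinge=(66, 68), main_body=(1, 65))
        inter = all_contacts(dimer, scope="inter")
        rep = classify_swap_interfaces(dimer, ann, inter)
        assert len(inter) > 0
        assert len(rep.c_interface) == len(inter)
        assert rep.o_interface == []

    def test_classification_partitions_interchain_contacts(self, swapped_dimer):
        dimer, _ = swapped_dimer
        ann = SwapAnnotation((69, 75), (66, 68), (1, 65))
        inter = all_contacts(dimer, scope="inter")
        rep = classify_swap_interfaces(dimer, ann, inter)
        assert len(rep.c_interface) + len(rep.o_interface) == len(inter)

    def test_two_fold_symmetry_of_interfaces(self, swapped_dimer):
        dimer, _ = swapped_dimer
        ann = SwapAnnotation((69, 75), (66, 68), (1, 65))
        rep = classify_swap_interfaces(dimer, ann)
        from_a = sum(1 for c in rep.c_interface
                     if (c.res1[0] == "A") == (ann.region(c.res1[1]) == "swapped"))
        from_b = len(rep.c_interface) - from_a
        assert abs(from_a - from_b) <= 2

    def test_three_chains_rejected(self, swapped_dimer):
        dimer, _ = swapped_dimer
        three = dimer.copy()
        extra = dimer.copy().chains[0]
        extra.id = "C"
        for r in extra.residues:
            for a in r.atoms:
                a.pos = a.pos + 300.0
        three.chains.append(extra)
        with pytest.raises(ValueError, match="2 protein chains"):
            classify_swap_interfaces(three, SwapAnnotation((69, 75), (66, 68), (1, 65)))


class TestLigandPocket:
    def _free_arg(self):
        return residue_from_atoms("ARG", 300, {
            "N": ("N", (0, 1.4, 0)), "CA": ("C", (0, 0, 0)), "C": ("C", (1.4, 0, 0)),
            "O": ("O", (2.0, 1.0, 0)), "OXT": ("O", (2.0, -1.0, 0)),
            "CB": ("C", (-1.0, -1.0, 0)), "CG": ("C", (-2.4, -0.6, 0)),
            "CD": ("C", (-3.4, -1.6, 0)), "NE": ("N", (-4.7, -1.0, 0)),
            "CZ": ("C", (-5.9, -1.6, 0)), "NH1": ("N", (-6.0, -2.9, 0)),
            "NH2": ("N", (-7.0, -0.9, 0)),
        }, hetero=True)

    def test_free_ligand_has_no_contacts(self):
        st = structure_from_residues({"L": [self._free_arg()]})
        contacts, lig_sasa = ligand_pocket_contacts(st, ("L", 300))
        assert contacts == []
        assert lig_sasa > 100  # fully exposed

    def test_pocket_salt_bridge_and_burial(self):
        arg = self._free_arg()
        # an aspartate whose carboxylate faces the guanidinium
        asp = residue_from_atoms("ASP", 37, {
            "CA": ("C", (-8.5, -4.5, 0)), "CB": ("C", (-8.0, -3.5, 0)),
            "CG": ("C", (-7.5, -3.3, 0)), "OD1": ("O", (-6.6, -3.9, 0.0)),
        })
        phe = residue_from_atoms("PHE", 38, {
            "CA": ("C", (-3.0, 2.5, 3.4)), "CB": ("C", (-3.2, 1.2, 3.4)),
            "CG": ("C", (-3.4, -0.2, 3.4)),
        })
        st = structure_from_residues({"A": [asp, phe], "L": [arg]})
        contacts, _ = ligand_pocket_contacts(st, ("L", 300))
        kinds = {c.kind for c in contacts}
        assert "salt_bridge" in kinds      # NH1/NH2 to OD1
        assert "hydrophobic" in kinds      # aliphatic stem to Phe ring carbons

    def test_missing_ligand_rejected(self):
        st = structure_from_residues({"L": [self._free_arg()]})
        with pytest.raises(KeyError):
            ligand_pocket_contacts(st, ("L", 999))


def test_contact_invariants():
    (c,) = salt_bridges(asp_lys_pair(3.0))
    # canonical ordering: stored once with sorted residue identity
    assert (c.res1[0], c.res1[1]) <= (c.res2[0], c.res2[1])
    with pytest.raises(ValueError):
        from argbp.contacts import Contact

        Contact("hbond", ("A", 1, "ALA"), ("A", 1, "ALA"), "N", "O", 3.0)
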