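"""Structure model, PDB round-trips and selections."""

import numpy as np
import pytest

from argbp.structure import (
    DomainDefinition,
    PdbParseError,
    SelectionError,
    parse_ranges,
    read_pdb,
    select,
    write_pdb,
)
from argbp.synth import make_peptide

GLY_CA_LINE = "ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C\n"


class TestReadPdb:
    def test_single_atom_identity_parse(self):
        st = read_pdb(GLY_CA_LINE + "END\n")
        assert len(st.chains) == 1
        res = st.chains[0].residues
        assert len(res) == 1 and res[0].name == "GLY" and res[0].number == 1
        assert len(res[0].atoms) == 1
        np.testing.assert_allclose(res[0].atoms[0].pos, [1.0, 2.0, 3.0])

    def test_two_equal_chains(self):
        lines = []
        serial = 1
        for cid in "AB":
            for i in (1, 2, 3):
                lines.append(
                    f"ATOM  {serial:5d}  CA  ALA {cid}{i:4d}    "
                    f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
                )
                serial += 1
        st = read_pdb("\n".join(lines) + "\nEND\n")
        assert st.chain_ids == ["A", "B"]
        assert len(st.chain("A").residues) == len(st.chain("B").residues) == 3

    def test_hetero_flagged(self):
        text = GLY_CA_LINE + "HETATM    2  N   ARG A 301      5.000   5.000   5.000  1.00  0.00           N\nEND\n"
        st = read_pdb(text)
        het = st.hetero_residues()
        assert len(het) == 1 and het[0][1].name == "ARG"

    def test_malformed_record_names_line(self):
        bad = GLY_CA_LINE + "ATOM      2  CA  GLY A   2       1.000   bad!!   3.000  1.00  0.00           C\n"
        with pytest.raises(PdbParseError, match="line 2"):
            read_pdb(bad)

    def test_empty_input_rejected(self):
        with pytest.raises(PdbParseError):
            read_pdb("\n\n")

    def test_first_model_only(self):
        text = (
            "MODEL        1\n" + GLY_CA_LINE + "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  GLY A   1      99.000  99.000  99.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        st = read_pdb(text)
        np.testing.assert_allclose(st.chains[0].residues[0].atoms[0].pos, [1, 2, 3])


class TestWritePdb:
    def test_empty_structure_only_end(self):
        from argbp.structure import Structure

        text = write_pdb(Structure())
        assert text.strip() == "END"

    def test_single_atom_records(self):
        st = read_pdb(GLY_CA_LINE + "END\n")
        text = write_pdb(st)
        kinds = [line[:6].strip() for line in text.splitlines() if line.strip()]
        assert "ATOM" in kinds and "TER" in kinds and kinds[-1] == "END"

    def test_long_atom_name_rejected(self):
        st = read_pdb(GLY_CA_LINE + "END\n")
        st.chains[0].residues[0].atoms[0].name = "TOOLONG"
        with pytest.raises(ValueError, match="longer than 4"):
            write_pdb(st)

    def test_round_trip_preserves_coordinates_and_numbering(self, monomer_and_domains, tmp_path):
        mono, _ = monomer_and_domains
        p = tmp_path / "mono.pdb"
        write_pdb(mono, p)
        back = read_pdb(p)
        assert [r.number for r in back.chains[0].residues] == [r.number for r in mono.chains[0].residues]
        assert [r.name for r in back.chains[0].residues] == [r.name for r in mono.chains[0].residues]
        a = np.array([at.pos for r in mono.chains[0].residues for at in r.atoms])
        b = np.array([at.pos for r in back.chains[0].residues for at in r.atoms])
        np.testing.assert_allclose(a, b, atol=5e-4)  # PDB stores 3 decimals
        # a second round trip is the identity exactly
        again = read_pdb(write_pdb(back))
        c = np.array([at.pos for r in again.chains[0].residues for at in r.atoms])
        np.testing.assert_array_equal(b, c)


class TestSelect:
    def test_all_ca_of_toy_chain(self):
        st = make_peptide(10)
        coords, index = select(st, DomainDefinition("all", [("A", 1, 10)]), ("CA",))
        assert coords.shape == (10, 3)
        assert [num for _, num, _ in index] == list(range(1, 11))

    def test_author_numbered_range_arithmetic(self):
        st = make_peptide(227, start_number=20)  # chain numbered 20..246
        coords, _ = select(st, DomainDefinition("lobe", [("A", 23, 110)]), ("CA",))
        assert len(coords) == 88

    def test_backbone_selection_count(self):
        st = make_peptide(10)
        coords, _ = select(st, DomainDefinition("all", [("A", 1, 10)]), ("N", "CA", "C", "O"))
        assert coords.shape == (40, 3)

    def test_empty_selection_raises(self):
        st = make_peptide(10)
        with pytest.raises(SelectionError):
            select(st, DomainDefinition("off", [("A", 500, 600)]), ("CA",))

    def test_lobe_union_covers_whole_toy_chain(self, monomer_and_domains):
        mono, dom = monomer_and_domains
        union = DomainDefinition("union", dom["lobe1"].ranges + dom["linker"].ranges
                                 + dom["lobe2"].ranges + dom["hinge"].ranges + dom["tail"].ranges)
        coords, _ = select(mono, union, ("CA",))
        assert len(coords) == len(mono.chains[0].residues)


def test_parse_ranges_round_trip():
    dd = parse_ranges("A:23-110,A:210-231", "lobe1")
    assert dd.ranges == [("A", 23, 110), ("A", 210, 231)]
    assert dd.contains("A", 23) and dd.contains("A", 231) and not dd.contains("A", 111)
    with pytest.raises(ValueError):
        parse_ranges("A23-110")


def test_domain_definition_invariants():
    with pytest.raises(ValueError):
        DomainDefinition("bad", [])
    with pytest.raises(ValueError):
        DomainDefinition("bad", [("A", 10, 5)])
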