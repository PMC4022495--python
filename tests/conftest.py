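"""Shared fixtures: every structure used in the suite is generated
programmatically by the synthetic-data module (no stored coordinate files)."""

import numpy as np
import pytest

from argbp.structure import Atom, Chain, Residue, Structure
from argbp.synth import ToySpec, make_ideal_peptide_fixtures, make_swapped_dimer, make_two_lobe_monomer


@pytest.fixture(scope="session")
def monomer_and_domains():
    return make_two_lobe_monomer(ToySpec(seed=1))


@pytest.fixture(scope="session")
def swapped_dimer(monomer_and_domains):
    mono, domains = monomer_and_domains
    return make_swapped_dimer(mono, domains)


@pytest.fixture(scope="session")
def peptide_fixtures():
    return make_ideal_peptide_fixtures()


def residue_from_atoms(name, number, atoms, hetero=False):
    """Hand-built residue: atoms as {atom_name: (element, xyz)}."""
    return Residue(
        name,
        number,
        atoms=[Atom(an, el, np.asarray(xyz, float)) for an, (el, xyz) in atoms.items()],
        hetero=hetero,
    )


def structure_from_residues(chains):
    """chains: {chain_id: [Residue, ...]}."""
    return Structure(chains=[Chain(cid, residues) for cid, residues in chains.items()])
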