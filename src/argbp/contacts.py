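"""Interaction censuses and swapped-dimer interface classification.

Salt bridges, hydrogen bonds and hydrophobic contacts are detected with
conventional geometric criteria (cutoffs overridable), one contact per
residue pair per kind with the minimum-distance atom pair retained.  For a
3D domain-swapped dimer, inter-chain contacts are split into the closed
C-interface (swapped segment of one chain against the main body of the
other — the interface a monomer would also have) and the open O-interface
(everything unique to the swapped assembly: hinge- and body-mediated
contacts).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .sasa import sasa
from .structure import Chain, Residue, Structure

__all__ = [
    "Contact",
    "SwapAnnotation",
    "SwapInterfaceReport",
    "salt_bridges",
    "hydrogen_bonds",
    "hydrophobic_contacts",
    "classify_swap_interfaces",
    "ligand_pocket_contacts",
    "all_contacts",
]

SALT_BRIDGE_CUTOFF = 4.0
HBOND_DMAX = 3.5
HBOND_ANGLE_MIN = 120.0
HYDROPHOBIC_CUTOFF = 4.5

# side-chain nitrogen donors of basic residues / oxygen acceptors of acidic ones
_BASIC_N = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
_ACIDIC_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_APOLAR = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Contact:
    kind: str                      # salt_bridge | hbond | hydrophobic
    res1: tuple[str, int, str]     # (chain, number, name)
    res2: tuple[str, int, str]
    atom1: str
    atom2: str
    distance: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if self.res1 == self.res2:
            raise ValueError("self-contact")


@dataclass
class SwapAnnotation:
    """Residue ranges of a swapped dimer, in author numbering (same on both
    chains).  Defaults are the domain layout of the thermophilic
    arginine-binding protein construct: body 20-233, hinge 232-236, swapped
    C-terminal helix 237-246."""

    swapped_segment: tuple[int, int] = (237, 246)
    hinge: tuple[int, int] = (232, 236)
    main_body: tuple[int, int] = (20, 233)

    def region(self, number: int) -> str:
        # precedence: swapped > hinge > body (hinge/body boundary may overlap)
        if self.swapped_segment[0] <= number <= self.swapped_segment[1]:
            return "swapped"
        if self.hinge[0] <= number <= self.hinge[1]:
            return "hinge"
        if self.main_body[0] <= number <= self.main_body[1]:
            return "body"
        return "other"


@dataclass
class SwapInterfaceReport:
    c_interface: list[Contact] = field(default_factory=list)
    o_interface: list[Contact] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for label, lst in (("c_interface", self.c_interface), ("o_interface", self.o_interface)):
            d: dict[str, int] = {}
            for c in lst:
                d[c.kind] = d.get(c.kind, 0) + 1
            d["total"] = len(lst)
            out[label] = d
        return out


def _iter_residues(structure: Structure, include_hetero: bool = False):
    for ch in structure.chains:
        for res in ch.residues:
            if res.is_water:
                continue
            if res.hetero and not include_hetero:
                continue
            yield ch.id, res


def _in_scope(cid1: str, cid2: str, scope: str) -> bool:
    if scope == "all":
        return True
    if scope == "intra":
        return cid1 == cid2
    if scope == "inter":
        return cid1 != cid2
    raise ValueError(f"unknown scope {scope!r}")


def _canonical(c: Contact) -> Contact:
    if (c.res2[0], c.res2[1], c.atom2) < (c.res1[0], c.res1[1], c.atom1):
        return Contact(c.kind, c.res2, c.res1, c.atom2, c.atom1, c.distance, c.flags)
    return c


def _dedupe_min(contacts: list[Contact]) -> list[Contact]:
    """One contact per unordered residue pair, minimum distance kept."""
    best: dict[tuple, Contact] = {}
    for c in contacts:
        c = _canonical(c)
        key = (c.kind, c.res1[:2], c.res2[:2])
        if key not in best or c.distance < best[key].distance:
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.res1, c.res2, c.kind))


def salt_bridges(
    structure: Structure,
    cutoff: float = SALT_BRIDGE_CUTOFF,
    scope: str = "all",
    include_hetero: bool = False,
) -> list[Contact]:
    """Basic-sidechain N within ``cutoff`` of an acidic-sidechain O.

    His is counted as a potential donor but flagged ``his_uncertain``
    (protonation state unknown from coordinates alone).
    """
    residues = list(_iter_residues(structure, include_hetero))
    found: list[Contact] = []
    for (c1, r1), (c2, r2) in itertools.combinations(residues, 2):
        if not _in_scope(c1, c2, scope):
            continue
        for (cb, rb), (ca_, ra) in (((c1, r1), (c2, r2)), ((c2, r2), (c1, r1))):
            if rb.name not in _BASIC_N or ra.name not in _ACIDIC_O:
                continue
            for n_name in _BASIC_N[rb.name]:
                na = rb.atom(n_name)
                if na is None:
                    continue
                for o_name in _ACIDIC_O[ra.name]:
                    oa = ra.atom(o_name)
                    if oa is None:
                        continue
                    d = float(np.linalg.norm(na.pos - oa.pos))
                    if d <= cutoff:
                        flags = ("his_uncertain",) if rb.name == "HIS" else ()
                        found.append(Contact("salt_bridge", (cb, rb.number, rb.name),
                                             (ca_, ra.number, ra.name), n_name, o_name, d, flags))
    return _dedupe_min(found)


def _heavy_neighbours(res: Residue, prev_c: np.ndarray | None, atom_name: str) -> list[np.ndarray]:
    """Heavy atoms covalently bonded to the named atom (distance-inferred
    within the residue, plus the preceding carbonyl C for backbone N)."""
    target = res.atom(atom_name)
    out = []
    for a in res.atoms:
        if a.name == atom_name:
            continue
        if np.linalg.norm(a.pos - target.pos) < 1.8:
            out.append(a.pos)
    if atom_name == "N" and prev_c is not None and np.linalg.norm(prev_c - target.pos) < 1.8:
        out.append(prev_c)
    return out


def hydrogen_bonds(
    structure: Structure,
    d_max: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
    scope: str = "all",
    include_hetero: bool = False,
) -> list[Contact]:
    """Heavy-atom N/O donor-acceptor pairs within ``d_max`` whose
    antecedent-donor-acceptor angle is at least ``angle_min``.

    Pairs whose donor angle cannot be computed (no bonded heavy atom found)
    are kept on distance alone and flagged ``no_angle``.  Directly bonded
    pairs and same-residue pairs are excluded.
    """
    from .stereochem import bond_angle

    chains = {c.id: c for c in structure.chains}
    prev_c_map: dict[tuple[str, int], np.ndarray] = {}
    for cid, ch in chains.items():
        poly = ch.polymer()
        for prev, cur in zip(poly, poly[1:]):
            cat = prev.atom("C")
            if cat is not None:
                prev_c_map[(cid, cur.number)] = cat.pos

    entries = []  # (chain, residue, atom)
    for cid, res in _iter_residues(structure, include_hetero):
        for a in res.atoms:
            if a.element in ("N", "O"):
                entries.append((cid, res, a))

    found: list[Contact] = []
    for (c1, r1, a1), (c2, r2, a2) in itertools.combinations(entries, 2):
        if (c1, r1.key) == (c2, r2.key):
            continue
        if not _in_scope(c1, c2, scope):
            continue
        d = float(np.linalg.norm(a1.pos - a2.pos))
        if d > d_max or d < 2.2:  # below 2.2 A it is a covalent/clash artefact
            continue
        # try each side as donor; accept if any donor geometry passes
        accepted = False
        flags: tuple[str, ...] = ()
        for (cd, rd, ad), (ca_, ra, aa) in (((c1, r1, a1), (c2, r2, a2)),
                                            ((c2, r2, a2), (c1, r1, a1))):
            antecedents = _heavy_neighbours(rd, prev_c_map.get((cd, rd.number)), ad.name)
            if not antecedents:
                accepted, flags = True, ("no_angle",)
                break
            ang = max(bond_angle(p, ad.pos, aa.pos) for p in antecedents)
            if ang >= angle_min:
                accepted = True
                break
        if accepted:
            found.append(Contact("hbond", (c1, r1.number, r1.name),
                                 (c2, r2.number, r2.name), a1.name, a2.name, d, flags))
    return _dedupe_min(found)


def hydrophobic_contacts(
    structure: Structure,
    cutoff: float = HYDROPHOBIC_CUTOFF,
    scope: str = "all",
    include_hetero: bool = False,
) -> list[Contact]:
    """Apolar side-chain carbon pairs within ``cutoff`` Angstrom."""
    entries = []
    for cid, res in _iter_residues(structure, include_hetero):
        if res.name not in _APOLAR:
            continue
        for a in res.atoms:
            if a.element == "C" and a.name not in _BACKBONE:
                entries.append((cid, res, a))
    found: list[Contact] = []
    for (c1, r1, a1), (c2, r2, a2) in itertools.combinations(entries, 2):
        if (c1, r1.key) == (c2, r2.key):
            continue
        if not _in_scope(c1, c2, scope):
            continue
        d = float(np.linalg.norm(a1.pos - a2.pos))
        if d <= cutoff:
            found.append(Contact("hydrophobic", (c1, r1.number, r1.name),
                                 (c2, r2.number, r2.name), a1.name, a2.name, d))
    return _dedupe_min(found)


def all_contacts(structure: Structure, scope: str = "all", **kw) -> list[Contact]:
    return (salt_bridges(structure, scope=scope)
            + hydrogen_bonds(structure, scope=scope)
            + hydrophobic_contacts(structure, scope=scope))


def classify_swap_interfaces(
    dimer: Structure,
    annotation: SwapAnnotation,
    contacts: list[Contact] | None = None,
) -> SwapInterfaceReport:
    """Partition inter-chain contacts of a 2-chain swapped dimer.

    C-interface: one partner in the swapped segment, the other in the main
    body of the opposite chain.  Every other inter-chain contact (hinge- or
    body-mediated) belongs to the O-interface, so the two classes partition
    the inter-chain contact set.  Intra-chain contacts are ignored.
    """
    protein = dimer.protein_chains()
    if len(protein) == 1:
        # an isolated monomer has no inter-chain contacts at all
        return SwapInterfaceReport()
    if len(protein) != 2:
        raise ValueError(f"swapped-dimer classification needs exactly 2 protein chains, got {len(protein)}")
    if contacts is None:
        contacts = all_contacts(dimer)
    report = SwapInterfaceReport()
    for c in contacts:
        if c.res1[0] == c.res2[0]:
            continue  # intra-chain
        reg1 = annotation.region(c.res1[1])
        reg2 = annotation.region(c.res2[1])
        if {reg1, reg2} == {"swapped", "body"}:
            report.c_interface.append(c)
        else:
            report.o_interface.append(c)
    return report


def ligand_pocket_contacts(
    structure: Structure,
    ligand: tuple[str, int],
    salt_cutoff: float = SALT_BRIDGE_CUTOFF,
    hbond_dmax: float = HBOND_DMAX,
    hydrophobic_cutoff: float = HYDROPHOBIC_CUTOFF,
) -> tuple[list[Contact], float]:
    """Contacts between a bound ligand residue and the protein, plus the
    ligand's SASA within the complex (solvent-inaccessibility check).

    ``ligand`` is (chain id, residue number).  The ligand is treated with
    the same criteria as protein residues: charged-group N/O pairs as salt
    bridges, N/O pairs as hydrogen bonds, carbon-carbon apolar contacts.
    """
    cid, num = ligand
    chain = structure.chain(cid)
    lig = chain.residue(num)
    if lig is None:
        raise KeyError(f"ligand residue {cid}:{num} not found")

    lig_n = [a for a in lig.atoms if a.element == "N"]
    lig_o = [a for a in lig.atoms if a.element == "O"]
    lig_c = [a for a in lig.atoms if a.element == "C"]

    found: list[Contact] = []
    lkey = (cid, lig.number, lig.name)
    for pcid, res in _iter_residues(structure, include_hetero=False):
        if (pcid, res.key) == (cid, lig.key):
            continue
        # salt bridges: ligand amine/guanidinium N vs acidic O, and ligand
        # carboxylate O vs basic side-chain N
        if res.name in _ACIDIC_O:
            for la in lig_n:
                for o_name in _ACIDIC_O[res.name]:
                    oa = res.atom(o_name)
                    if oa is not None:
                        d = float(np.linalg.norm(la.pos - oa.pos))
                        if d <= salt_cutoff:
                            found.append(Contact("salt_bridge", lkey, (pcid, res.number, res.name),
                                                 la.name, o_name, d))
        if res.name in _BASIC_N:
            for la in lig_o:
                for n_name in _BASIC_N[res.name]:
                    na = res.atom(n_name)
                    if na is not None:
                        d = float(np.linalg.norm(la.pos - na.pos))
                        if d <= salt_cutoff:
                            found.append(Contact("salt_bridge", lkey, (pcid, res.number, res.name),
                                                 la.name, n_name, d))
        # hydrogen bonds: any ligand N/O vs protein N/O
        for la in lig_n + lig_o:
            for pa in res.atoms:
                if pa.element not in ("N", "O"):
                    continue
                d = float(np.linalg.norm(la.pos - pa.pos))
                if 2.2 <= d <= hbond_dmax:
                    found.append(Contact("hbond", lkey, (pcid, res.number, res.name),
                                         la.name, pa.name, d, ("no_angle",)))
        # hydrophobic: ligand C vs apolar side-chain C
        if res.name in _APOLAR:
            for la in lig_c:
                for pa in res.atoms:
                    if pa.element == "C" and pa.name not in _BACKBONE:
                        d = float(np.linalg.norm(la.pos - pa.pos))
                        if d <= hydrophobic_cutoff:
                            found.append(Contact("hydrophobic", lkey, (pcid, res.number, res.name),
                                                 la.name, pa.name, d))
    contacts = _dedupe_min(found)

    full = sasa(structure, include_hetero=True)
    lig_area = sum(
        area for area, (acid, anum, _an) in zip(full.per_atom, full.atom_index)
        if acid == cid and anum == num
    )
    return contacts, float(lig_area)
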