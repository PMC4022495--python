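"""Shrake-Rupley solvent-accessible surface area and buried interface area.

A deterministic quasi-uniform point set (golden-spiral / Fibonacci sphere)
is placed on each atom's solvent-expanded sphere (van der Waals radius +
probe).  A point is exposed iff it lies outside every neighbouring expanded
sphere; the atom's area is the exposed fraction times 4*pi*(r+w)^2.

Buried interface area follows the usual convention for a binary complex:

    buried_total = SASA(side1 alone) + SASA(side2 alone) - SASA(complex)

which is the *total* area lost by both sides; the halved "interface area"
(one face) is also reported since databases differ in convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = ["SasaResult", "InterfaceReport", "sasa", "buried_area", "DEFAULT_RADII", "sphere_points"]

# Chothia-style heavy-atom radii (Angstrom); unknown elements fall back to the default.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    per_atom: np.ndarray            # Angstrom^2 per atom, parse order
    total: float                    # Angstrom^2
    probe_radius: float
    n_points: int
    atom_index: list[tuple[str, int, str]] = field(default_factory=list)  # (chain, resnum, atom name)

    def per_residue(self) -> dict[tuple[str, int], float]:
        out: dict[tuple[str, int], float] = {}
        for area, (cid, num, _an) in zip(self.per_atom, self.atom_index):
            out[(cid, num)] = out.get((cid, num), 0.0) + float(area)
        return out


@dataclass
class InterfaceReport:
    buried_total: float                     # SASA_1 + SASA_2 - SASA_12
    buried_per_side: dict[str, float]       # keyed by side label
    interface_area: float                   # buried_total / 2 (one-face convention)
    interface_residues: dict[str, list[tuple[int, float]]]  # per side: (resnum, area lost)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere points, shape (n, 3)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))   # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii_for(elements: list[str], radii_set: dict[str, float] | None, default: float | None) -> np.ndarray:
    table = dict(DEFAULT_RADII)
    if radii_set:
        table.update({k.upper(): v for k, v in radii_set.items()})
    out = np.empty(len(elements))
    for k, el in enumerate(elements):
        key = el.upper()
        if key in table:
            out[k] = table[key]
        elif default is not None:
            out[k] = default
        else:
            raise KeyError(f"no van der Waals radius for element {el!r} and no default given")
    return out


def sasa_coords(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA for raw coordinates + radii."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
        raise ValueError("coords must be a non-empty Nx3 array")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    expanded = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        # neighbours whose expanded sphere could cover any test point
        nbr = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in nbr:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > expanded[j] ** 2
        areas[i] = exposed.mean() * 4.0 * math.pi * ri * ri
    return areas


def sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii_set: dict[str, float] | None = None,
    default_radius: float | None = DEFAULT_RADIUS,
    include_water: bool = False,
    include_hetero: bool = True,
) -> SasaResult:
    """Shrake-Rupley SASA of a structure's heavy atoms."""
    triples = structure.atoms(include_water=include_water, include_hetero=include_hetero)
    if not triples:
        raise ValueError("structure has no atoms for SASA")
    coords = np.array([a.pos for _, _, a in triples])
    radii = _radii_for([a.element for _, _, a in triples], radii_set, default_radius)
    per_atom = sasa_coords(coords, radii, probe=probe, n_points=n_points)
    return SasaResult(
        per_atom=per_atom,
        total=float(per_atom.sum()),
        probe_radius=probe,
        n_points=n_points,
        atom_index=[(cid, r.number, a.name) for cid, r, a in triples],
    )


def _subset(structure: Structure, chain_ids: list[str]) -> Structure:
    return Structure(chains=[c for c in structure.copy().chains if c.id in chain_ids], id=structure.id)


def buried_area(
    structure: Structure,
    chains_side1: list[str],
    chains_side2: list[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    residue_threshold: float = 1.0,
    include_hetero: bool = False,
    radii_set: dict[str, float] | None = None,
) -> InterfaceReport:
    """SASA-based buried area between two groups of chains.

    Waters and hetero ligands are excluded by default: a ligand sitting in an
    intra-monomer cleft must not contribute to the dimer interface.
    """
    s1, s2 = set(chains_side1), set(chains_side2)
    if not s1 or not s2:
        raise ValueError("both sides must name at least one chain")
    if s1 & s2:
        raise ValueError(f"overlapping side definitions: {sorted(s1 & s2)}")
    kw = dict(probe=probe, n_points=n_points, include_hetero=include_hetero, radii_set=radii_set)
    r1 = sasa(_subset(structure, chains_side1), **kw)
    r2 = sasa(_subset(structure, chains_side2), **kw)
    r12 = sasa(_subset(structure, chains_side1 + chains_side2), **kw)
    buried_total = r1.total + r2.total - r12.total

    per_res_complex = r12.per_residue()
    buried_per_side: dict[str, float] = {}
    interface_residues: dict[str, list[tuple[int, float]]] = {}
    for label, iso in (("side1", r1), ("side2", r2)):
        lost_side = 0.0
        res_list: list[tuple[int, float]] = []
        for (cid, num), iso_area in iso.per_residue().items():
            lost = iso_area - per_res_complex.get((cid, num), 0.0)
            lost_side += lost
            if lost > residue_threshold:
                res_list.append((num, lost))
        buried_per_side[label] = lost_side
        interface_residues[label] = sorted(res_list)
    return InterfaceReport(
        buried_total=float(buried_total),
        buried_per_side=buried_per_side,
        interface_area=float(buried_total) / 2.0,
        interface_residues=interface_residues,
    )
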