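"""Backbone stereochemistry: dihedrals, NCaC angle, peptide planarity,
carbonyl pyramidalization, lightweight secondary structure, psi-window stats.

Conventions
-----------
* omega(i) = tau(Ca_i, C_i, N_{i+1}, Ca_{i+1}) is the torsion of the peptide
  bond *following* residue i, and Delta-omega(i) = wrap(omega - 180) is its
  deviation from trans planarity (wrap maps 181 -> -179, so omega = -179
  gives Delta-omega = +1).
* theta_c(i) = wrap(tau(O_i, C_i, N_{i+1}, Ca_i) - 180): the out-of-plane
  bend (pyramidalization) at the carbonyl carbon, measured as an improper
  torsion; sign follows the right-hand rule of that torsion and can be
  flipped via ``theta_c_sign``.
* psi-window statistics pair residue i's psi with peptide i's Delta-omega
  and theta_c — the quantities whose systematic psi-dependence is a marker
  of well-refined structures.
* Chains are split logically at breaks (consecutive Ca-Ca > 4.5 A).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .structure import Chain, Structure

__all__ = [
    "ResidueGeometry",
    "PsiWindowStats",
    "dihedral",
    "bond_angle",
    "wrap_angle",
    "backbone_geometry",
    "assign_ss",
    "psi_window_stats",
]

logger = logging.getLogger(__name__)

CHAIN_BREAK_CA_CA = 4.5  # Angstrom


def wrap_angle(deg: float) -> float:
    """Wrap into (-180, 180]."""
    w = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees, IUPAC right-hand convention."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return math.degrees(math.atan2(y, x))


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 in degrees."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    cos = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


@dataclass
class ResidueGeometry:
    chain: str
    number: int
    name: str
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None        # peptide i -> i+1
    ncac: float | None = None
    delta_omega: float | None = None  # wrap(omega - 180)
    theta_c: float | None = None      # carbonyl pyramidalization of peptide i
    ss: str = "C"


@dataclass
class PsiWindowStats:
    window: tuple[float, float]
    quantity: str
    n: int
    mean: float | None
    sd: float | None


def _fragments(chain: Chain) -> list[list]:
    """Split the polymer at chain breaks (Ca-Ca > 4.5 A) or missing Ca."""
    frags: list[list] = []
    current: list = []
    prev_ca = None
    for res in chain.polymer():
        ca = res.atom("CA")
        if ca is None:
            if current:
                frags.append(current)
            current, prev_ca = [], None
            logger.info("chain %s residue %d: missing CA, splitting", chain.id, res.number)
            continue
        if prev_ca is not None and np.linalg.norm(ca.pos - prev_ca) > CHAIN_BREAK_CA_CA:
            frags.append(current)
            current = []
        current.append(res)
        prev_ca = ca.pos
    if current:
        frags.append(current)
    return frags


def backbone_geometry(structure: Structure, theta_c_sign: float = 1.0) -> list[ResidueGeometry]:
    """Per-residue backbone geometry for every protein chain.

    Residues missing a needed backbone atom get ``None`` for the dependent
    values.  Terminal residues have undefined phi (first) and undefined
    psi/omega-linked values (last).
    """
    out: list[ResidueGeometry] = []
    ss_map = assign_ss(structure)
    for chain in structure.protein_chains():
        for frag in _fragments(chain):
            n = len(frag)
            for i, res in enumerate(frag):
                g = ResidueGeometry(chain.id, res.number, res.name,
                                    ss=ss_map.get((chain.id, res.number), "C"))
                N, CA, C, O = (res.atom(a) for a in ("N", "CA", "C", "O"))
                if N and CA and C:
                    g.ncac = bond_angle(N.pos, CA.pos, C.pos)
                if i > 0:
                    Cp = frag[i - 1].atom("C")
                    if Cp and N and CA and C:
                        g.phi = dihedral(Cp.pos, N.pos, CA.pos, C.pos)
                if i < n - 1:
                    nxt = frag[i + 1]
                    Nn, CAn = nxt.atom("N"), nxt.atom("CA")
                    if N and CA and C and Nn:
                        g.psi = dihedral(N.pos, CA.pos, C.pos, Nn.pos)
                    if CA and C and Nn and CAn:
                        g.omega = dihedral(CA.pos, C.pos, Nn.pos, CAn.pos)
                        g.delta_omega = wrap_angle(g.omega - 180.0)
                    if O and C and Nn and CA:
                        g.theta_c = theta_c_sign * wrap_angle(
                            dihedral(O.pos, C.pos, Nn.pos, CA.pos) - 180.0
                        )
                out.append(g)
    return out


# ---------------------------------------------------------------------------
# Secondary structure: hydrogen-bond-pattern assignment (not a DSSP energy model)
# ---------------------------------------------------------------------------

_HB_NO_MAX = 3.5  # Angstrom, backbone N...O


def assign_ss(structure: Structure) -> dict[tuple[str, int], str]:
    """Per-residue {H, E, C} from backbone N...O hydrogen-bond patterns.

    H: runs (length >= 4) of residues whose O(i)...N(i+4) distance is within
    hydrogen-bond range.  E: residues participating, together with a sequence
    neighbour, in a cross-strand backbone N-O ladder (partner separation > 2
    in sequence or on another chain).  Everything else: C.
    """
    frags_by_chain: dict[str, list[list]] = {
        c.id: _fragments(c) for c in structure.protein_chains()
    }
    # gather backbone N / O coordinates with identity
    entries = []  # (chain, fragidx, pos_in_frag, number, Npos, Opos)
    for cid, frags in frags_by_chain.items():
        for fi, frag in enumerate(frags):
            for k, res in enumerate(frag):
                N, O = res.atom("N"), res.atom("O")
                entries.append((cid, fi, k, res.number,
                                None if N is None else N.pos,
                                None if O is None else O.pos))
    ss: dict[tuple[str, int], str] = {(e[0], e[3]): "C" for e in entries}

    # helix: O(i)...N(i+4)
    helical: set[tuple[str, int]] = set()
    for cid, frags in frags_by_chain.items():
        for frag in frags:
            flags = []
            for i in range(len(frag)):
                ok = False
                if i + 4 < len(frag):
                    O = frag[i].atom("O")
                    N4 = frag[i + 4].atom("N")
                    if O is not None and N4 is not None:
                        ok = np.linalg.norm(O.pos - N4.pos) <= _HB_NO_MAX
                flags.append(ok)
            # residue j is helical if it lies inside a run of i..i+4 turns
            marks = [False] * len(frag)
            run_start = None
            for i, f in enumerate(flags + [False]):
                if f and run_start is None:
                    run_start = i
                elif not f and run_start is not None:
                    if i - run_start >= 1:  # each turn covers 5 residues
                        for j in range(run_start, min(i - 1 + 5, len(frag))):
                            marks[j] = True
                    run_start = None
            for res, m in zip(frag, marks):
                if m:
                    helical.add((cid, res.number))

    # strand ladders: cross N-O hydrogen bonds with |sep| > 2 or cross-chain
    partnered: set[tuple[str, int]] = set()
    coords_o = [(e[0], e[1], e[2], e[3], e[5]) for e in entries if e[5] is not None]
    for cid, fi, k, num, Npos in [(e[0], e[1], e[2], e[3], e[4]) for e in entries if e[4] is not None]:
        for cid2, fi2, k2, num2, Opos in coords_o:
            same_strand = cid == cid2 and fi == fi2 and abs(k - k2) <= 2
            if same_strand:
                continue
            if np.linalg.norm(Npos - Opos) <= _HB_NO_MAX:
                partnered.add((cid, num))
                partnered.add((cid2, num2))
    # a ladder needs at least two rungs; in an antiparallel sheet successive
    # rungs sit two residues apart (narrow pairs), so accept rungs within 2
    strand: set[tuple[str, int]] = set()
    for cid, frags in frags_by_chain.items():
        for frag in frags:
            nums = [r.number for r in frag]
            rungs = [j for j, num in enumerate(nums) if (cid, num) in partnered]
            for j in rungs:
                if any(k != j and abs(k - j) <= 2 for k in rungs):
                    strand.add((cid, nums[j]))
            # residues bridged between two rungs of the same ladder
            for j in rungs:
                if j + 2 in rungs and (cid, nums[j + 1]) not in helical:
                    strand.add((cid, nums[j + 1]))

    for key in ss:
        if key in helical:
            ss[key] = "H"
        elif key in strand:
            ss[key] = "E"
    return ss


def psi_window_stats(
    geometries: list[ResidueGeometry],
    quantity: str,
    windows: list[tuple[float, float]] = ((75.0, 105.0), (135.0, 165.0)),
) -> list[PsiWindowStats]:
    """Count/mean/sd of a geometric quantity over residues whose psi falls
    strictly inside each window.  ``quantity`` is one of ``ncac``,
    ``delta_omega``, ``theta_c``."""
    if quantity not in ("ncac", "delta_omega", "theta_c"):
        raise ValueError(f"unknown quantity {quantity!r}")
    if not geometries:
        raise ValueError("no geometries given")
    out = []
    for lo, hi in windows:
        vals = [
            getattr(g, quantity)
            for g in geometries
            if g.psi is not None and lo < g.psi < hi and getattr(g, quantity) is not None
        ]
        arr = np.array(vals, float)
        out.append(
            PsiWindowStats(
                window=(lo, hi),
                quantity=quantity,
                n=len(arr),
                mean=float(arr.mean()) if len(arr) else None,
                sd=float(arr.std(ddof=1)) if len(arr) > 1 else (0.0 if len(arr) == 1 else None),
            )
        )
    return out
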