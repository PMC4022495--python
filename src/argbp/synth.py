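"""Deterministic synthetic structure and fixture generators.

Fixtures are poly-alanine chains built from exact internal coordinates with
a NeRF-style (natural extension reference frame) chain builder, so every
dihedral, bond angle, peptide planarity deviation and carbonyl
pyramidalization is prescribed to machine precision.  That exactness is the
point: the geometry, superposition and interface modules are validated
against constructions whose ground truth is known analytically, not against
energy-minimised or physically packed models.

All generators are pure functions of their arguments (plus an integer seed
where noise is involved) and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import Atom, Chain, DomainDefinition, Residue, Structure

__all__ = [
    "ToySpec",
    "place_atom",
    "build_backbone",
    "make_peptide",
    "make_two_lobe_monomer",
    "apply_domain_rotation",
    "make_swapped_dimer",
    "perturb",
    "make_ideal_peptide_fixtures",
    "HELIX_PHI",
    "HELIX_PSI",
    "STRAND_PHI",
    "STRAND_PSI",
]

# Engh-Huber-style ideal backbone internal coordinates (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.0     # the NCaC angle; overridable per residue
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_N1_C_O = 122.7     # O placed relative to the following N
ANGLE_N_CA_CB = 110.4
TORSION_CB = -122.0      # C-N-CA-CB improper, L-configuration

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0


@dataclass
class ToySpec:
    n_res_per_lobe: int = 30
    linker_length: int = 5
    helix_tail_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_res_per_lobe, self.linker_length, self.helix_tail_length) < 1:
            raise ValueError("all ToySpec counts must be >= 1")


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d with |c-d| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: np.ndarray,
    psi: np.ndarray,
    omega: np.ndarray | None = None,
    ncac: np.ndarray | None = None,
    theta_c: np.ndarray | None = None,
    with_cb: bool = True,
    start_number: int = 1,
    chain_id: str = "A",
    res_name: str = "ALA",
) -> Chain:
    """Build an n-residue poly-Ala chain from exact internal coordinates.

    ``phi[i]``/``psi[i]`` are the dihedrals of residue i (phi[0] and psi[-1]
    are unused); ``omega[i]`` is the peptide torsion between residues i and
    i+1 (omega[-1] unused); ``ncac[i]`` the N-Ca-C bond angle; ``theta_c[i]``
    the prescribed carbonyl pyramidalization of peptide i, realised by
    placing O(i) at improper torsion tau(Ca_i, N_{i+1}, C_i, O_i) =
    180 + theta_c[i].
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    n = len(phi)
    if n < 2 or len(psi) != n:
        raise ValueError("need phi/psi arrays of equal length >= 2")
    omega = np.full(n, 180.0) if omega is None else np.asarray(omega, float)
    ncac = np.full(n, ANGLE_N_CA_C) if ncac is None else np.asarray(ncac, float)
    theta_c = np.zeros(n) if theta_c is None else np.asarray(theta_c, float)

    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    # first residue seeded in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    a0 = math.radians(180.0 - ncac[0])
    C[0] = CA[0] + BOND_CA_C * np.array([math.cos(a0), math.sin(a0), 0.0])
    for i in range(1, n):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ncac[i], phi[i])

    residues: list[Residue] = []
    for i in range(n):
        atoms = [
            Atom("N", "N", N[i]),
            Atom("CA", "C", CA[i]),
            Atom("C", "C", C[i]),
        ]
        if i < n - 1:
            # carbonyl O with prescribed pyramidalization at C(i)
            O = place_atom(CA[i], N[i + 1], C[i], BOND_C_O, ANGLE_N1_C_O, 180.0 + theta_c[i])
        else:
            O = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_N1_C_O, 180.0)
        atoms.append(Atom("O", "O", O))
        if with_cb and res_name != "GLY":
            CB = place_atom(C[i], N[i], CA[i], BOND_CA_CB, ANGLE_N_CA_CB, TORSION_CB)
            atoms.append(Atom("CB", "C", CB))
        residues.append(Residue(res_name, start_number + i, atoms=atoms))
    return Chain(chain_id, residues)


def make_peptide(
    n_res: int,
    phi: float = STRAND_PHI,
    psi: float = STRAND_PSI,
    omega: float = 180.0,
    ncac: float = ANGLE_N_CA_C,
    theta_c: float = 0.0,
    chain_id: str = "A",
    start_number: int = 1,
    with_cb: bool = True,
) -> Structure:
    """Uniform-dihedral peptide; the simplest geometry fixture."""
    ch = build_backbone(
        np.full(n_res, phi), np.full(n_res, psi), np.full(n_res, omega),
        np.full(n_res, ncac), np.full(n_res, theta_c),
        with_cb=with_cb, start_number=start_number, chain_id=chain_id,
    )
    return Structure(chains=[ch], id=f"peptide{n_res}")


# ---------------------------------------------------------------------------
# Two-lobe monomer and swapped dimer
# ---------------------------------------------------------------------------

HINGE_LEN = 3  # extended residues at the start of the C-terminal tail


def make_two_lobe_monomer(spec: ToySpec) -> tuple[Structure, dict[str, DomainDefinition]]:
    """Bilobed poly-Ala monomer: two helical lobes, an extended inter-lobe
    linker, and a C-terminal tail whose first residues are extended (the
    swap hinge) followed by a helix (the swapped segment).

    Returns the structure plus named DomainDefinitions (lobe1, lobe2,
    linker, hinge, tail, main_body) in author numbering starting at 1.
    """
    n1 = n2 = spec.n_res_per_lobe
    nl = spec.linker_length
    nt = spec.helix_tail_length
    hinge_len = min(HINGE_LEN, max(nt - 1, 0))
    n = n1 + nl + n2 + nt

    phi = np.empty(n)
    psi = np.empty(n)
    seg = np.zeros(n, dtype=int)  # 0 lobe1, 1 linker, 2 lobe2, 3 hinge, 4 tail helix
    idx = 0
    for length, code, (p, q) in (
        (n1, 0, (HELIX_PHI, HELIX_PSI)),
        (nl, 1, (STRAND_PHI, STRAND_PSI)),
        (n2, 2, (HELIX_PHI, HELIX_PSI)),
        (hinge_len, 3, (STRAND_PHI, STRAND_PSI)),
        (nt - hinge_len, 4, (HELIX_PHI, HELIX_PSI)),
    ):
        phi[idx:idx + length] = p
        psi[idx:idx + length] = q
        seg[idx:idx + length] = code
        idx += length

    chain = build_backbone(phi, psi, chain_id="A")
    st = Structure(chains=[chain], id=f"two_lobe_{spec.seed}")

    def rng(code: int) -> tuple[int, int]:
        nums = [r.number for r, c in zip(chain.residues, seg) if c == code]
        return nums[0], nums[-1]

    lo1, hi1 = rng(0)
    lo_l, hi_l = rng(1)
    lo2, hi2 = rng(2)
    if hinge_len:
        lo_h, hi_h = rng(3)
    else:
        lo_h, hi_h = rng(4)[0], rng(4)[0]
    lo_t, hi_t = rng(4)
    domains = {
        "lobe1": DomainDefinition("lobe1", [("A", lo1, hi1)]),
        "linker": DomainDefinition("linker", [("A", lo_l, hi_l)]),
        "lobe2": DomainDefinition("lobe2", [("A", lo2, hi2)]),
        "hinge": DomainDefinition("hinge", [("A", lo_h, hi_h)]),
        "tail": DomainDefinition("tail", [("A", lo_t, hi_t)]),
        "main_body": DomainDefinition("main_body", [("A", lo1, hi2)]),
    }
    return st, domains


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero-length rotation axis")
    u = axis / norm
    t = math.radians(angle_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def apply_domain_rotation(
    structure: Structure,
    domain: DomainDefinition,
    axis: np.ndarray,
    angle_deg: float,
    pivot: np.ndarray,
) -> Structure:
    """Rigidly rotate only the domain's atoms about (axis, pivot)."""
    R = _rotation_about(axis, angle_deg)
    pivot = np.asarray(pivot, float)
    new = structure.copy()
    for c in new.chains:
        for r in c.residues:
            if domain.contains(c.id, r.number):
                for a in r.atoms:
                    a.pos = R @ (a.pos - pivot) + pivot
    return new


def _all_coords(st: Structure, chain_id: str | None = None) -> np.ndarray:
    pts = []
    for c in st.chains:
        if chain_id is not None and c.id != chain_id:
            continue
        for r in c.residues:
            for a in r.atoms:
                pts.append(a.pos)
    return np.array(pts)


def make_swapped_dimer(
    monomer: Structure,
    domains: dict[str, DomainDefinition],
    separation: float = 4.0,
) -> tuple[Structure, dict[str, DomainDefinition]]:
    """Exact 2-fold symmetric swapped dimer from a two-lobe monomer.

    Chain B is chain A rotated 180 degrees about an axis perpendicular to
    the body-to-tail direction, placed so that each chain's C-terminal tail
    packs against the *other* chain's main body at a closest-approach
    distance of ``separation`` Angstrom.  By construction the only short
    inter-chain contacts are tail <-> opposite main body (the closed,
    C-interface of a swapped dimer); the main bodies never meet.
    """
    from scipy.spatial import cKDTree

    chain_a = monomer.chains[0]
    tail = domains["tail"]
    hinge = domains["hinge"]
    body = domains["main_body"]
    if len(tail.ranges) != 1 or (tail.ranges[0][2] - tail.ranges[0][1] + 1) < 4:
        raise ValueError("tail too short to span the two-fold axis (need >= 4 residues)")

    def region_xyz(dom: DomainDefinition) -> np.ndarray:
        return np.array([a.pos for r in chain_a.residues for a in r.atoms
                         if dom.contains("A", r.number)])

    def region_cb(dom: DomainDefinition) -> np.ndarray:
        pts = [r.atom("CB").pos for r in chain_a.residues
               if dom.contains("A", r.number) and r.atom("CB") is not None]
        return np.array(pts) if pts else np.empty((0, 3))

    body_xyz, hinge_xyz, tail_xyz = region_xyz(body), region_xyz(hinge), region_xyz(tail)
    body_cb, tail_cb = region_cb(body), region_cb(tail)
    if not len(body_cb) or not len(tail_cb):
        raise ValueError("swapped-dimer packing needs CB atoms on body and tail")
    b, t = body_xyz.mean(axis=0), tail_xyz.mean(axis=0)
    u = t - b
    d = np.linalg.norm(u)
    if d < 1e-6:
        raise ValueError("tail does not protrude from the body")
    u /= d
    e = np.eye(3)[np.argmin(np.abs(u))]
    v = np.cross(u, e)
    v /= np.linalg.norm(v)      # two-fold axis direction, perpendicular to u
    w = np.cross(u, v)          # lateral offset direction

    R = _rotation_about(v, 180.0)

    # Chain B is the 180-degree image about the axis (v, through P) with
    #   P = (b + t)/2 + (delta/2) w + (s/2) u.
    # delta sets the tail <-> opposite-body closest approach; s slides the
    # image along the protrusion axis.  A deterministic grid-plus-bisection
    # search picks (s, delta) so that the tail packs at ``separation`` while
    # every other region pair (body-body, hinge-anything, tail-tail) stays
    # well clear of contact cutoffs — the construction guarantee that all
    # inter-chain contacts belong to the closed (C) interface.
    # the image transform is an involution, so every region-pair distance can
    # be computed by transforming one side's points against fixed trees
    trees = {
        "body": cKDTree(body_xyz),
        "hinge": cKDTree(hinge_xyz),
        "tail": cKDTree(tail_xyz),
        "body_cb": cKDTree(body_cb),
    }

    def region_mins(s: float, delta: float, sign: float) -> dict[str, float]:
        P = (b + t) / 2.0 + (delta / 2.0) * sign * w + (s / 2.0) * u
        img = lambda X: (X - P) @ R.T + P

        def dmin(tree_key: str, pts: np.ndarray) -> float:
            return float(trees[tree_key].query(img(pts), k=1)[0].min())

        return {
            # packing metric: side-chain carbon pairs, so the interface shows
            # up in the hydrophobic-contact census
            "tail_body": dmin("body_cb", tail_cb),
            "tail_body_any": dmin("body", tail_xyz),
            "body_body": dmin("body", body_xyz),
            "hinge_body": min(dmin("body", hinge_xyz), dmin("hinge", body_xyz)),
            "hinge_hinge": dmin("hinge", hinge_xyz),
            "tail_hinge": min(dmin("hinge", tail_xyz), dmin("tail", hinge_xyz)),
            "tail_tail": dmin("tail", tail_xyz),
        }

    def tail_body_only(s: float, delta: float, sign: float) -> float:
        P = (b + t) / 2.0 + (delta / 2.0) * sign * w + (s / 2.0) * u
        return float(trees["body_cb"].query((tail_cb - P) @ R.T + P, k=1)[0].min())

    best: tuple[float, float, float, float] | None = None
    for sign in (1.0, -1.0):
        for s in np.arange(-10.0, 25.0, 1.0):
            lo, hi = 0.0, 80.0
            for _ in range(40):
                mid = (lo + hi) / 2.0
                if tail_body_only(s, mid, sign) < separation:
                    lo = mid
                else:
                    hi = mid
            delta = (lo + hi) / 2.0
            m = region_mins(s, delta, sign)
            if m["tail_body_any"] < 2.8:  # steric clash at the packed interface
                continue
            margin = min(val for key, val in m.items()
                         if key not in ("tail_body", "tail_body_any"))
            if best is None or margin > best[0]:
                best = (margin, s, delta, sign)
    if best is None:
        raise ValueError("no clash-free tail-body packing found")
    margin, s, delta, sign = best
    if margin < 6.0:
        raise ValueError(f"could not isolate the tail-body interface (clearance {margin:.1f} A)")
    P = (b + t) / 2.0 + (delta / 2.0) * sign * w + (s / 2.0) * u

    dimer = Structure(id=monomer.id + "_dimer")
    chain_a2 = monomer.copy().chains[0]
    chain_a2.id = "A"
    chain_b = monomer.copy().chains[0]
    chain_b.id = "B"
    for r in chain_b.residues:
        for at in r.atoms:
            at.pos = R @ (at.pos - P) + P
    dimer.chains = [chain_a2, chain_b]

    ddom = {}
    for key in ("lobe1", "lobe2", "linker", "hinge", "tail", "main_body"):
        spans = domains[key].ranges
        ddom[key] = DomainDefinition(key, [("A", s, e) for _, s, e in spans] + [("B", s, e) for _, s, e in spans])
    return dimer, ddom


def perturb(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """Isotropic Gaussian coordinate noise, deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    new = structure.copy()
    if sigma == 0:
        return new
    rng = np.random.default_rng(seed)
    for c in new.chains:
        for r in c.residues:
            for a in r.atoms:
                a.pos = a.pos + rng.normal(0.0, sigma, size=3)
    return new


# ---------------------------------------------------------------------------
# Ideal peptide fixtures for the stereochemistry module
# ---------------------------------------------------------------------------

def _make_sheet(n_res: int = 8) -> Structure:
    """Ideal antiparallel two-strand beta sheet.

    The strand frame is taken from the built strand itself: extent axis u
    (Ca_first -> Ca_last), carbonyl/H-bond axis w (the minor SVD component
    of the backbone — C=O bonds point along +-w in an extended strand), and
    pleat axis v = w x u.  The partner strand is the 180-degree rotation of
    the first about v (the crystallographic two-fold of an antiparallel
    pair), translated in the sheet (u, w) plane by a deterministic grid
    search that maximises the number of cross-strand backbone N...O pairs
    at hydrogen-bond distance without steric overlap.
    """
    from scipy.spatial import cKDTree

    s1 = make_peptide(n_res, phi=STRAND_PHI, psi=STRAND_PSI, chain_id="A")
    ch1 = s1.chains[0]
    xyz1 = _all_coords(s1)
    c = xyz1.mean(axis=0)
    ca = np.array([r.atom("CA").pos for r in ch1.residues])
    u = ca[-1] - ca[0]
    u /= np.linalg.norm(u)
    _, _, Vt = np.linalg.svd(xyz1 - c)
    w = Vt[2]
    v = np.cross(w, u)
    v /= np.linalg.norm(v)
    R = _rotation_about(v, 180.0)

    n1 = np.array([r.atom("N").pos for r in ch1.residues])
    o1 = np.array([r.atom("O").pos for r in ch1.residues])

    best = (-1, 0.0, 4.8)
    for a_ in np.arange(-6.0, 6.0, 0.1):
        for b_ in np.arange(3.5, 6.5, 0.1):
            for sb in (1.0, -1.0):
                t = a_ * u + sb * b_ * w
                x2 = (xyz1 - c) @ R.T + c + t
                if cKDTree(x2).query(xyz1, k=1)[0].min() < 2.6:
                    continue
                n2 = (n1 - c) @ R.T + c + t
                o2 = (o1 - c) @ R.T + c + t
                good = sum(1 for p in n1 if np.min(np.linalg.norm(o2 - p, axis=1)) <= 3.3) \
                    + sum(1 for p in n2 if np.min(np.linalg.norm(o1 - p, axis=1)) <= 3.3)
                if good > best[0]:
                    best = (good, a_, sb * b_)
    _, a_, b_ = best
    t = a_ * u + b_ * w
    ch2 = make_peptide(n_res, phi=STRAND_PHI, psi=STRAND_PSI, chain_id="B").chains[0]
    for r in ch2.residues:
        for at in r.atoms:
            at.pos = R @ (at.pos - c) + c + t
    return Structure(chains=[ch1, ch2], id="ideal_sheet")


def make_ideal_peptide_fixtures() -> dict[str, Structure]:
    """Named exact-geometry fixtures for the stereochemistry oracles.

    Keys: ``helix`` (12-residue ideal alpha helix), ``sheet`` (antiparallel
    two-strand), ``dipeptide`` (planar trans), ``omega175`` (all peptides at
    omega 175, Delta-omega -5), ``pyramidal3`` (theta_c +3 at every
    carbonyl), ``ncac104`` (NCaC bond angle 104 everywhere).
    """
    return {
        "helix": make_peptide(12, phi=HELIX_PHI, psi=HELIX_PSI, chain_id="A"),
        "sheet": _make_sheet(),
        "dipeptide": make_peptide(2, phi=STRAND_PHI, psi=STRAND_PSI),
        "omega175": make_peptide(6, omega=175.0),
        "pyramidal3": make_peptide(6, theta_c=3.0),
        "ncac104": make_peptide(6, ncac=104.0),
    }
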