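"""Rigid-body superposition, RMSD and domain-closure analysis.

The closure ("Venus fly-trap") angle between two conformers of a bilobed
protein is measured with a deterministic two-stage fit: superpose on the
fixed lobe, then measure the residual rotation that carries the moving lobe
of one conformer onto the other.  Lobe definitions are supplied explicitly
(the analysis uses published residue ranges), so no automatic domain
detection is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure import DomainDefinition, Structure, select

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "DomainMotionResult",
    "kabsch",
    "rmsd",
    "closure_analysis",
    "rotation_angle_axis",
]

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    rotation: np.ndarray  # 3x3, proper orthonormal
    translation: np.ndarray  # 3-vector

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not math.isclose(np.linalg.det(R), 1.0, abs_tol=1e-9):
            raise ValueError("rotation determinant is not +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int


@dataclass
class DomainMotionResult:
    angle: float          # degrees, [0, 180]
    axis: np.ndarray      # unit vector, right-handed rotation sense
    fixed_rmsd: float     # Angstrom, after the fixed-domain fit
    moving_rmsd: float    # Angstrom, of the moving domain in the fixed frame


def kabsch(coords_ref: np.ndarray, coords_mov: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid transform mapping ``coords_mov`` onto ``coords_ref``.

    Classic SVD solution with reflection correction (the sign of the smallest
    singular value is flipped when det < 0 so the result is a proper
    rotation).  Requires >= 3 paired points spanning at least a plane.
    """
    A = np.asarray(coords_ref, float)
    B = np.asarray(coords_mov, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"paired Nx3 coordinate arrays required, got {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"at least 3 paired atoms required, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-12 * max(S[0], 1.0):
        raise ValueError("degenerate point set (collinear or coincident)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    resid = A0 - B0 @ R.T
    value = float(np.sqrt((resid ** 2).sum() / n))
    return SuperpositionResult(RigidTransform(R, t), value, n)


def rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, [0,180]) and right-handed unit axis of a rotation matrix."""
    R = np.asarray(R, float)
    # tr(R) = 1 + 2 cos(theta); |skew vector| = 2 sin(theta).  atan2 of the
    # two is well conditioned at both ends (acos alone loses ~sqrt(eps) of
    # precision near 0 and 180 degrees)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    nw = np.linalg.norm(w)
    angle = math.degrees(math.atan2(nw, np.trace(R) - 1.0))
    if nw > 1e-12:
        axis = w / nw
    else:
        evals, evecs = np.linalg.eigh((R + R.T) / 2.0)
        axis = evecs[:, np.argmax(evals)] if angle < 90 else evecs[:, np.argmin(np.abs(evals - 1.0))]
        # for angle ~180 the +1 eigenvector of R itself is the axis
        evals_r, evecs_r = np.linalg.eig(R)
        k = int(np.argmin(np.abs(evals_r - 1.0)))
        axis = np.real(evecs_r[:, k])
        axis /= np.linalg.norm(axis)
    return angle, axis


def _paired_selection(
    struct_a: Structure,
    struct_b: Structure,
    domain_a: DomainDefinition,
    domain_b: DomainDefinition,
    atom_names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates paired by (residue number, atom name); unmatched dropped."""
    ca, ia = select(struct_a, domain_a, atom_names)
    cb, ib = select(struct_b, domain_b, atom_names)
    pos_a = {(num, an): k for k, (_, num, an) in enumerate(ia)}
    pos_b = {(num, an): k for k, (_, num, an) in enumerate(ib)}
    common = [key for key in pos_a if key in pos_b]
    common.sort()
    dropped = (len(ia) - len(common)) + (len(ib) - len(common))
    if dropped:
        logger.info("residue pairing dropped %d unmatched atoms", dropped)
    if len(common) < 3:
        raise ValueError(f"pairing produced only {len(common)} atoms (need >= 3)")
    return ca[[pos_a[k] for k in common]], cb[[pos_b[k] for k in common]]


def rmsd(
    struct_a: Structure,
    struct_b: Structure,
    selection_a: DomainDefinition,
    selection_b: DomainDefinition | None = None,
    atom_names: Sequence[str] = ("CA",),
    fit: bool = True,
) -> float:
    """RMSD between two structures over paired selections.

    With ``fit`` the optimal rigid superposition is applied first; otherwise
    coordinates are compared in their current frames.
    """
    if selection_b is None:
        selection_b = selection_a
    A, B = _paired_selection(struct_a, struct_b, selection_a, selection_b, atom_names)
    if fit:
        return kabsch(A, B).rmsd
    return float(np.sqrt(((A - B) ** 2).sum() / len(A)))


def closure_analysis(
    struct_a: Structure,
    struct_b: Structure,
    fixed_domain: DomainDefinition,
    moving_domain: DomainDefinition,
    atom_names: Sequence[str] = ("CA",),
    fixed_domain_b: DomainDefinition | None = None,
    moving_domain_b: DomainDefinition | None = None,
) -> DomainMotionResult:
    """Inter-domain (closure) rotation between two conformers.

    Stage 1 superposes conformer B onto A over the fixed domain; stage 2 fits
    the transformed moving domain of B onto A's moving domain.  The stage-2
    rotation is the closure: its angle is reported in [0, 180] degrees with a
    right-handed unit axis, together with both diagnostic RMSDs.
    """
    fixed_b = fixed_domain_b or fixed_domain
    moving_b = moving_domain_b or moving_domain
    FA, FB = _paired_selection(struct_a, struct_b, fixed_domain, fixed_b, atom_names)
    MA, MB = _paired_selection(struct_a, struct_b, moving_domain, moving_b, atom_names)
    stage1 = kabsch(FA, FB)
    MB_in_A = stage1.transform.apply(MB)
    moving_rmsd = float(np.sqrt(((MA - MB_in_A) ** 2).sum() / len(MA)))
    stage2 = kabsch(MA, MB_in_A)
    angle, axis = rotation_angle_axis(stage2.transform.rotation)
    return DomainMotionResult(angle=angle, axis=axis, fixed_rmsd=stage1.rmsd, moving_rmsd=moving_rmsd)
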