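"""Torsion angles and rigid-body least-squares superposition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["dihedral", "RigidTransform", "superpose", "rmsd", "place_atom"]


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, 180].

    IUPAC sign convention: looking from p2 towards p3, a clockwise rotation
    of p4 relative to p1 is positive. Torsions are reversal-symmetric:
    dihedral(p1..p4) == dihedral(p4..p1).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b, label in ((p1, p2, "p1/p2"), (p2, p3, "p2/p3"), (p3, p4, "p3/p4")):
        if np.linalg.norm(b - a) < 1e-9:
            raise ValueError(f"degenerate geometry: consecutive points {label} coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate geometry: collinear points leave torsion undefined")
    m1 = np.cross(b2 / np.linalg.norm(b2), n1)
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    # normalize -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R @ x + t with its least-squares fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        if self.fit_rmsd < 0:
            raise ValueError("fit_rmsd must be non-negative")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares fit of ``mobile`` onto ``reference`` (Kabsch).

    Minimizes RMSD over proper rotations + translations; mirror solutions
    are excluded, so a mirror-image point set keeps a positive residual.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"cardinality mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a unique rigid fit")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m0 = mobile - mc
    r0 = reference - rc
    # collinearity check: rank of the centered set
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2:
        raise ValueError("degenerate point set: all mobile points collinear")
    rot, rssd = Rotation.align_vectors(r0, m0)
    R = rot.as_matrix()
    t = rc - R @ mc
    fit = float(rssd / np.sqrt(n))
    return RigidTransform(R, t, fit)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without refitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def place_atom(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place a fourth atom from internal coordinates (NeRF construction).

    The new atom X satisfies |X-p3| = bond, angle(p2,p3,X) = angle_deg and
    dihedral(p1,p2,p3,X) = torsion_deg.
    """
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return p3 + d[0] * bc + d[1] * m + d[2] * n
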