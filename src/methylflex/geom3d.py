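"""Small 3-D geometry kernel: torsions, internal-coordinate placement,
rigid-body fits and rotations.  Angles in degrees, distances in Angstrom."""

from __future__ import annotations

import numpy as np

__all__ = ["torsion", "angle_between", "place_atom", "kabsch",
           "rotation_about_axis", "wrap180", "wrap360"]


def wrap180(angle):
    """Wrap angle(s) to (-180, +180] degrees."""
    a = np.asarray(angle, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def wrap360(angle):
    """Wrap angle(s) to [0, 360) degrees."""
    a = np.asarray(angle, dtype=float)
    out = a % 360.0
    return out if out.ndim else float(out)


def torsion(p1, p2, p3, p4) -> float:
    """Signed torsion p1-p2-p3-p4 in (-180, +180], IUPAC convention.

    Cis (eclipsed) is 0 deg; the sign follows the right-hand rule about
    the p2->p3 axis.  Raises on coincident consecutive points or three
    collinear consecutive points.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < 1e-10:
            raise ValueError(f"degenerate torsion: coincident points {a} {b}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate torsion: three collinear points")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang  # atan2 boundary: map -pi to +pi


def angle_between(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float):
    """Place atom d bonded to c with |cd| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = dihedral (NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang, dih = np.radians(angle), np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(dih),
        np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through origin."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation R and translation t with R @ mobile_i + t ~ ref_i.

    Proper rotation (no reflection); returns (R, t, rmsd).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - reference) ** 2).sum(axis=1).mean()))
    return R, t, rmsd
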