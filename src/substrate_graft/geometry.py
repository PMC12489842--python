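"""Low-level vector geometry shared across modules.

All angles are in degrees, all lengths in Angstrom.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in (-180, 180], IUPAC sign convention."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise GeometryError("rotation axis has zero length")
    x, y, z = axis / norm
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Natural-extension placement of atom d bonded to c.

    Returns the position with |d-c| = ``bond``, angle(b, c, d) =
    ``bond_angle`` and dihedral(a, b, c, d) = ``torsion``.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise GeometryError("collinear reference atoms in place_atom")
    n /= n_norm
    m = np.cross(n, bc)
    ang = np.radians(180.0 - bond_angle)
    tor = np.radians(torsion)
    d_local = np.array([
        bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    # local frame: bc, m, n
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through >= 3 points."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise GeometryError("plane fitting needs at least 3 points")
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8:
        raise GeometryError("degenerate (collinear) points: no unique plane")
    return vt[2]


def pairwise_distances(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
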