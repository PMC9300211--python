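"""Elementary vector geometry on atomic coordinates.

Signed dihedrals follow the IUPAC convention: looking from atom b towards
atom c, the angle is positive when the far bond c->d is rotated clockwise
relative to the near bond b->a.  Values are reported in (-180, 180] degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = ["distance", "angle", "dihedral", "unit_vector", "nerf_place", "kabsch_rmsd"]


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance |a - b|."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def unit_vector(origin: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Unit vector pointing from *origin* to *target*."""
    v = np.asarray(target, float) - np.asarray(origin, float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise a zero-length vector")
    return v / n


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, in degrees within [0, 180]."""
    u = unit_vector(b, a)
    v = unit_vector(b, c)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a-b-c-d in degrees, IUPAC sign, range (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    theta: float,
    chi: float,
) -> np.ndarray:
    """Place atom D bonded to *c* by internal coordinates.

    Natural-extension-of-reference-frame construction: D is at distance
    *bond* from c, with angle(b, c, D) = *theta* and dihedral(a, b, c, D) =
    *chi* (both in degrees).
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta_r = np.radians(theta)
    chi_r = np.radians(chi)
    d_local = bond * np.array(
        [
            -np.cos(theta_r),
            np.sin(theta_r) * np.cos(chi_r),
            -np.sin(theta_r) * np.sin(chi_r),
        ]
    )
    bc = unit_vector(b, c)
    n = np.cross(b - a, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:
        raise ValueError("collinear reference frame in nerf_place")
    n /= n_norm
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD between coordinate sets after optimal superposition (Kabsch)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    diff = qc - pc @ rot.T
    return float(np.sqrt((diff**2).sum() / len(p)))
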