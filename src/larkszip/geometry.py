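"""Small rigid-geometry toolkit: dihedrals, internal-coordinate atom placement,
and least-squares superposition.

Everything here works in Angstroms and degrees and is deliberately free of any
chemistry; higher modules supply bond lengths/angles.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle",
    "place_atom",
    "rotation_about_axis",
    "kabsch",
    "superpose",
    "rmsd",
    "random_rigid_transform",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = _unit(np.asarray(a, float) - b)
    w = _unit(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = _unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(a, b, c, bond: float, ang_deg: float, dih_deg: float) -> np.ndarray:
    """NeRF placement: position of atom d such that |cd| = bond,
    angle(b, c, d) = ang_deg and dihedral(a, b, c, d) = dih_deg.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    ang = np.radians(ang_deg)
    dih = np.radians(dih_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about ``axis``."""
    u = _unit(np.asarray(axis, float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    return np.array(
        [
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ]
    )


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ mobile.T + t ~= target.

    Returns (R, t) such that ``mobile @ R.T + t`` superposes onto ``target``.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return ``mobile`` superposed onto ``target`` (least squares)."""
    R, t = kabsch(mobile, target)
    return np.asarray(mobile, float) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray, superposed: bool = False) -> float:
    """RMSD between matched coordinate sets; optionally after superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if superposed:
        a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 20.0):
    """Uniform random rotation (QR-based) plus bounded random translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation, max_translation, size=3)
    return Q, t
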