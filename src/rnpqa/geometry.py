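"""Small vector-geometry helpers shared across modules.

All angles are in degrees unless a name says otherwise; coordinates are
float64 Angstrom 3-vectors.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle_between",
    "bond_angle",
    "rotation_matrix",
    "random_rotation",
    "nerf_place",
]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, range (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    return angle_between(np.asarray(a, float) - b, np.asarray(c, float) - b)


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        return np.eye(3)
    x, y, z = axis / n
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def random_rotation(rng: np.random.Generator, max_angle_deg: float | None = None) -> np.ndarray:
    """Uniform random rotation axis; angle uniform in [0, max] (or [0, 180])."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    hi = 180.0 if max_angle_deg is None else max_angle_deg
    return rotation_matrix(v, rng.uniform(0.0, hi))


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms a, b, c.

    D is at distance ``bond`` from c, with angle b-c-D = ``angle_deg`` and
    dihedral a-b-c-D = ``torsion_deg`` (natural extension reference frame).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = -np.radians(torsion_deg)  # sign matches the dihedral() convention
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
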