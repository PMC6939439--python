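"""Internal-coordinate geometry: measurement and NeRF-style atom placement.

An internal-coordinate record places atom X relative to three reference
positions (r1, r2, r3) as

    |X - r1| = length,  angle(X, r1, r2) = angle,  torsion(X, r1, r2, r3) = torsion.

Placement from exact references reproduces the original Cartesian position
exactly, which is what makes template-built models satisfy their own ideal
restraints to machine precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bond_length",
    "bond_angle",
    "torsion_angle",
    "place_atom",
]


def bond_length(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def torsion_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(
    r1: np.ndarray,
    r2: np.ndarray,
    r3: np.ndarray,
    length: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place a new atom X with |X-r1| = length, angle(X,r1,r2) = angle (deg)
    and torsion(X,r1,r2,r3) = torsion (deg)."""
    r1, r2, r3 = (np.asarray(x, float) for x in (r1, r2, r3))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # Local frame at r1 with x along r2->r1.
    bc = r1 - r2
    bc /= np.linalg.norm(bc)
    n = np.cross(r2 - r3, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms in internal-coordinate placement")
    n /= nn
    m = np.cross(n, bc)
    d = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            -length * np.sin(ang) * np.sin(tor),
        ]
    )
    return r1 + d[0] * bc + d[1] * m + d[2] * n
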