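"""Ideal-geometry restraint target with analytic gradients.

Every class is a weighted residual sum((value - ideal)/sigma)^2: bonds (A),
angles (deg), omega torsions (deg, deviation wrapped into the period),
chiral volumes (A^3), planarity (A, deviations from the least-squares plane)
and a purely repulsive nonbonded term

    sum max(0, r_i + r_j - tol - d)^2 / sigma_rep^2

over pairs within the screen distance, with 1-2/1-3/1-4, altloc cross-copy
and donor-acceptor pairs excluded.  Only repulsive, never attractive:
well-separated atoms contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomicModel
from .prep import RestraintSet

__all__ = ["GeoEnergyReport", "geo_target_grad", "geometry_rmsd"]


@dataclass
class GeoEnergyReport:
    total: float
    subtotals: dict[str, float]
    worst: list[tuple[str, int, float]] = field(default_factory=list)  # (class, id, dev/sigma)

    def __post_init__(self):
        assert abs(self.total - sum(self.subtotals.values())) < 1e-9 * max(1.0, abs(self.total))


def _bond_terms(xyz, rs, grad):
    i, j = rs.bonds[:, 0], rs.bonds[:, 1]
    d_vec = xyz[i] - xyz[j]
    d = np.linalg.norm(d_vec, axis=1)
    if np.any(d < 1e-9):
        raise ValueError("zero-length bond vector (degenerate geometry)")
    dev = (d - rs.bond_ideal) / rs.bond_sigma
    coef = 2.0 * dev / rs.bond_sigma / d
    g = coef[:, None] * d_vec
    np.add.at(grad, i, g)
    np.add.at(grad, j, -g)
    return float(np.sum(dev**2)), dev


def _angle_terms(xyz, rs, grad):
    i, j, k = rs.angles.T
    u = xyz[i] - xyz[j]
    v = xyz[k] - xyz[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cu = u / nu[:, None]
    cv = v / nv[:, None]
    cos_t = np.clip(np.sum(cu * cv, axis=1), -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_t))
    dev = (theta - rs.angle_ideal) / rs.angle_sigma
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
    deg = 180.0 / np.pi
    dti = (cos_t[:, None] * cu - cv) / (nu * sin_t)[:, None] * deg
    dtk = (cos_t[:, None] * cv - cu) / (nv * sin_t)[:, None] * deg
    coef = (2.0 * dev / rs.angle_sigma)[:, None]
    np.add.at(grad, i, coef * dti)
    np.add.at(grad, k, coef * dtk)
    np.add.at(grad, j, -coef * (dti + dtk))
    return float(np.sum(dev**2)), dev


def torsion_value_grad(xyz, quads):
    """Dihedrals (deg) and their gradients for an (m, 4) index array.

    Returns (phi_deg, dphi (m, 4, 3) in deg/A).
    """
    a, b, c, d = (xyz[quads[:, x]] for x in range(4))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / nb2[:, None])
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    phi = np.degrees(np.arctan2(y, x))

    # exact analytic gradient (Blondel-Karplus construction, adapted to this
    # sign convention): F = a-b, G = b-c, H = d-c, A = FxG, B = HxG
    F = -b1
    G = -b2
    H = b3
    A = np.cross(F, G)
    B = np.cross(H, G)
    nG = np.linalg.norm(G, axis=1)
    A2 = np.sum(A * A, axis=1)
    B2 = np.sum(B * B, axis=1)
    fg = np.sum(F * G, axis=1)
    hg = np.sum(H * G, axis=1)
    da = (nG / A2)[:, None] * A
    dd = -(nG / B2)[:, None] * B
    db = -da - (fg / (A2 * nG))[:, None] * A + (hg / (B2 * nG))[:, None] * B
    dc = -dd + (fg / (A2 * nG))[:, None] * A - (hg / (B2 * nG))[:, None] * B
    deg = 180.0 / np.pi
    dphi = np.stack([da, db, dc, dd], axis=1) * deg
    return phi, dphi


def _wrap(dev, period):
    span = 360.0 / np.asarray(period, float)
    return (dev + span / 2.0) % span - span / 2.0


def _torsion_terms(xyz, rs, grad):
    if len(rs.torsions) == 0:
        return 0.0, np.zeros(0)
    phi, dphi = torsion_value_grad(xyz, rs.torsions)
    dev = _wrap(phi - rs.torsion_ideal, rs.torsion_period) / rs.torsion_sigma
    coef = 2.0 * dev / rs.torsion_sigma
    for col in range(4):
        np.add.at(grad, rs.torsions[:, col], coef[:, None] * dphi[:, col])
    return float(np.sum(dev**2)), dev


def _chiral_terms(xyz, rs, grad):
    if len(rs.chirals) == 0:
        return 0.0, np.zeros(0)
    c, p1, p2, p3 = (xyz[rs.chirals[:, x]] for x in range(4))
    v1, v2, v3 = p1 - c, p2 - c, p3 - c
    vol = np.sum(np.cross(v1, v2) * v3, axis=1)
    dev = (vol - rs.chiral_ideal) / rs.chiral_sigma
    coef = (2.0 * dev / rs.chiral_sigma)[:, None]
    d1 = np.cross(v2, v3)
    d2 = np.cross(v3, v1)
    d3 = np.cross(v1, v2)
    np.add.at(grad, rs.chirals[:, 1], coef * d1)
    np.add.at(grad, rs.chirals[:, 2], coef * d2)
    np.add.at(grad, rs.chirals[:, 3], coef * d3)
    np.add.at(grad, rs.chirals[:, 0], -coef * (d1 + d2 + d3))
    return float(np.sum(dev**2)), dev


def _plane_terms(xyz, rs, grad):
    total = 0.0
    devs = []
    inv_s2 = 1.0 / rs.plane_sigma**2
    for idxs in rs.planes:
        pts = xyz[idxs]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        # least-squares plane normal: smallest principal axis
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        normal = vt[-1]
        d = centered @ normal
        total += float(np.sum(d**2) * inv_s2)
        devs.append(np.max(np.abs(d)) / rs.plane_sigma)
        # plane parameters minimize the residual, so by the envelope theorem
        # they are held fixed when differentiating
        g = 2.0 * inv_s2 * d[:, None] * normal[None, :]
        np.add.at(grad, idxs, g)
    return total, np.array(devs)


def _repulsion_terms(xyz, rs, grad):
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(rs.repulsion_screen, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0, np.zeros(0)
    i, j = pairs.T
    keep = ~(rs.excluded[i, j] | rs.hb_exempt[i, j])
    i, j = i[keep], j[keep]
    d_vec = xyz[i] - xyz[j]
    d = np.linalg.norm(d_vec, axis=1)
    r_eff = rs.vdw_radius[i] + rs.vdw_radius[j] - rs.repulsion_tolerance
    overlap = r_eff - d
    act = overlap > 0
    if not np.any(act):
        return 0.0, np.zeros(0)
    i, j, d, d_vec, overlap = i[act], j[act], d[act], d_vec[act], overlap[act]
    dev = overlap / rs.repulsion_sigma
    coef = -2.0 * dev / rs.repulsion_sigma / d
    g = coef[:, None] * d_vec
    np.add.at(grad, i, g)
    np.add.at(grad, j, -g)
    return float(np.sum(dev**2)), dev


def geo_target_grad(
    model: AtomicModel, restraints: RestraintSet
) -> tuple[GeoEnergyReport, np.ndarray]:
    """Restraint residual, per-class breakdown, and analytic gradient."""
    xyz = model.coords
    grad = np.zeros_like(xyz)
    sub = {}
    worst: list[tuple[str, int, float]] = []
    for name, fn in (
        ("bond", _bond_terms),
        ("angle", _angle_terms),
        ("torsion", _torsion_terms),
        ("chirality", _chiral_terms),
        ("plane", _plane_terms),
        ("repulsion", _repulsion_terms),
    ):
        val, devs = fn(xyz, restraints, grad)
        sub[name] = val
        if len(devs):
            idx = int(np.argmax(np.abs(devs)))
            worst.append((name, idx, float(np.abs(devs[idx]))))
    worst.sort(key=lambda t: -t[2])
    report = GeoEnergyReport(total=sum(sub.values()), subtotals=sub, worst=worst)
    return report, grad


def geometry_rmsd(model: AtomicModel, restraints: RestraintSet) -> tuple[float, float]:
    """RMS deviation from ideal over all bond (A) and angle (deg) restraints."""
    if len(restraints.bonds) == 0 or len(restraints.angles) == 0:
        raise ValueError("need at least one bond and one angle restraint")
    xyz = model.coords
    i, j = restraints.bonds.T
    d = np.linalg.norm(xyz[i] - xyz[j], axis=1)
    rmsd_b = float(np.sqrt(np.mean((d - restraints.bond_ideal) ** 2)))
    i, j, k = restraints.angles.T
    u = xyz[i] - xyz[j]
    v = xyz[k] - xyz[j]
    cos_t = np.clip(
        np.sum(u * v, axis=1)
        / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)),
        -1.0,
        1.0,
    )
    theta = np.degrees(np.arccos(cos_t))
    rmsd_a = float(np.sqrt(np.mean((theta - restraints.angle_ideal) ** 2)))
    return rmsd_b, rmsd_a
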