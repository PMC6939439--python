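"""Molecular-mechanics restraint target (reduced Amber-style force field)
with analytic gradients, including the locally-enhanced-sampling (LES)
treatment of alternate conformers.

    E = sum kb (b - b0)^2 + sum ktheta (theta - theta0)^2
      + sum (V/2)(1 + cos(n phi - gamma))
      + sum_LJ eps [(rmin/r)^12 - 2 (rmin/r)^6] + sum_coul 332.0637 qi qj / r

1-2 and 1-3 pairs are excluded; 1-4 pairs are scaled (1/1.2 electrostatic,
1/2 LJ by default).  Nonbonded pairs beyond the 1-4 list use a 12 A cutoff
with a smooth switching function from 10 A, so the energy is C1-continuous
at the cutoff.  Under LES, every term is weighted by the product of the copy
weights of the distinct (group, copy) labels it touches, and terms linking
two different copies of the same group are dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geo import torsion_value_grad
from .model import AtomicModel
from .prep import MMTopology

__all__ = ["MMEnergyReport", "mm_energy_grad", "les_energy_grad", "COULOMB_CONSTANT"]

COULOMB_CONSTANT = 332.0637  # kcal A / (mol e^2)


@dataclass
class MMEnergyReport:
    total: float
    subtotals: dict[str, float]

    def __post_init__(self):
        assert abs(self.total - sum(self.subtotals.values())) < 1e-9 * max(1.0, abs(self.total))


def _pair_weights(top: MMTopology, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """LES weight of pair terms: product over distinct (group, copy) labels,
    zero when i and j are different copies of the same group."""
    gi, ci = top.copy_id[i, 0], top.copy_id[i, 1]
    gj, cj = top.copy_id[j, 0], top.copy_id[j, 1]
    wi = np.where(gi >= 0, top.copy_weight[i], 1.0)
    wj = np.where(gj >= 0, top.copy_weight[j], 1.0)
    same_copy = (gi >= 0) & (gi == gj) & (ci == cj)
    cross_copy = (gi >= 0) & (gi == gj) & (ci != cj)
    # distinct labels multiply; a shared label counts once
    w = wi * np.where(same_copy, 1.0, wj)
    w[cross_copy] = 0.0
    return w


def _term_weights(top: MMTopology, idx: np.ndarray) -> np.ndarray:
    """LES weight of an (m, arity) bonded-term index array."""
    m = len(idx)
    w = np.ones(m)
    for t in range(m):
        labels: dict[int, int] = {}
        wt = 1.0
        for a in idx[t]:
            g, c = top.copy_id[a]
            if g < 0:
                continue
            if g in labels:
                if labels[g] != c:
                    wt = 0.0
                    break
            else:
                labels[g] = c
                wt *= top.copy_weight[a]
        w[t] = wt
    return w


def _switch(r, r_on, r_off):
    """CHARMM-style C1 switching function and its derivative."""
    s = np.ones_like(r)
    ds = np.zeros_like(r)
    mid = (r > r_on) & (r < r_off)
    off2, on2 = r_off**2, r_on**2
    denom = (off2 - on2) ** 3
    r2 = r[mid] ** 2
    s[mid] = (off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2) / denom
    ds[mid] = 12.0 * r[mid] * (off2 - r2) * (on2 - r2) / denom
    s[r >= r_off] = 0.0
    return s, ds


def _energy_grad(model: AtomicModel, top: MMTopology, use_les: bool):
    xyz = model.coords
    grad = np.zeros_like(xyz)
    sub: dict[str, float] = {}

    # LES: drop zero-weight terms up front; cross-copy terms may sit on
    # degenerate geometry (coincident copies) that must never be evaluated
    def _weighted(idx):
        if not use_les or len(idx) == 0:
            return idx, np.ones(len(idx)), np.arange(len(idx))
        w = _term_weights(top, idx)
        keep = w > 0
        return idx[keep], w[keep], np.flatnonzero(keep)

    bonds_i, wb, bsel = _weighted(top.bonds)
    i, j = bonds_i.T if len(bonds_i) else (np.zeros(0, int), np.zeros(0, int))
    d_vec = xyz[i] - xyz[j]
    d = np.linalg.norm(d_vec, axis=1)
    if np.any(d < 1e-6):
        raise ValueError("overlapping bonded atoms (r < 1e-6 A)")
    kb = top.bond_kb[bsel]
    dev = d - top.bond_b0[bsel]
    sub["bond"] = float(np.sum(wb * kb * dev**2))
    coef = (wb * 2.0 * kb * dev / d)[:, None]
    np.add.at(grad, i, coef * d_vec)
    np.add.at(grad, j, -coef * d_vec)

    angles_i, wa, asel = _weighted(top.angles)
    ak = top.angle_k[asel]
    at0 = top.angle_t0[asel]
    i, j, k = angles_i.T if len(angles_i) else (np.zeros(0, int),) * 3
    u = xyz[i] - xyz[j]
    v = xyz[k] - xyz[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cu = u / nu[:, None]
    cv = v / nv[:, None]
    cos_t = np.clip(np.sum(cu * cv, axis=1), -1.0, 1.0)
    theta = np.arccos(cos_t)
    dev = theta - at0
    sub["angle"] = float(np.sum(wa * ak * dev**2))
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
    dti = (cos_t[:, None] * cu - cv) / (nu * sin_t)[:, None]
    dtk = (cos_t[:, None] * cv - cu) / (nv * sin_t)[:, None]
    coef = (wa * 2.0 * ak * dev)[:, None]
    np.add.at(grad, i, coef * dti)
    np.add.at(grad, k, coef * dtk)
    np.add.at(grad, j, -coef * (dti + dtk))

    tors_i, wt, tsel = _weighted(top.torsions)
    if len(tors_i):
        phi_deg, dphi_deg = torsion_value_grad(xyz, tors_i)
        phi = np.radians(phi_deg)
        dphi = dphi_deg * (np.pi / 180.0)
        v2 = top.torsion_v2[tsel]
        per = top.torsion_n[tsel]
        gam = top.torsion_gamma[tsel]
        arg = per * phi - gam
        sub["torsion"] = float(np.sum(wt * v2 * (1.0 + np.cos(arg))))
        coef = -wt * v2 * per * np.sin(arg)
        for col in range(4):
            np.add.at(grad, tors_i[:, col], coef[:, None] * dphi[:, col])
    else:
        sub["torsion"] = 0.0

    # nonbonded: all pairs within cutoff, minus exclusions and 1-4 pairs
    pairs = cKDTree(xyz).query_pairs(top.cutoff, output_type="ndarray")
    mask14 = getattr(top, "_mask14", None)
    if mask14 is None:
        mask14 = np.zeros_like(top.excluded)
        if len(top.pairs14):
            mask14[top.pairs14[:, 0], top.pairs14[:, 1]] = True
            mask14[top.pairs14[:, 1], top.pairs14[:, 0]] = True
        top._mask14 = mask14
    if len(pairs):
        i, j = pairs.T
        keep = ~(top.excluded[i, j] | mask14[i, j])
        i, j = i[keep], j[keep]
    else:
        i = j = np.zeros(0, dtype=int)
    lj, coul = _nonbonded(xyz, top, i, j, grad, use_les, switched=True)
    sub["lj"] = lj
    sub["coulomb"] = coul
    if len(top.pairs14):
        i, j = top.pairs14.T
        lj14, coul14 = _nonbonded(
            xyz, top, i, j, grad, use_les, switched=False,
            lj_scale=top.scale14_lj, coul_scale=top.scale14_elec,
        )
    else:
        lj14 = coul14 = 0.0
    sub["lj14"] = lj14
    sub["coulomb14"] = coul14

    report = MMEnergyReport(total=sum(sub.values()), subtotals=sub)
    return report, grad


def _nonbonded(xyz, top, i, j, grad, use_les, switched, lj_scale=1.0, coul_scale=1.0):
    if len(i) == 0:
        return 0.0, 0.0
    w = _pair_weights(top, i, j) if use_les else np.ones(len(i))
    act = w != 0.0
    i, j, w = i[act], j[act], w[act]
    if len(i) == 0:
        return 0.0, 0.0
    d_vec = xyz[i] - xyz[j]
    r = np.linalg.norm(d_vec, axis=1)
    if np.any(r < 1e-6):
        raise ValueError("overlapping nonbonded atoms (r < 1e-6 A)")
    rmin = top.lj_rmin2[i] + top.lj_rmin2[j]
    eps = np.sqrt(top.lj_eps[i] * top.lj_eps[j])
    x6 = (rmin / r) ** 6
    e_lj = lj_scale * eps * (x6**2 - 2.0 * x6)
    de_lj = lj_scale * eps * 12.0 * (x6 - x6**2) / r
    qq = COULOMB_CONSTANT * top.charges[i] * top.charges[j]
    e_c = coul_scale * qq / r
    de_c = -coul_scale * qq / r**2
    if switched:
        s, ds = _switch(r, top.switch_start, top.cutoff)
        de_lj = de_lj * s + e_lj * ds
        de_c = de_c * s + e_c * ds
        e_lj = e_lj * s
        e_c = e_c * s
    coef = (w * (de_lj + de_c) / r)[:, None]
    np.add.at(grad, i, coef * d_vec)
    np.add.at(grad, j, -coef * d_vec)
    return float(np.sum(w * e_lj)), float(np.sum(w * e_c))


def mm_energy_grad(model: AtomicModel, topology: MMTopology) -> tuple[MMEnergyReport, np.ndarray]:
    """Force-field energy (kcal/mol) and gradient for a single-conformer model."""
    if topology.has_les:
        raise ValueError("topology has LES groups; use les_energy_grad")
    return _energy_grad(model, topology, use_les=False)


def les_energy_grad(model: AtomicModel, topology: MMTopology) -> tuple[MMEnergyReport, np.ndarray]:
    """LES energy: copies of a group never see each other; everything else
    sees them through occupancy-weighted averages."""
    if not topology.has_les:
        raise ValueError("topology has no LES groups; use mm_energy_grad")
    for g in topology.les_groups:
        s = sum(g["weights"].values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"LES copy weights for chain {g['chain']} sum to {s}")
    return _energy_grad(model, topology, use_les=True)


def energy_grad(model: AtomicModel, topology: MMTopology) -> tuple[MMEnergyReport, np.ndarray]:
    """Dispatch to the plain or LES energy depending on the topology."""
    if topology.has_les:
        return les_energy_grad(model, topology)
    return mm_energy_grad(model, topology)
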