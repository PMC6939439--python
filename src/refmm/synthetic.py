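"""Synthetic toy crystals: ideal peptides in P1 boxes, simulated amplitudes
and seeded coordinate perturbations.

These fixtures stand in for deposited starting models: a ground-truth
all-atom peptide built from the residue templates at class phi/psi values,
error-free (or multiplicatively noisy) amplitudes computed from it, and a
Gaussian coordinate perturbation of exactly the requested RMSD playing the
role of an imperfect starting model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import assign_free_set
from .model import Atom, AtomicModel, Crystal, ReflectionSet
from .nerf import bond_angle, bond_length, place_atom
from .params import ParameterLibrary, load_library
from .xray import calc_fcalc

__all__ = ["ToyCrystalSpec", "make_toy_crystal", "simulate_fobs", "perturb_model"]

ONE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# class phi/psi in degrees
CONFORMATIONS = {
    "helix": (-57.0, -47.0),
    "strand": (-119.0, 113.0),
    "extended": (-180.0, 180.0),
}


@dataclass
class ToyCrystalSpec:
    sequence: str
    conformation: str = "helix"
    padding: float = 8.0       # A of empty cell on every side
    b_iso: float = 15.0
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) < 2:
            raise ValueError("sequence must have at least 2 residues")
        if self.conformation not in CONFORMATIONS:
            raise ValueError(f"unknown conformation {self.conformation!r}")
        if self.padding < 6.0:
            raise ValueError("padding must be >= 6 A to isolate the molecule")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")


def build_peptide(
    sequence: str,
    phi_psi: list[tuple[float, float]] | tuple[float, float],
    library: ParameterLibrary | None = None,
    chain: str = "A",
    b_iso: float = 15.0,
) -> AtomicModel:
    """All-atom peptide built from templates at the given phi/psi values.

    ``phi_psi`` is a single (phi, psi) pair applied to every residue or one
    pair per residue.  Backbone N/CA/C are chained with standard peptide-link
    geometry (omega = 180); O, the amide H and the side chains come from the
    template ideals, so every internal coordinate is at its restraint ideal.
    """
    library = library or load_library()
    res_names = []
    for ch in sequence:
        if ch not in ONE_LETTER:
            raise ValueError(f"unknown residue letter {ch!r}")
        res_names.append(ONE_LETTER[ch])
    nres = len(res_names)
    if isinstance(phi_psi, tuple):
        phi_psi = [phi_psi] * nres
    link = library.link
    ang_cacn = _link_angle(link, ("CA", "C", "N"))
    ang_cnca = _link_angle(link, ("C", "N", "CA"))

    bb: list[dict[str, np.ndarray]] = []
    for i, rn in enumerate(res_names):
        tpl = library.template(rn)
        d_nca, d_cac, ang_ncac = tpl.root
        phi, psi = phi_psi[i]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([d_nca, 0.0, 0.0])
            th = np.radians(ang_ncac)
            c = ca + d_cac * np.array([-np.cos(th), np.sin(th), 0.0])
        else:
            prev = bb[-1]
            psi_prev = phi_psi[i - 1][1]
            n = place_atom(prev["C"], prev["CA"], prev["N"], link.bond[2], ang_cacn, psi_prev)
            ca = place_atom(n, prev["C"], prev["CA"], d_nca, ang_cnca, 180.0)
            c = place_atom(ca, n, prev["C"], d_cac, ang_ncac, phi)
        bb.append({"N": n, "CA": ca, "C": c})

    atoms: list[Atom] = []
    for i, rn in enumerate(res_names):
        tpl = library.template(rn)
        ideal = library.ideal_coords(rn)
        coords = dict(bb[i])
        psi = phi_psi[i][1]
        for rec in tpl.ics:
            if rec.atom == "O":
                coords["O"] = place_atom(
                    coords["C"], coords["CA"], coords["N"],
                    bond_length(ideal["O"], ideal["C"]),
                    bond_angle(ideal["O"], ideal["C"], ideal["CA"]),
                    psi + 180.0,
                )
            elif rec.atom == "H" and i > 0:
                prev = bb[i - 1]
                o_prev = next(a for a in atoms if a.res_seq == i and a.name == "O")
                coords["H"] = place_atom(
                    coords["N"], prev["C"], o_prev.xyz,
                    library.ic_length(tpl, rec),
                    _link_angle(link, ("C", "N", "H")),
                    180.0,
                )
            else:
                coords[rec.atom] = place_atom(
                    coords[rec.r1], coords[rec.r2], coords[rec.r3],
                    library.ic_length(tpl, rec), rec.angle, rec.torsion,
                )
        for an in tpl.atoms:
            atoms.append(
                Atom(
                    name=an, element=tpl.elements[an], chain=chain,
                    res_name=rn, res_seq=i + 1, altloc="",
                    occupancy=1.0, b_iso=b_iso, xyz=coords[an],
                )
            )
    return AtomicModel(atoms)


def _link_angle(link, names):
    for a, b, c, val in link.angles:
        if (a, b, c) == names:
            return val
    raise KeyError(names)


def make_toy_crystal(
    spec: ToyCrystalSpec, library: ParameterLibrary | None = None
) -> tuple[AtomicModel, Crystal]:
    """Ground-truth model and its padded P1 cell.

    The peptide is translated so its bounding box starts ``padding`` A from
    the origin and the cell extends the same margin past it, which keeps
    periodic images far enough apart that ignoring symmetry contacts in the
    energy terms is exact.
    """
    library = library or load_library()
    phi, psi = CONFORMATIONS[spec.conformation]
    model = build_peptide(spec.sequence, (phi, psi), library, b_iso=spec.b_iso)
    xyz = model.coords
    lo = xyz.min(axis=0)
    hi = xyz.max(axis=0)
    shift = spec.padding - lo
    model = model.with_coords(xyz + shift)
    extent = hi - lo + 2 * spec.padding
    crystal = Crystal(*extent, 90.0, 90.0, 90.0)
    return model, crystal


def hkl_sphere(crystal: Crystal, d_min: float) -> np.ndarray:
    """Unique Miller indices (Friedel half) with d >= d_min, deterministic
    lexicographic order."""
    if d_min < 0.5:
        raise ValueError("d_min below 0.5 A is outside the form-factor table's validity")
    # conservative index bounds from the cell edges
    hmax = int(np.ceil(crystal.a / d_min))
    kmax = int(np.ceil(crystal.b / d_min))
    lmax = int(np.ceil(crystal.c / d_min))
    hs, ks, ls = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([hs.ravel(), ks.ravel(), ls.ravel()])
    nonzero = np.any(hkl != 0, axis=1)
    hkl = hkl[nonzero]
    # Friedel half: first nonzero index positive
    h, k, l_ = hkl.T
    half = (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l_ > 0))
    hkl = hkl[half]
    d = crystal.d_spacing(hkl)
    hkl = hkl[d >= d_min]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


def simulate_fobs(
    model: AtomicModel,
    crystal: Crystal,
    d_min: float,
    noise_fraction: float = 0.0,
    seed: int = 0,
    free_fraction: float = 0.05,
) -> ReflectionSet:
    """Simulated observed amplitudes to d_min with multiplicative Gaussian
    noise: f_obs = |F_calc| (1 + noise * eps), clipped at zero."""
    hkl = hkl_sphere(crystal, d_min)
    amp = calc_fcalc(model, crystal, hkl).amplitude
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(len(amp))
    f_obs = np.clip(amp * (1.0 + noise_fraction * eps), 0.0, None)
    sigma = noise_fraction * amp
    refl = ReflectionSet(hkl, f_obs, sigma, np.zeros(len(amp), bool))
    return assign_free_set(refl, free_fraction, seed=seed + 1)


def perturb_model(model: AtomicModel, target_rmsd: float, seed: int = 0) -> AtomicModel:
    """Seeded Gaussian coordinate displacement rescaled to the exact RMSD."""
    if target_rmsd < 0:
        raise ValueError("target RMSD must be >= 0")
    if target_rmsd == 0:
        return model.with_coords(model.coords)
    rng = np.random.default_rng(seed)
    disp = rng.standard_normal((len(model), 3))
    rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    disp *= target_rmsd / rms
    return model.with_coords(model.coords + disp)
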