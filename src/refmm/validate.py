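"""Model-quality metrics: C-beta deviation, clashscore, hydrogen bonds per
1000 atoms, and a combined validation report.

The C-beta deviation measures distortion of the tetrahedron around CA: an
ideal CB is rebuilt from the backbone (N, C, CA) twice -- once through each
of the N-C-CA-CB and C-N-CA-CB improper dihedrals -- the two positions are
averaged and the CA-CB vector is rescaled to the ideal bond length; the
deviation is the distance between the modeled CB and this ideal position.
Residues at or past 0.25 A are outliers.  Because the construction uses only
ideal internal coordinates, a residue whose angles about CA are all ideal
scores zero even if it sits in the wrong place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geo import geometry_rmsd
from .model import AtomicModel, Crystal, ReflectionSet
from .nerf import bond_angle, place_atom, torsion_angle
from .params import ParameterLibrary, load_library
from .prep import RestraintSet, _exclusion_masks, bond_graph

logger = logging.getLogger(__name__)

__all__ = [
    "CBETA_OUTLIER_THRESHOLD",
    "cbeta_deviation",
    "cbeta_deviations",
    "clashscore",
    "hbond_fraction",
    "validation_report",
    "ValidationReport",
]

CBETA_OUTLIER_THRESHOLD = 0.25  # A
CLASH_OVERLAP = 0.4             # A past van der Waals contact
HBOND_DIST = 3.5                # A donor-heavy to acceptor
HBOND_ANGLE = 135.0             # deg donor-H...acceptor


def ideal_cbeta_position(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, library: ParameterLibrary, res_name: str
) -> np.ndarray:
    """Ideal CB from the actual backbone and the residue's template ideals."""
    ideal = library.ideal_coords(res_name)
    if "CB" not in ideal:
        raise ValueError(f"{res_name} has no CB")
    length = float(np.linalg.norm(ideal["CB"] - ideal["CA"]))
    # via the N-C-CA-CB improper (reference leg through C)
    p1 = place_atom(
        ca, c, n, length,
        bond_angle(ideal["CB"], ideal["CA"], ideal["C"]),
        torsion_angle(ideal["CB"], ideal["CA"], ideal["C"], ideal["N"]),
    )
    # via the C-N-CA-CB improper (reference leg through N)
    p2 = place_atom(
        ca, n, c, length,
        bond_angle(ideal["CB"], ideal["CA"], ideal["N"]),
        torsion_angle(ideal["CB"], ideal["CA"], ideal["N"], ideal["C"]),
    )
    avg = 0.5 * (p1 + p2)
    v = avg - ca
    return ca + v * (length / np.linalg.norm(v))


def cbeta_deviation(
    residue_atoms: dict[str, np.ndarray],
    library: ParameterLibrary | None = None,
    res_name: str = "ALA",
) -> float | None:
    """C-beta deviation (A) for one residue given name -> coordinate map.

    Returns None for glycine or when a backbone atom is missing.
    """
    library = library or load_library()
    if res_name == "GLY":
        return None
    for req in ("N", "CA", "C", "CB"):
        if req not in residue_atoms:
            logger.info("cbeta_deviation: %s missing %s", res_name, req)
            return None
    ideal = ideal_cbeta_position(
        np.asarray(residue_atoms["N"], float),
        np.asarray(residue_atoms["CA"], float),
        np.asarray(residue_atoms["C"], float),
        library, res_name,
    )
    return float(np.linalg.norm(np.asarray(residue_atoms["CB"], float) - ideal))


def cbeta_deviations(
    model: AtomicModel, library: ParameterLibrary | None = None
) -> dict[tuple, float]:
    """Per-residue-conformer C-beta deviations: (chain, seq, altloc) -> Cbd."""
    library = library or load_library()
    out: dict[tuple, float] = {}
    for chain, seq, rname, idxs in model.residues():
        if rname == "GLY":
            continue
        amap: dict[tuple[str, str], np.ndarray] = {}
        for i in idxs:
            a = model.atoms[i]
            amap[(a.name, a.altloc)] = a.xyz
        alts = sorted({alt for (_, alt) in amap if alt}) or [""]
        for alt in alts:
            def get(name):
                for key in ((name, alt), (name, "")):
                    if key in amap:
                        return amap[key]
                return None
            res = {n: get(n) for n in ("N", "CA", "C", "CB")}
            if any(v is None for v in res.values()):
                continue
            d = cbeta_deviation(res, library, rname)
            if d is not None:
                out[(chain, seq, alt)] = d
    return out


def clashscore(
    model: AtomicModel, library: ParameterLibrary | None = None
) -> tuple[list[tuple[int, int, float]], float]:
    """Serious steric overlaps per 1000 atoms.

    A clash is a nonbonded pair (1-2/1-3/1-4, altloc cross-copy and plausible
    donor-acceptor pairs excluded) whose van der Waals overlap
    r_i + r_j - d is >= 0.4 A.  Returns (clash list, score).
    """
    library = library or load_library()
    n = len(model)
    if n == 0:
        return [], 0.0
    if not any(a.element == "H" for a in model.atoms):
        logger.warning("clashscore: model has no hydrogens; score is low-confidence")
    bonds = bond_graph(model, library)
    excluded, hb, _ = _exclusion_masks(model, library, bonds)
    res_of = {}
    for chain, seq, rname, idxs in model.residues():
        for i in idxs:
            res_of[i] = rname
    radius = np.array(
        [library.ff.lj[library.template(res_of[i]).lj_types[model.atoms[i].name]][2]
         for i in range(n)]
    )
    xyz = model.coords
    pairs = cKDTree(xyz).query_pairs(2 * radius.max(), output_type="ndarray")
    clashes = []
    if len(pairs):
        i, j = pairs.T
        keep = ~(excluded[i, j] | hb[i, j])
        i, j = i[keep], j[keep]
        d = np.linalg.norm(xyz[i] - xyz[j], axis=1)
        overlap = radius[i] + radius[j] - d
        bad = overlap >= CLASH_OVERLAP
        clashes = [(int(a), int(b), float(o)) for a, b, o in zip(i[bad], j[bad], overlap[bad])]
    score = 1000.0 * len(clashes) / n
    return clashes, score


def hbond_fraction(
    model: AtomicModel, library: ParameterLibrary | None = None
) -> tuple[list[tuple[int, int, int]], float]:
    """Hydrogen bonds per 1000 atoms.

    A bond is a donor-H/acceptor triple with donor-heavy-to-acceptor
    distance <= 3.5 A and donor-H...acceptor angle >= 135 deg; donors are
    N/O with a bonded H, acceptors are O atoms and bare ring nitrogens.
    Without hydrogens the angle criterion is dropped with a logged downgrade.
    Returns (list of (donor, H, acceptor) indices, rate per 1000 atoms).
    """
    library = library or load_library()
    n = len(model)
    if n == 0:
        return [], 0.0
    bonds = bond_graph(model, library)
    nb = [[] for _ in range(n)]
    for i, j in bonds:
        nb[i].append(j)
        nb[j].append(i)
    elem = [a.element for a in model.atoms]
    has_h = any(e == "H" for e in elem)
    if not has_h:
        logger.warning("hbond_fraction: no hydrogens; using distance-only criterion")

    donors = []  # (heavy, H) pairs
    for i in range(n):
        if elem[i] in ("N", "O"):
            hs = [j for j in nb[i] if elem[j] == "H"]
            if has_h:
                donors.extend((i, h) for h in hs)
            elif elem[i] == "N" or len(nb[i]) < 2:
                donors.append((i, None))
    acceptors = [
        i for i in range(n)
        if (elem[i] == "O")
        or (elem[i] == "N" and not any(elem[j] == "H" for j in nb[i]) and len(nb[i]) <= 2)
    ]
    # exclude acceptors within two bonds of the donor
    near = {}
    for d, _ in donors:
        s = {d} | set(nb[d])
        for x in list(s):
            s |= set(nb[x])
        near[d] = s
    xyz = model.coords
    alt = [a.altloc for a in model.atoms]
    out = []
    for d, h in donors:
        for a in acceptors:
            if a in near[d]:
                continue
            if alt[d] and alt[a] and alt[d] != alt[a]:
                continue
            dist = np.linalg.norm(xyz[d] - xyz[a])
            if dist > HBOND_DIST:
                continue
            if h is not None:
                ang = bond_angle(xyz[d], xyz[h], xyz[a])
                if ang < HBOND_ANGLE:
                    continue
            out.append((d, h if h is not None else -1, a))
    return out, 1000.0 * len(out) / n


@dataclass
class ValidationReport:
    cbeta: dict[tuple, float]
    cbeta_outliers: int
    clashes: list
    clashscore: float
    hbonds: list
    hbond_rate: float
    rmsd_bonds: float | None = None
    rmsd_angles: float | None = None
    r_work: float | None = None
    r_free: float | None = None

    def as_dict(self):
        return {
            "cbeta": {f"{c}:{s}:{a}": v for (c, s, a), v in self.cbeta.items()},
            "cbeta_outliers": self.cbeta_outliers,
            "n_clashes": len(self.clashes),
            "clashscore": self.clashscore,
            "n_hbonds": len(self.hbonds),
            "hbonds_per_1000_atoms": self.hbond_rate,
            "rmsd_bonds": self.rmsd_bonds,
            "rmsd_angles": self.rmsd_angles,
            "r_work": self.r_work,
            "r_free": self.r_free,
        }


def validation_report(
    model: AtomicModel,
    library: ParameterLibrary | None = None,
    restraints: RestraintSet | None = None,
    crystal: Crystal | None = None,
    reflections: ReflectionSet | None = None,
) -> ValidationReport:
    """Aggregate the three metrics plus geometry r.m.s.d. and R factors."""
    library = library or load_library()
    cb = cbeta_deviations(model, library)
    clashes, cs = clashscore(model, library)
    hbonds, rate = hbond_fraction(model, library)
    rb = ra = None
    if restraints is not None:
        rb, ra = geometry_rmsd(model, restraints)
    rw = rf = None
    if crystal is not None and reflections is not None:
        from .xray import calc_fcalc, r_factors
        fc = calc_fcalc(model, crystal, reflections.hkl)
        rw, rf = r_factors(reflections, fc)
    return ValidationReport(
        cbeta=cb,
        cbeta_outliers=sum(1 for v in cb.values() if v >= CBETA_OUTLIER_THRESHOLD),
        clashes=clashes,
        clashscore=cs,
        hbonds=hbonds,
        hbond_rate=rate,
        rmsd_bonds=rb,
        rmsd_angles=ra,
        r_work=rw,
        r_free=rf,
    )
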