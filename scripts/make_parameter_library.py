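#!/usr/bin/env python
"""Regenerate the shipped parameter library (src/refmm/data/params.txt).

Residue topology and ideal geometry are measured from the Chemical Component
Dictionary ideal coordinates bundled with biotite; charges, Lennard-Jones
parameters and force constants are the package's own reduced scheme (see
docs/methods.md).  The output is a plain-text library in the dialect
documented in docs/parameter_dialect.md.  Run from the repository root:

    python scripts/make_parameter_library.py
"""

from __future__ import annotations

import sys
from collections import defaultdict
from pathlib import Path

import networkx as nx
import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from refmm.nerf import bond_angle, bond_length, torsion_angle  # noqa: E402

import biotite.structure.info as ccd_info  # noqa: E402

AMINO = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

# Atoms absent from the mid-chain polymeric form.  Side-chain protonation:
# Asp/Glu anionic, Lys/Arg cationic, His neutral (delta tautomer).
STRIP = {"OXT", "HXT", "H2"}
STRIP_EXTRA = {
    "ASP": {"HD2"},
    "GLU": {"HE2"},
    "HIS": {"HE2"},
    "PRO": {"H"},
}
FORMAL = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

# Bond-polarity charge increments (e) moved onto the more electronegative
# partner; "double" entries apply to bond order >= 2.
ELECTRONEG = {"H": 2.20, "C": 2.55, "S": 2.58, "N": 3.04, "O": 3.44}
INCREMENT = {
    ("C", "H"): 0.06,
    ("H", "N"): 0.33,
    ("H", "O"): 0.40,
    ("H", "S"): 0.12,
    ("C", "N"): 0.25,
    ("C", "O"): 0.30,
    ("C", "O", "double"): 0.48,
    ("C", "S"): 0.08,
    ("C", "C"): 0.00,
    ("N", "N"): 0.00,
    ("C", "C", "double"): 0.00,
    ("N", "N", "double"): 0.00,
    ("C", "N", "double"): 0.25,
}
# Extra charge spread over the formally charged group.
FORMAL_SPREAD = {
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
    "LYS": {"NZ": 0.4, "HZ1": 0.2, "HZ2": 0.2, "HZ3": 0.2},
    "ARG": {
        "NE": 0.1, "CZ": 0.2, "NH1": 0.2, "NH2": 0.2,
        "HH11": 0.075, "HH12": 0.075, "HH21": 0.075, "HH22": 0.075,
    },
}

# Lennard-Jones types: rmin/2 (A), epsilon (kcal/mol) and a van der Waals
# contact radius used by the validation metrics and the repulsion restraints.
LJ = {
    "CT": (1.9080, 0.1094, 1.70),
    "C":  (1.9080, 0.0860, 1.65),
    "CA": (1.9080, 0.0860, 1.75),
    "N":  (1.8240, 0.1700, 1.55),
    "O":  (1.6612, 0.2100, 1.52),
    "OH": (1.7210, 0.2104, 1.52),
    "S":  (2.0000, 0.2500, 1.80),
    "HC": (1.4870, 0.0157, 1.17),
    "H":  (0.6000, 0.0157, 1.00),
}

TORSIONS = [
    ("X", "CT", "CT", "X", 0.1556, 3, 0.0),
    ("X", "C", "N", "X", 10.0, 2, 180.0),
    ("X", "CA", "CA", "X", 3.625, 2, 180.0),
    ("X", "CA", "N", "X", 4.80, 2, 180.0),
    ("X", "CT", "OH", "X", 0.16, 3, 0.0),
    ("X", "CT", "S", "X", 0.333, 3, 0.0),
    ("X", "C", "OH", "X", 1.80, 2, 180.0),
]

ROOT = ("N", "CA", "C")


def residue_data(name: str):
    res = ccd_info.residue(name)
    strip = STRIP | STRIP_EXTRA.get(name, set())
    keep = [i for i, an in enumerate(res.atom_name) if an not in strip]
    names = [str(res.atom_name[i]) for i in keep]
    elems = [str(res.element[i]).capitalize() for i in keep]
    coords = {names[j]: np.array(res.coord[i], float) for j, i in enumerate(keep)}
    idx = {res.atom_name[i]: i for i in keep}
    bonds = []
    for i, j, order in res.bonds.as_array():
        ni, nj = str(res.atom_name[i]), str(res.atom_name[j])
        if ni in strip or nj in strip:
            continue
        dbl = int(order) in (2, 6)
        bonds.append((ni, nj, dbl))
    return names, elems, coords, bonds


def neighbor_map(names, bonds):
    nb = {n: [] for n in names}
    for a, b, _ in bonds:
        nb[a].append(b)
        nb[b].append(a)
    return nb


def assign_types(name, names, elems, bonds):
    """LJ-type assignment from element and bonded environment."""
    nb = neighbor_map(names, bonds)
    elem = dict(zip(names, elems))
    g = nx.Graph([(a, b) for a, b, _ in bonds if elem[a] != "H" and elem[b] != "H"])
    aromatic = set()
    for cycle in nx.cycle_basis(g):
        if all(len(nb[a]) <= 3 for a in cycle):
            aromatic.update(cycle)
    types = {}
    for an in names:
        e = elem[an]
        if e == "H":
            types[an] = "HC" if elem[nb[an][0]] == "C" else "H"
        elif e == "C":
            if an in aromatic:
                types[an] = "CA"
            elif len(nb[an]) == 3:
                types[an] = "C"
            else:
                types[an] = "CT"
        elif e == "N":
            types[an] = "N"
        elif e == "O":
            has_h = any(elem[x] == "H" for x in nb[an])
            types[an] = "OH" if has_h else "O"
        elif e == "S":
            types[an] = "S"
        else:
            raise ValueError(f"unsupported element {e} in {name}")
    # Backbone carbonyl C is type C even when the CCD form leaves it with
    # only two in-residue bonds (the third partner is the next residue's N).
    if "C" in types:
        types["C"] = "C"
    if "CA" in types and elem.get("CA") == "C":
        types["CA"] = "CT"
    return types


def assign_charges(name, names, elems, bonds):
    elem = dict(zip(names, elems))
    q = defaultdict(float)
    for a, b, dbl in bonds:
        ea, eb = elem[a], elem[b]
        key = tuple(sorted((ea, eb)))
        inc = INCREMENT.get(key + ("double",) if dbl else key)
        if inc is None:
            inc = INCREMENT[key]
        lo, hi = (a, b) if ELECTRONEG[ea] < ELECTRONEG[eb] else (b, a)
        q[lo] += inc
        q[hi] -= inc
    for an, extra in FORMAL_SPREAD.get(name, {}).items():
        if an in q or an in names:
            q[an] += extra
    total = sum(q[an] for an in names)
    assert abs(total - FORMAL.get(name, 0)) < 1e-9, (name, total)
    return {an: q[an] for an in names}


def placement_order(names, elems, bonds, coords):
    """Choose a deterministic placement order and reference triples."""
    nb = neighbor_map(names, bonds)
    placed = [r for r in ROOT if r in names]
    order = []  # (atom, r1, r2, r3)

    elem = {n: e for n, e in zip(names, elems)}

    def pick_refs(x, r1):
        # heavy reference atoms preferred: hydrogens may be re-placed by
        # chain rules (amide H), which would invalidate torsions through them
        cands = [n for n in nb[r1] if n in placed and n != x]
        cands.sort(key=lambda n: (elem[n] == "H", placed.index(n)))
        for r2 in cands:
            bonded = {n for n in nb[r2] if n in placed and n not in (x, r1)}
            pool = sorted(
                (p for p in placed if p not in (x, r1, r2)),
                key=lambda n: (elem[n] == "H", n not in bonded, placed.index(n)),
            )
            for r3 in pool:
                u = coords[r1] - coords[r2]
                v = coords[r3] - coords[r2]
                sin = np.linalg.norm(np.cross(u, v)) / (
                    np.linalg.norm(u) * np.linalg.norm(v)
                )
                if sin > 0.05:
                    return r2, r3
        return None

    # Place O immediately after the backbone root so that it can serve as a
    # reference for everything else.
    pending = [n for n in names if n not in placed]
    if "O" in pending:
        pending.remove("O")
        pending.insert(0, "O")
    while pending:
        progressed = False
        for x in list(pending):
            parents = [n for n in nb[x] if n in placed]
            if not parents:
                continue
            r1 = min(parents, key=lambda n: placed.index(n))
            refs = pick_refs(x, r1)
            if refs is None:
                continue
            r2, r3 = refs
            order.append((x, r1, r2, r3))
            placed.append(x)
            pending.remove(x)
            progressed = True
        if not progressed:
            raise RuntimeError(f"cannot place atoms {pending}")
    return order


def plane_groups(names, elems, bonds, coords):
    """sp2 groups (center + 3 neighbors), merged when they share >= 2 atoms."""
    nb = neighbor_map(names, bonds)
    elem = dict(zip(names, elems))
    groups = []
    for an in names:
        if elem[an] not in ("C", "N") or len(nb[an]) != 3 or an in ("CA", "C", "N"):
            continue
        grp = [an] + nb[an]
        pts = np.array([coords[a] for a in grp])
        centered = pts - pts.mean(axis=0)
        dev = np.linalg.svd(centered, compute_uv=False)[-1] / np.sqrt(len(grp))
        if dev < 0.05:
            groups.append(set(grp))
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if len(groups[i] & groups[j]) >= 2:
                    groups[i] |= groups.pop(j)
                    merged = True
                    break
            if merged:
                break
    out = []
    for grp in groups:
        pts = np.array([coords[a] for a in grp])
        centered = pts - pts.mean(axis=0)
        dev = np.linalg.svd(centered, compute_uv=False)[-1] / np.sqrt(len(grp))
        if dev < 0.05:
            out.append(sorted(grp, key=names.index))
    return out


def chirality_records(name, names, coords):
    recs = []

    def vol(center, n1, n2, n3):
        c = coords[center]
        v = np.dot(
            np.cross(coords[n1] - c, coords[n2] - c), coords[n3] - c
        )
        return float(v)

    if name != "GLY":
        recs.append(("CA", "N", "C", "CB", vol("CA", "N", "C", "CB")))
    if name == "THR":
        recs.append(("CB", "CA", "OG1", "CG2", vol("CB", "CA", "OG1", "CG2")))
    if name == "ILE":
        recs.append(("CB", "CA", "CG1", "CG2", vol("CB", "CA", "CG1", "CG2")))
    return recs


def main():
    out = []
    out.append("# refmm parameter library")
    out.append("# Topology and ideal internal coordinates measured from CCD ideal")
    out.append("# coordinates (via biotite); charges, LJ parameters and force")
    out.append("# constants are the package's reduced self-consistent scheme.")
    out.append("# Regenerate with scripts/make_parameter_library.py.")
    out.append("")

    bond_obs = defaultdict(list)
    angle_obs = defaultdict(list)

    residue_blocks = []
    for name in AMINO:
        names, elems, coords, bonds = residue_data(name)
        types = assign_types(name, names, elems, bonds)
        charges = assign_charges(name, names, elems, bonds)
        order = placement_order(names, elems, bonds, coords)
        nb = neighbor_map(names, bonds)

        for a, b, _ in bonds:
            key = tuple(sorted((types[a], types[b])))
            bond_obs[key].append(bond_length(coords[a], coords[b]))
        for b in names:
            for i, a in enumerate(nb[b]):
                for c in nb[b][i + 1:]:
                    key = (types[b], tuple(sorted((types[a], types[c]))))
                    angle_obs[key].append(bond_angle(coords[a], coords[b], coords[c]))

        blk = [f"[residue {name}]"]
        blk.append(f"formal_charge {FORMAL.get(name, 0)}")
        blk.append(
            "root {:.4f} {:.4f} {:.3f}".format(
                bond_length(coords["N"], coords["CA"]),
                bond_length(coords["CA"], coords["C"]),
                bond_angle(coords["N"], coords["CA"], coords["C"]),
            )
        )
        for an in names:
            blk.append(
                f"atom {an} {dict(zip(names, elems))[an]} "
                f"{charges[an]:+.4f} {types[an]}"
            )
        for a, b, _ in bonds:
            blk.append(f"bond {a} {b}")
        for x, r1, r2, r3 in order:
            length = bond_length(coords[x], coords[r1])
            ang = bond_angle(coords[x], coords[r1], coords[r2])
            tor = torsion_angle(coords[x], coords[r1], coords[r2], coords[r3])
            if x == "H" and (r1, r2) == ("N", "CA"):
                # polymeric amide H: planar N (CCD monomers carry a free
                # amine); H-N-CA closes 360 deg with the two link angles
                ang = 360.0 - 121.7 - 119.2
                tor = 180.0
            blk.append(
                "ic {} {} {} {} {:.4f} {:.3f} {:.3f}".format(x, r1, r2, r3, length, ang, tor)
            )
        for center, n1, n2, n3, v in chirality_records(name, names, coords):
            blk.append(f"chiral {center} {n1} {n2} {n3} {v:+.4f}")
        for grp in plane_groups(names, elems, bonds, coords):
            blk.append("plane " + " ".join(grp))
        blk.append("")
        residue_blocks.append("\n".join(blk))

    # Water (rigid template; used for completeness of the library).
    res = ccd_info.residue("HOH")
    wnames = [str(a) for a in res.atom_name]
    blk = ["[residue HOH]", "formal_charge 0"]
    blk.append("atom O O -0.8000 OH")
    blk.append("atom H1 H +0.4000 H")
    blk.append("atom H2 H +0.4000 H")
    blk.append("bond O H1")
    blk.append("bond O H2")
    blk.append("")
    residue_blocks.append("\n".join(blk))

    # Peptide-link ideal values (standard single-conformation values).
    link = [
        "[link peptide]",
        "bond C N 1.329",
        "angle CA C N 116.2",
        "angle O C N 123.0",
        "angle C N CA 121.7",
        "angle C N H 119.2",
        "angle C N CD 124.2",
        "torsion CA C N CA 180.0 5.0 1",
        "plane CA C O +N +H +CA",
        "",
    ]
    # Register link bond/angle ideals in the type averages as well.
    bond_obs[("C", "N")].append(1.329)
    angle_obs[("C", ("CT", "N"))].append(116.2)
    angle_obs[("C", ("N", "O"))].append(123.0)
    angle_obs[("N", ("C", "CT"))].append(121.7)
    angle_obs[("N", ("C", "H"))].append(119.2)
    # amide N is planar in the polymer: override the free-amine CCD values
    angle_obs[("N", ("CT", "H"))] = [360.0 - 121.7 - 119.2]

    ff = ["[ff]"]
    ff.append("scale14 0.833333 0.500000")
    ff.append("improper 10.5 2 180.0")
    for t, (rmin2, eps, vdw) in LJ.items():
        ff.append(f"ljtype {t} {rmin2:.4f} {eps:.4f} {vdw:.2f}")
    for (t1, t2), vals in sorted(bond_obs.items()):
        kb = 350.0 if "H" in (t1[:1], t2[:1]) and ("H" in (t1, t2) or "HC" in (t1, t2)) else 300.0
        kb = 350.0 if {"H", "HC"} & {t1, t2} else 300.0
        ff.append(f"bondtype {t1} {t2} {kb:.1f} {np.mean(vals):.4f}")
    for (tc, (t1, t2)), vals in sorted(angle_obs.items()):
        kt = 50.0 if {"H", "HC"} & {t1, t2} else 63.0
        ff.append(f"angletype {t1} {tc} {t2} {kt:.1f} {np.mean(vals):.3f}")
    for t1, t2, t3, t4, v, n, g in TORSIONS:
        ff.append(f"torsiontype {t1} {t2} {t3} {t4} {v:.4f} {n} {g:.1f}")
    ff.append("")

    geo = [
        "[geo]",
        "sigma_bond 0.02",
        "sigma_angle 2.0",
        "sigma_torsion 5.0",
        "sigma_chirality 0.2",
        "sigma_plane 0.02",
        "sigma_repulsion 0.2",
        "repulsion_screen 4.5",
        "repulsion_tolerance 0.4",
        "ec_bond C H 0.95",
        "ec_bond N H 0.86",
        "ec_bond O H 0.84",
        "ec_bond S H 1.20",
        "",
    ]

    text = "\n".join(out + ff + geo + link) + "\n" + "\n".join(residue_blocks)
    dest = Path(__file__).resolve().parents[1] / "src" / "refmm" / "data" / "params.txt"
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_text(text)
    print(f"wrote {dest} ({dest.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
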