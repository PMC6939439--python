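"""Model preparation: hydrogen/heavy-atom completion and compilation of the
two restraint representations (ideal-geometry records and force-field
topology) from the shared parameter library.

Both representations are derived from the same covalent bond graph, so the
ideal-geometry target and the force-field target see identical connectivity.
Models are kept in their mid-chain polymeric form: termini carry no OXT or
extra amine hydrogens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import Atom, AtomicModel
from .nerf import place_atom
from .params import ParameterLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "add_hydrogens",
    "build_restraints",
    "build_mm_topology",
    "RestraintSet",
    "MMTopology",
    "bond_graph",
]

# Inter-residue angle ideals live in the [link peptide] block; this maps the
# atom-name triple spanning the link to the block's record.
_LINK_ANGLE_NAMES = [
    ("CA", "C", "N"),
    ("O", "C", "N"),
    ("C", "N", "CA"),
    ("C", "N", "H"),
    ("C", "N", "CD"),
]


# ---------------------------------------------------------------------------
# covalent bond graph

def _residue_entries(model: AtomicModel):
    """Residues with (chain, seq, name, {(atom name, altloc): index})."""
    out = []
    for chain, seq, rname, idxs in model.residues():
        amap = {}
        for i in idxs:
            a = model.atoms[i]
            amap[(a.name, a.altloc)] = i
        out.append((chain, seq, rname, amap))
    return out


def _instances(amap, name):
    """All (index, altloc) instances of an atom name within a residue."""
    return [(i, alt) for (n, alt), i in amap.items() if n == name]


def _compatible(alt1: str, alt2: str) -> bool:
    return alt1 == alt2 or alt1 == "" or alt2 == ""


def bond_graph(model: AtomicModel, library: ParameterLibrary) -> list[tuple[int, int]]:
    """Covalent bonds as atom-index pairs: template bonds per residue (with
    altloc-compatible matching) plus C(i)-N(i+1) peptide links."""
    bonds: set[tuple[int, int]] = set()
    residues = _residue_entries(model)
    for chain, seq, rname, amap in residues:
        tpl = library.template(rname)
        for a, b in tpl.bonds:
            for ia, alta in _instances(amap, a):
                for ib, altb in _instances(amap, b):
                    if _compatible(alta, altb):
                        bonds.add((min(ia, ib), max(ia, ib)))
    by_key = {(chain, seq): amap for chain, seq, _, amap in residues}
    for chain, seq, rname, amap in residues:
        nxt = by_key.get((chain, seq + 1))
        if nxt is None:
            continue
        for ic_, altc in _instances(amap, "C"):
            for in_, altn in _instances(nxt, "N"):
                if _compatible(altc, altn):
                    bonds.add((min(ic_, in_), max(ic_, in_)))
    return sorted(bonds)


# ---------------------------------------------------------------------------
# completion (hydrogens and missing heavy atoms)

def add_hydrogens(model: AtomicModel, library: ParameterLibrary) -> AtomicModel:
    """Complete every residue to its full template atom set.

    Missing atoms (hydrogens and heavy atoms alike) are placed from the
    template internal coordinates using already-present reference atoms;
    the backbone amide hydrogen is placed in the peptide plane, trans to
    the preceding carbonyl oxygen.  Added atoms inherit occupancy, B factor
    and altloc from the reference heavy atom they attach to.
    """
    residues = _residue_entries(model)
    by_key = {(chain, seq): amap for chain, seq, _, amap in residues}
    new_atoms: list[Atom] = []
    for chain, seq, rname, amap in residues:
        try:
            tpl = library.template(rname)
        except KeyError:
            raise ValueError(f"no template for residue {rname} {chain}{seq}") from None
        for (name, alt) in amap:
            if name in tpl.atoms and alt and (name, "") in amap:
                raise ValueError(
                    f"atom {name} in {rname} {chain}{seq} present both with and "
                    f"without altloc label"
                )
        conformers = sorted({alt for (_, alt) in amap if alt}) or [""]
        coords = {k: model.atoms[i].xyz for k, i in amap.items()}
        placed_new: dict[tuple[str, str], Atom] = {}

        def lookup(name, alt):
            for key in ((name, alt), (name, "")):
                if key in coords:
                    return coords[key], key
                if key in placed_new:
                    return placed_new[key].xyz, key
            return None, None

        ic_by_atom = {rec.atom: rec for rec in tpl.ics}
        for alt in conformers:
            missing = [
                an for an in tpl.atoms
                if lookup(an, alt)[0] is None
            ]
            progress = True
            while missing and progress:
                progress = False
                for an in list(missing):
                    atom = self_place = None
                    rec = ic_by_atom.get(an)
                    if rec is None:
                        continue  # backbone root atoms cannot be rebuilt
                    if an == "H":
                        atom = _place_amide_h(
                            model, library, tpl, by_key, chain, seq, lookup, rec
                        )
                    if atom is None:
                        p1, k1 = lookup(rec.r1, alt)
                        p2, _ = lookup(rec.r2, alt)
                        p3, _ = lookup(rec.r3, alt)
                        if p1 is None or p2 is None or p3 is None:
                            continue
                        atom = place_atom(
                            p1, p2, p3, library.ic_length(tpl, rec), rec.angle, rec.torsion
                        )
                        self_place = k1
                    else:
                        _, self_place = lookup(rec.r1, alt)
                    parent_key = self_place
                    parent = (
                        model.atoms[amap[parent_key]]
                        if parent_key in amap
                        else placed_new[parent_key]
                    )
                    new_alt = parent.altloc
                    placed_new[(an, new_alt)] = Atom(
                        name=an, element=tpl.elements[an], chain=chain,
                        res_name=rname, res_seq=seq, altloc=new_alt,
                        occupancy=parent.occupancy, b_iso=parent.b_iso, xyz=atom,
                    )
                    missing.remove(an)
                    progress = True
            if missing:
                raise ValueError(
                    f"cannot place atoms {missing} in {rname} {chain}{seq}: "
                    f"reference atoms absent"
                )
        new_atoms.append((chain, seq, placed_new))

    # Reassemble: original atoms in order, completions appended per residue.
    out: list[Atom] = []
    added = {(c, s): list(p.values()) for c, s, p in new_atoms}
    for chain, seq, rname, idxs in model.residues():
        for i in idxs:
            out.append(model.atoms[i])
        out.extend(added.get((chain, seq), []))
    return AtomicModel(out)


def _place_amide_h(model, library, tpl, by_key, chain, seq, lookup, rec):
    """Backbone amide H: in the peptide plane, trans to the carbonyl O of the
    preceding residue.  Returns None (template fallback) at the N-terminus."""
    prev = by_key.get((chain, seq - 1))
    if prev is None:
        return None
    pn, _ = lookup("N", "")
    if pn is None:
        return None
    c_prev = prev.get(("C", ""))
    o_prev = prev.get(("O", ""))
    if c_prev is None or o_prev is None:
        return None
    n_h = library.ic_length(tpl, rec)
    angle = _link_angle(library, ("C", "N", "H"))
    return place_atom(
        pn, model.atoms[c_prev].xyz, model.atoms[o_prev].xyz, n_h, angle, 180.0
    )


def _link_angle(library, names):
    for a, b, c, val in library.link.angles:
        if (a, b, c) == names:
            return val
    raise KeyError(f"no peptide-link angle for {names}")


# ---------------------------------------------------------------------------
# restraint compilation

@dataclass
class RestraintSet:
    """Ideal-value + sigma restraint records on atom indices."""

    n_atoms: int = 0
    bonds: np.ndarray = None          # (m,2) int
    bond_ideal: np.ndarray = None     # (m,) A
    bond_sigma: np.ndarray = None
    angles: np.ndarray = None         # (m,3)
    angle_ideal: np.ndarray = None    # degrees
    angle_sigma: np.ndarray = None
    torsions: np.ndarray = None       # (m,4)
    torsion_ideal: np.ndarray = None  # degrees
    torsion_sigma: np.ndarray = None
    torsion_period: np.ndarray = None
    chirals: np.ndarray = None        # (m,4) center + 3 neighbors
    chiral_ideal: np.ndarray = None   # signed volume A^3
    chiral_sigma: np.ndarray = None
    planes: list[np.ndarray] = field(default_factory=list)
    plane_sigma: float = 0.02
    vdw_radius: np.ndarray = None     # per atom, A
    excluded: np.ndarray = None       # (n,n) bool: 1-2/1-3/1-4, altloc cross-copy
    hb_exempt: np.ndarray = None      # (n,n) bool: donor-H vs acceptor pairs
    repulsion_screen: float = 4.5
    repulsion_sigma: float = 0.2
    repulsion_tolerance: float = 0.2


def _neighbor_lists(n, bonds):
    nb = [[] for _ in range(n)]
    for i, j in bonds:
        nb[i].append(j)
        nb[j].append(i)
    return nb


def _exclusion_masks(model, library, bonds):
    """1-2/1-3/1-4 and altloc cross-copy exclusions, plus donor-acceptor
    exemption flags shared by repulsion restraints and the clashscore."""
    n = len(model)
    nb = _neighbor_lists(n, bonds)
    excluded = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(excluded, True)
    one_four = set()
    for i, j in bonds:
        excluded[i, j] = excluded[j, i] = True
    for j in range(n):
        for i in nb[j]:
            for k in nb[j]:
                if i < k:
                    excluded[i, k] = excluded[k, i] = True
    for j, k in bonds:
        for i in nb[j]:
            for l_ in nb[k]:
                if i != k and l_ != j and i != l_ and not excluded[i, l_]:
                    one_four.add((min(i, l_), max(i, l_)))
    for i, j in one_four:
        excluded[i, j] = excluded[j, i] = True
    # different copies of the same altloc group never interact
    alt = np.array([a.altloc for a in model.atoms])
    chain = np.array([a.chain for a in model.atoms])
    labelled = alt != ""
    for i in np.flatnonzero(labelled):
        for j in np.flatnonzero(labelled):
            if chain[i] == chain[j] and alt[i] != alt[j]:
                excluded[i, j] = True

    elem = np.array([a.element for a in model.atoms])
    polar_h = np.zeros(n, dtype=bool)
    for i, j in bonds:
        if elem[i] == "H" and elem[j] in ("N", "O", "S"):
            polar_h[i] = True
        if elem[j] == "H" and elem[i] in ("N", "O", "S"):
            polar_h[j] = True
    acceptor = np.isin(elem, ("N", "O", "S"))
    hb = (polar_h[:, None] & acceptor[None, :]) | (acceptor[:, None] & polar_h[None, :])
    return excluded, hb, one_four


def build_restraints(model: AtomicModel, library: ParameterLibrary) -> RestraintSet:
    """Compile ideal-geometry restraints for a complete model.

    Ideal values come from the residue templates (rebuilt ideal geometry)
    and from the peptide-link block; sigmas are the library-wide values.
    Repulsion uses per-atom contact radii with 1-2/1-3/1-4 and altloc
    cross-copy exclusions and a donor-acceptor exemption; the pair list
    itself is rebuilt at evaluation time within the configured screen.
    """
    geo = library.geo
    bonds = bond_graph(model, library)
    residues = _residue_entries(model)
    res_of = {}
    for chain, seq, rname, amap in residues:
        for key, i in amap.items():
            res_of[i] = (chain, seq, rname)
    atoms = model.atoms
    n = len(atoms)

    b_idx, b_ideal = _bond_ideals(library, atoms, bonds, res_of)
    nb = _neighbor_lists(n, bonds)
    a_idx, a_ideal = _angle_ideals(library, atoms, nb, res_of)

    # omega torsion restraints across each peptide link
    t_idx, t_ideal, t_sigma, t_period = [], [], [], []
    by_key = {(chain, seq): amap for chain, seq, _, amap in residues}
    om_ideal, om_sigma, om_period = library.link.omega
    for chain, seq, rname, amap in residues:
        nxt = by_key.get((chain, seq + 1))
        if nxt is None:
            continue
        for ica, alt1 in _instances(amap, "CA"):
            for ic_, alt2 in _instances(amap, "C"):
                for in_, alt3 in _instances(nxt, "N"):
                    for ica2, alt4 in _instances(nxt, "CA"):
                        alts = {a for a in (alt1, alt2, alt3, alt4) if a}
                        if len(alts) > 1:
                            continue
                        t_idx.append((ica, ic_, in_, ica2))
                        t_ideal.append(om_ideal)
                        t_sigma.append(om_sigma)
                        t_period.append(om_period)

    c_idx, c_ideal = [], []
    planes: list[np.ndarray] = []
    for chain, seq, rname, amap in residues:
        tpl = library.template(rname)
        conformers = sorted({alt for (_, alt) in amap if alt}) or [""]
        ideal = library.ideal_coords(rname) if tpl.root else None
        for alt in conformers:
            def gi(name):
                for key in ((name, alt), (name, "")):
                    if key in amap:
                        return amap[key]
                return None
            for center, n1, n2, n3, vol in tpl.chirals:
                idxs = [gi(center), gi(n1), gi(n2), gi(n3)]
                if None in idxs:
                    continue
                c_idx.append(tuple(idxs))
                # ideal volume from the rebuilt template geometry (the file
                # value documents magnitude and handedness at low precision)
                ic = ideal or library.ideal_coords(rname)
                v = np.dot(
                    np.cross(ic[n1] - ic[center], ic[n2] - ic[center]),
                    ic[n3] - ic[center],
                )
                c_ideal.append(float(v))
            for grp in tpl.planes:
                idxs = [gi(g) for g in grp]
                idxs = [i for i in idxs if i is not None]
                if len(idxs) >= 4:
                    planes.append(np.array(sorted(set(idxs)), dtype=int))
        nxt = by_key.get((chain, seq + 1))
        if nxt is not None and library.link.plane:
            for alt in conformers:
                idxs = []
                for name in library.link.plane:
                    here = not name.startswith("+")
                    nm = name.lstrip("+")
                    amap_x = amap if here else nxt
                    got = None
                    for key in ((nm, alt), (nm, "")):
                        if key in amap_x:
                            got = amap_x[key]
                            break
                    if got is None and nm == "H":  # proline: CD replaces H
                        for key in (("CD", alt), ("CD", "")):
                            if key in amap_x:
                                got = amap_x[key]
                                break
                    if got is not None:
                        idxs.append(got)
                if len(idxs) >= 4:
                    planes.append(np.array(sorted(set(idxs)), dtype=int))

    # deduplicate plane groups from altloc conformers sharing all atoms
    uniq_planes = []
    seen = set()
    for p in planes:
        key = tuple(p.tolist())
        if key not in seen:
            seen.add(key)
            uniq_planes.append(p)

    excluded, hb, _ = _exclusion_masks(model, library, bonds)
    vdw = np.array(
        [library.ff.lj[_lj_type_of(library, res_of[i][2], atoms[i].name)][2] for i in range(n)]
    )

    rs = RestraintSet(
        n_atoms=n,
        bonds=np.array(b_idx, int).reshape(-1, 2),
        bond_ideal=np.array(b_ideal, float),
        bond_sigma=np.full(len(b_idx), geo.sigma_bond),
        angles=np.array(a_idx, int).reshape(-1, 3),
        angle_ideal=np.array(a_ideal, float),
        angle_sigma=np.full(len(a_idx), geo.sigma_angle),
        torsions=np.array(t_idx, int).reshape(-1, 4),
        torsion_ideal=np.array(t_ideal, float),
        torsion_sigma=np.array(t_sigma, float),
        torsion_period=np.array(t_period, int),
        chirals=np.array(c_idx, int).reshape(-1, 4),
        chiral_ideal=np.array(c_ideal, float),
        chiral_sigma=np.full(len(c_idx), geo.sigma_chirality),
        planes=uniq_planes,
        plane_sigma=geo.sigma_plane,
        vdw_radius=vdw,
        excluded=excluded,
        hb_exempt=hb,
        repulsion_screen=geo.repulsion_screen,
        repulsion_sigma=geo.sigma_repulsion,
        repulsion_tolerance=geo.repulsion_tolerance,
    )
    return rs


def _bond_ideals(library, atoms, bonds, res_of):
    """Per-instance ideal bond lengths: template geometry within a residue,
    the link value across the peptide bond."""
    b_idx, b_ideal = [], []
    for i, j in bonds:
        ci, si, ri = res_of[i]
        cj, sj, rj = res_of[j]
        if (ci, si) == (cj, sj):
            ideal = library.ideal_bond(ri, atoms[i].name, atoms[j].name)
        else:
            ideal = library.link.bond[2]
        b_idx.append((i, j))
        b_ideal.append(ideal)
    return b_idx, b_ideal


def _angle_ideals(library, atoms, nb, res_of):
    a_idx, a_ideal = [], []
    for j in range(len(nb)):
        for x, i in enumerate(nb[j]):
            for k in nb[j][x + 1:]:
                ci, si, ri = res_of[i]
                cj, sj, rj = res_of[j]
                ck, sk, rk = res_of[k]
                if (ci, si) == (cj, sj) == (ck, sk):
                    ideal = library.ideal_angle(rj, atoms[i].name, atoms[j].name, atoms[k].name)
                else:
                    ideal = _link_angle_lookup(library, atoms, i, j, k, res_of)
                a_idx.append((i, j, k))
                a_ideal.append(ideal)
    return a_idx, a_ideal


def _lj_type_of(library, rname, atom_name):
    tpl = library.template(rname)
    if atom_name not in tpl.lj_types:
        raise KeyError(f"atom {atom_name} not in template {rname}")
    return tpl.lj_types[atom_name]


def _link_angle_lookup(library, atoms, i, j, k, res_of):
    ni, nj, nk = atoms[i].name, atoms[j].name, atoms[k].name
    if {ni, nk} == {"O", "N"} and nj == "C":
        # planar carbonyl: O-C-N closes 360 deg with CA-C-N and the
        # residue's own CA-C-O ideal, so built-at-ideal models are exact
        rname = res_of[j][2]
        return 360.0 - _link_angle(library, ("CA", "C", "N")) - library.ideal_angle(
            rname, "CA", "C", "O"
        )
    for a, b, c in _LINK_ANGLE_NAMES:
        if (ni, nj, nk) == (a, b, c) or (nk, nj, ni) == (a, b, c):
            return _link_angle(library, (a, b, c))
    raise KeyError(f"no link angle ideal for {ni}-{nj}-{nk}")


# ---------------------------------------------------------------------------
# force-field topology

@dataclass
class MMTopology:
    """Reduced Amber-style force-field terms on atom indices."""

    n_atoms: int = 0
    charges: np.ndarray = None
    lj_rmin2: np.ndarray = None
    lj_eps: np.ndarray = None
    bonds: np.ndarray = None           # (m,2)
    bond_kb: np.ndarray = None         # kcal/mol/A^2
    bond_b0: np.ndarray = None         # A
    angles: np.ndarray = None          # (m,3)
    angle_k: np.ndarray = None         # kcal/mol/rad^2
    angle_t0: np.ndarray = None        # rad
    torsions: np.ndarray = None        # (m,4) proper + improper
    torsion_v2: np.ndarray = None      # V/2 kcal/mol
    torsion_n: np.ndarray = None
    torsion_gamma: np.ndarray = None   # rad
    excluded: np.ndarray = None        # (n,n) bool (1-2 and 1-3)
    pairs14: np.ndarray = None         # (m,2)
    scale14_elec: float = 1.0 / 1.2
    scale14_lj: float = 0.5
    les_groups: list[dict] = field(default_factory=list)
    copy_weight: np.ndarray = None     # per-atom LES weight (1 for common atoms)
    copy_id: np.ndarray = None         # per-atom (group, copy) id, -1 for common
    cutoff: float = 12.0
    switch_start: float = 10.0

    @property
    def has_les(self) -> bool:
        return any(len(g["copies"]) > 0 for g in self.les_groups)


def build_mm_topology(model: AtomicModel, library: ParameterLibrary) -> MMTopology:
    """Compile the force-field representation of a complete model.

    Bonded terms are typed through the reduced parameter set; 1-2 and 1-3
    pairs are excluded from nonbonded sums and 1-4 pairs are scaled.
    Alternate-conformer atoms become LES groups (one group per chain, one
    copy per altloc label) with occupancy-derived copy weights.
    """
    atoms = model.atoms
    n = len(atoms)
    residues = _residue_entries(model)
    res_of = {}
    for chain, seq, rname, amap in residues:
        for key, i in amap.items():
            res_of[i] = rname
    types = []
    charges = []
    for i, a in enumerate(atoms):
        tpl = library.template(res_of[i])
        if a.name not in tpl.lj_types:
            raise KeyError(f"unparameterized atom {a.name} in {a.res_name} {a.chain}{a.res_seq}")
        types.append(tpl.lj_types[a.name])
        charges.append(tpl.charges[a.name])
    for t in set(types):
        if t not in library.ff.lj:
            raise KeyError(f"no LJ parameters for type {t}")
    lj = np.array([library.ff.lj[t][:2] for t in types])

    res_of3 = {}
    for chain, seq, rname, amap in residues:
        for key, i in amap.items():
            res_of3[i] = (chain, seq, rname)
    bonds = bond_graph(model, library)
    # force constants by type; equilibrium values per instance from the same
    # ideal-geometry source the restraint target uses, except that X-H bonds
    # take nuclear lengths (the force field models nuclei)
    b_idx, b_ideal = _bond_ideals(library.nuclear(), atoms, bonds, res_of3)
    kb = [library.ff.bond_param(types[i], types[j])[0] for i, j in bonds]
    b0 = b_ideal

    nb = _neighbor_lists(n, bonds)
    ang, a_ideal = _angle_ideals(library, atoms, nb, res_of3)
    ak = [library.ff.angle_param(types[i], types[j], types[k])[0] for i, j, k in ang]
    at0 = list(np.radians(a_ideal))

    tor, tv, tn, tg = [], [], [], []
    for j, k in bonds:
        for i in nb[j]:
            if i == k:
                continue
            for l_ in nb[k]:
                if l_ == j or l_ == i:
                    continue
                p = library.ff.torsion_param(types[i], types[j], types[k], types[l_])
                if p is None or p[0] == 0.0:
                    continue
                v, per, g = p
                tor.append((i, j, k, l_))
                tv.append(v)
                tn.append(per)
                tg.append(np.radians(g))
    # impropers hold sp2 centers planar
    ffp = library.ff
    for c in range(n):
        if len(nb[c]) != 3:
            continue
        tc = types[c]
        planar = tc in ("C", "CA") or (
            tc == "N" and any(types[x] in ("C", "CA") for x in nb[c])
        )
        if not planar:
            continue
        n1, n2, n3 = sorted(nb[c])
        tor.append((n1, n2, c, n3))
        tv.append(ffp.improper_k)
        tn.append(ffp.improper_period)
        tg.append(np.radians(ffp.improper_phase))

    # exclusions: 1-2, 1-3 excluded; 1-4 scaled
    excluded = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(excluded, True)
    for i, j in bonds:
        excluded[i, j] = excluded[j, i] = True
    for j in range(n):
        for x, i in enumerate(nb[j]):
            for k in nb[j][x + 1:]:
                excluded[i, k] = excluded[k, i] = True
    one_four = set()
    for j, k in bonds:
        for i in nb[j]:
            for l_ in nb[k]:
                if i != k and l_ != j and i != l_ and not excluded[i, l_]:
                    one_four.add((min(i, l_), max(i, l_)))
    pairs14 = np.array(sorted(one_four), int).reshape(-1, 2)

    les_groups, copy_weight, copy_id = _les_groups(model)

    net = float(np.sum(charges))
    expected = sum(
        library.template(rname).formal_charge for _, _, rname, _ in residues
    )
    if abs(net - expected) > 1e-6:
        logger.warning("net charge %.4f differs from formal total %d", net, expected)

    return MMTopology(
        n_atoms=n,
        charges=np.array(charges, float),
        lj_rmin2=lj[:, 0].copy(),
        lj_eps=lj[:, 1].copy(),
        bonds=np.array(bonds, int).reshape(-1, 2),
        bond_kb=np.array(kb, float),
        bond_b0=np.array(b0, float),
        angles=np.array(ang, int).reshape(-1, 3),
        angle_k=np.array(ak, float),
        angle_t0=np.array(at0, float),
        torsions=np.array(tor, int).reshape(-1, 4),
        torsion_v2=np.array(tv, float),
        torsion_n=np.array(tn, int),
        torsion_gamma=np.array(tg, float),
        excluded=excluded,
        pairs14=pairs14,
        scale14_elec=library.ff.scale14_elec,
        scale14_lj=library.ff.scale14_lj,
        les_groups=les_groups,
        copy_weight=copy_weight,
        copy_id=copy_id,
    )


def _les_groups(model: AtomicModel):
    """One LES group per chain that carries altloc labels; copies are the
    labels, weights are renormalized mean occupancies of each copy."""
    n = len(model)
    copy_weight = np.ones(n)
    copy_id = np.full((n, 2), -1, dtype=int)
    groups = []
    chains: dict[str, dict[str, list[int]]] = {}
    for i, a in enumerate(model.atoms):
        if a.altloc:
            chains.setdefault(a.chain, {}).setdefault(a.altloc, []).append(i)
    for g, (chain, copies) in enumerate(sorted(chains.items())):
        occ = {alt: float(np.mean([model.atoms[i].occupancy for i in idxs]))
               for alt, idxs in copies.items()}
        total = sum(occ.values())
        weights = {alt: occ[alt] / total for alt in occ}
        for c, (alt, idxs) in enumerate(sorted(copies.items())):
            for i in idxs:
                copy_weight[i] = weights[alt]
                copy_id[i] = (g, c)
        groups.append({
            "chain": chain,
            "copies": {alt: np.array(idxs, int) for alt, idxs in sorted(copies.items())},
            "weights": weights,
        })
    return groups, copy_weight, copy_id
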