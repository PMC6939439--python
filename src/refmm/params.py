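"""Parser for the plain-text parameter library.

The library carries three kinds of information in one file:

* ``[residue XXX]`` blocks: template topology (atoms, charges, LJ types,
  bonds), internal coordinates for rebuilding ideal geometry, chirality
  volumes and planarity groups;
* ``[ff]`` block: the reduced force-field constants (LJ, bond/angle/torsion
  types, 1-4 scaling, improper constants);
* ``[geo]`` block: restraint sigmas and the repulsion screen, plus
  electron-cloud-center X-H bond lengths;
* ``[link peptide]`` block: ideal values for the inter-residue peptide link.

A formal grammar is given in docs/parameter_dialect.md.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .nerf import bond_angle, bond_length, place_atom

__all__ = [
    "ResidueTemplate",
    "ForceFieldParams",
    "GeoParams",
    "PeptideLink",
    "ParameterLibrary",
    "load_library",
    "default_library_path",
]


@dataclass
class ICRecord:
    atom: str
    r1: str
    r2: str
    r3: str
    length: float
    angle: float
    torsion: float


@dataclass
class ResidueTemplate:
    """Topology and ideal internal coordinates of one residue."""

    name: str
    formal_charge: int
    atoms: list[str] = field(default_factory=list)
    elements: dict[str, str] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)
    lj_types: dict[str, str] = field(default_factory=dict)
    bonds: list[tuple[str, str]] = field(default_factory=list)
    ics: list[ICRecord] = field(default_factory=list)
    chirals: list[tuple[str, str, str, str, float]] = field(default_factory=list)
    planes: list[list[str]] = field(default_factory=list)
    root: tuple[float, float, float] | None = None  # N-CA, CA-C, N-CA-C angle

    def neighbor_map(self) -> dict[str, list[str]]:
        nb: dict[str, list[str]] = {a: [] for a in self.atoms}
        for a, b in self.bonds:
            nb[a].append(b)
            nb[b].append(a)
        return nb

    def heavy_atoms(self) -> list[str]:
        return [a for a in self.atoms if self.elements[a] != "H"]

    def hydrogens(self) -> list[str]:
        return [a for a in self.atoms if self.elements[a] == "H"]


@dataclass
class ForceFieldParams:
    lj: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    bond_types: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    angle_types: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    torsion_types: list[tuple[str, str, str, str, float, int, float]] = field(default_factory=list)
    scale14_elec: float = 1.0 / 1.2
    scale14_lj: float = 0.5
    improper_k: float = 10.5
    improper_period: int = 2
    improper_phase: float = 180.0

    def bond_param(self, t1: str, t2: str) -> tuple[float, float]:
        key = tuple(sorted((t1, t2)))
        if key not in self.bond_types:
            raise KeyError(f"no bond type for {t1}-{t2}")
        return self.bond_types[key]

    def angle_param(self, t1: str, t2: str, t3: str) -> tuple[float, float]:
        key = (min(t1, t3), t2, max(t1, t3))
        if key not in self.angle_types:
            raise KeyError(f"no angle type for {t1}-{t2}-{t3}")
        return self.angle_types[key]

    def torsion_param(self, t1: str, t2: str, t3: str, t4: str):
        """Wildcard-matched torsion constants, or None if the bond is free."""
        for a1, a2, a3, a4, v, n, g in self.torsion_types:
            for c1, c2, c3, c4 in ((a1, a2, a3, a4), (a4, a3, a2, a1)):
                if (
                    c2 == t2 and c3 == t3
                    and c1 in ("X", t1) and c4 in ("X", t4)
                ):
                    return v, n, g
        return None


@dataclass
class GeoParams:
    sigma_bond: float = 0.02
    sigma_angle: float = 2.0
    sigma_torsion: float = 5.0
    sigma_chirality: float = 0.2
    sigma_plane: float = 0.02
    sigma_repulsion: float = 0.2
    repulsion_screen: float = 4.5
    repulsion_tolerance: float = 0.2
    ec_bond: dict[str, float] = field(default_factory=dict)  # heavy element -> X-H length


@dataclass
class PeptideLink:
    """Ideal values for the C(i)-N(i+1) peptide link."""

    bond: tuple[str, str, float] = ("C", "N", 1.329)
    angles: list[tuple[str, str, str, float]] = field(default_factory=list)
    omega: tuple[float, float, int] = (180.0, 5.0, 1)  # ideal, sigma, period
    plane: list[str] = field(default_factory=list)  # '+X' marks next residue


class ParameterLibrary:
    def __init__(
        self,
        residues: dict[str, ResidueTemplate],
        ff: ForceFieldParams,
        geo: GeoParams,
        link: PeptideLink,
        h_mode: str = "electron-cloud",
    ):
        if h_mode not in ("electron-cloud", "nuclear"):
            raise ValueError(f"unknown hydrogen mode {h_mode!r}")
        self.residues = residues
        self.ff = ff
        self.geo = geo
        self.link = link
        self.h_mode = h_mode
        self._ideal_cache: dict[str, dict[str, np.ndarray]] = {}

    def nuclear(self) -> "ParameterLibrary":
        """Same library with nuclear X-H bond lengths (used by the
        force-field topology, which models nuclei, not electron clouds)."""
        if self.h_mode == "nuclear":
            return self
        if not hasattr(self, "_nuclear"):
            self._nuclear = ParameterLibrary(
                self.residues, self.ff, self.geo, self.link, h_mode="nuclear"
            )
        return self._nuclear

    def template(self, res_name: str) -> ResidueTemplate:
        if res_name not in self.residues:
            raise KeyError(f"no template for residue {res_name!r}")
        return self.residues[res_name]

    def ic_length(self, tpl: ResidueTemplate, rec: ICRecord) -> float:
        """Template bond length with the electron-cloud X-H convention applied."""
        if self.h_mode == "electron-cloud" and tpl.elements[rec.atom] == "H":
            ec = self.geo.ec_bond.get(tpl.elements[rec.r1])
            if ec is not None:
                return ec
        return rec.length

    def ideal_coords(self, res_name: str) -> dict[str, np.ndarray]:
        """Rebuild the template's ideal Cartesian geometry from its internal
        coordinates.  Used as the source of every per-instance ideal value."""
        if res_name in self._ideal_cache:
            return self._ideal_cache[res_name]
        tpl = self.template(res_name)
        if tpl.root is None:
            raise ValueError(f"residue {res_name} has no rebuildable geometry")
        d_nca, d_cac, ang = tpl.root
        coords: dict[str, np.ndarray] = {
            "N": np.array([0.0, 0.0, 0.0]),
            "CA": np.array([d_nca, 0.0, 0.0]),
        }
        th = np.radians(ang)
        coords["C"] = coords["CA"] + d_cac * np.array([-np.cos(th), np.sin(th), 0.0])
        for rec in tpl.ics:
            coords[rec.atom] = place_atom(
                coords[rec.r1], coords[rec.r2], coords[rec.r3],
                self.ic_length(tpl, rec), rec.angle, rec.torsion,
            )
        self._ideal_cache[res_name] = coords
        return coords

    def ideal_bond(self, res_name: str, a: str, b: str) -> float:
        c = self.ideal_coords(res_name)
        return bond_length(c[a], c[b])

    def ideal_angle(self, res_name: str, a: str, b: str, c_: str) -> float:
        c = self.ideal_coords(res_name)
        return bond_angle(c[a], c[b], c[c_])


def _parse(text: str) -> tuple[dict, ForceFieldParams, GeoParams, PeptideLink]:
    residues: dict[str, ResidueTemplate] = {}
    ff = ForceFieldParams()
    geo = GeoParams()
    link = PeptideLink()
    section = None
    current: ResidueTemplate | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            head = line.strip("[]").split()
            if head[0] == "residue":
                current = ResidueTemplate(name=head[1], formal_charge=0)
                residues[head[1]] = current
                section = "residue"
            elif head[0] == "ff":
                section = "ff"
            elif head[0] == "geo":
                section = "geo"
            elif head[0] == "link":
                section = "link"
            else:
                raise ValueError(f"line {lineno}: unknown section {line!r}")
            continue
        tok = line.split()
        try:
            if section == "ff":
                _parse_ff(ff, tok)
            elif section == "geo":
                _parse_geo(geo, tok)
            elif section == "link":
                _parse_link(link, tok)
            elif section == "residue":
                _parse_residue(current, tok)
            else:
                raise ValueError("content outside any section")
        except (IndexError, ValueError, KeyError) as exc:
            raise ValueError(f"parameter file line {lineno}: {raw!r} ({exc})") from exc
    return residues, ff, geo, link


def _parse_ff(ff: ForceFieldParams, tok: list[str]):
    kind = tok[0]
    if kind == "ljtype":
        ff.lj[tok[1]] = (float(tok[2]), float(tok[3]), float(tok[4]))
    elif kind == "bondtype":
        ff.bond_types[tuple(sorted(tok[1:3]))] = (float(tok[3]), float(tok[4]))
    elif kind == "angletype":
        t1, t2, t3 = tok[1:4]
        ff.angle_types[(min(t1, t3), t2, max(t1, t3))] = (float(tok[4]), float(tok[5]))
    elif kind == "torsiontype":
        ff.torsion_types.append(
            (tok[1], tok[2], tok[3], tok[4], float(tok[5]), int(tok[6]), float(tok[7]))
        )
    elif kind == "scale14":
        ff.scale14_elec, ff.scale14_lj = float(tok[1]), float(tok[2])
    elif kind == "improper":
        ff.improper_k, ff.improper_period, ff.improper_phase = (
            float(tok[1]), int(tok[2]), float(tok[3]),
        )
    else:
        raise ValueError(f"unknown ff record {kind!r}")


def _parse_geo(geo: GeoParams, tok: list[str]):
    kind = tok[0]
    if kind == "ec_bond":
        geo.ec_bond[tok[1]] = float(tok[3])
    elif hasattr(geo, kind):
        setattr(geo, kind, float(tok[1]))
    else:
        raise ValueError(f"unknown geo record {kind!r}")


def _parse_link(link: PeptideLink, tok: list[str]):
    kind = tok[0]
    if kind == "bond":
        link.bond = (tok[1], tok[2], float(tok[3]))
    elif kind == "angle":
        link.angles.append((tok[1], tok[2], tok[3], float(tok[4])))
    elif kind == "torsion":
        link.omega = (float(tok[5]), float(tok[6]), int(tok[7]))
    elif kind == "plane":
        link.plane = tok[1:]
    else:
        raise ValueError(f"unknown link record {kind!r}")


def _parse_residue(tpl: ResidueTemplate, tok: list[str]):
    kind = tok[0]
    if kind == "formal_charge":
        tpl.formal_charge = int(tok[1])
    elif kind == "root":
        tpl.root = (float(tok[1]), float(tok[2]), float(tok[3]))
    elif kind == "atom":
        name, elem, q, t = tok[1], tok[2], float(tok[3]), tok[4]
        if elem not in {"H", "C", "N", "O", "S"}:
            raise ValueError(f"unsupported element {elem}")
        tpl.atoms.append(name)
        tpl.elements[name] = elem
        tpl.charges[name] = q
        tpl.lj_types[name] = t
    elif kind == "bond":
        tpl.bonds.append((tok[1], tok[2]))
    elif kind == "ic":
        tpl.ics.append(
            ICRecord(tok[1], tok[2], tok[3], tok[4], float(tok[5]), float(tok[6]), float(tok[7]))
        )
    elif kind == "chiral":
        tpl.chirals.append((tok[1], tok[2], tok[3], tok[4], float(tok[5])))
    elif kind == "plane":
        tpl.planes.append(tok[1:])
    else:
        raise ValueError(f"unknown residue record {kind!r}")


def default_library_path():
    return importlib.resources.files("refmm") / "data" / "params.txt"


@lru_cache(maxsize=4)
def _load_cached(path_str: str, h_mode: str) -> ParameterLibrary:
    text = open(path_str).read() if path_str else default_library_path().read_text()
    residues, ff, geo, link = _parse(text)
    return ParameterLibrary(residues, ff, geo, link, h_mode=h_mode)


def load_library(path=None, h_mode: str = "electron-cloud") -> ParameterLibrary:
    """Load a parameter library (the packaged one by default).

    ``h_mode`` selects the X-H bond-length convention used when building or
    restraining hydrogens: "electron-cloud" (default, appropriate for X-ray
    scattering) or "nuclear".
    """
    return _load_cached(str(path) if path is not None else "", h_mode)
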