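"""Domain types: atoms, models, crystals and reflection sets.

Coordinates are Cartesian angstroms throughout; fractional coordinates
appear only at structure-factor time.  The unit-cell convention is the
standard crystallographic one (a along x, b in the x-y plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import gemmi
import numpy as np

SUPPORTED_ELEMENTS = {"H", "C", "N", "O", "S"}

__all__ = ["Atom", "AtomicModel", "Crystal", "ReflectionSet", "SUPPORTED_ELEMENTS"]


@dataclass
class Atom:
    """One atom of a crystallographic model.

    ``altloc`` is a single alternate-location character, or the empty string
    for single-conformer atoms.  ``b_iso`` is the isotropic displacement
    parameter in A^2.
    """

    name: str
    element: str
    chain: str
    res_name: str
    res_seq: int
    altloc: str
    occupancy: float
    b_iso: float
    xyz: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not (0.0 <= self.occupancy <= 1.0 + 1e-9):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for {self.name}")
        if self.b_iso < 0:
            raise ValueError(f"negative B factor for {self.name}")

    @property
    def key(self):
        return (self.chain, self.res_seq, self.name, self.altloc)


class AtomicModel:
    """Ordered collection of atoms with a chain -> residue -> atom hierarchy."""

    def __init__(self, atoms: list[Atom]):
        self.atoms = list(atoms)
        seen = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom {a.key}")
            seen.add(a.key)
        self._check_altloc_occupancies()

    def _check_altloc_occupancies(self):
        groups: dict[tuple, float] = {}
        for a in self.atoms:
            if a.altloc:
                k = (a.chain, a.res_seq, a.name)
                groups[k] = groups.get(k, 0.0) + a.occupancy
        for k, s in groups.items():
            if s > 1.0 + 1e-6:
                raise ValueError(f"altloc occupancies for {k} sum to {s:.4f} > 1")

    def __len__(self):
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array (a copy)."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        """New model with the same atoms at the given coordinates."""
        coords = np.asarray(coords, dtype=float).reshape(len(self.atoms), 3)
        atoms = [replace(a, xyz=c.copy()) for a, c in zip(self.atoms, coords)]
        return AtomicModel(atoms)

    def residues(self) -> list[tuple[str, int, str, list[int]]]:
        """Residues in model order as (chain, res_seq, res_name, atom indices)."""
        out: list[tuple[str, int, str, list[int]]] = []
        index: dict[tuple[str, int], int] = {}
        for i, a in enumerate(self.atoms):
            k = (a.chain, a.res_seq)
            if k not in index:
                index[k] = len(out)
                out.append((a.chain, a.res_seq, a.res_name, []))
            out[index[k]][3].append(i)
        return out

    def find(self, chain: str, res_seq: int, name: str, altloc: str = "") -> int | None:
        for i, a in enumerate(self.atoms):
            if (a.chain, a.res_seq, a.name, a.altloc) == (chain, res_seq, name, altloc):
                return i
        return None

    def rmsd_to(self, other: "AtomicModel") -> float:
        """Coordinate RMSD against a model with identical atom ordering."""
        if len(self) != len(other):
            raise ValueError("models differ in atom count")
        d = self.coords - other.coords
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


@dataclass
class Crystal:
    """Unit cell (A, degrees) plus symmetry operators in fractional space.

    ``symmetry_ops`` is a list of (3x3 rotation, translation) pairs; the
    identity is always present.  Toy fixtures use P1.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        if not self.symmetry_ops:
            self.symmetry_ops = [(np.eye(3), np.zeros(3))]
        self._cell = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        if not (self.volume > 0):  # catches NaN from impossible angle sets
            raise ValueError("degenerate unit cell (volume <= 0)")
        self._validate_ops()

    def _validate_ops(self):
        ops = [(np.asarray(r, float), np.asarray(t, float)) for r, t in self.symmetry_ops]
        self.symmetry_ops = ops
        if not any(np.allclose(r, np.eye(3)) and np.allclose(t % 1.0, 0.0) for r, t in ops):
            raise ValueError("symmetry operator set lacks the identity")
        for r1, t1 in ops:
            for r2, t2 in ops:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                if not any(
                    np.allclose(r, rr) and np.allclose(t, tt % 1.0, atol=1e-8)
                    for rr, tt in ops
                ):
                    raise ValueError("symmetry operator set not closed under composition")

    @property
    def volume(self) -> float:
        return float(self._cell.volume)

    @property
    def orth_matrix(self) -> np.ndarray:
        m = self._cell.orth.mat
        return np.array(m.tolist(), dtype=float)

    @property
    def frac_matrix(self) -> np.ndarray:
        m = self._cell.frac.mat
        return np.array(m.tolist(), dtype=float)

    def orthogonalize(self, frac_xyz: np.ndarray) -> np.ndarray:
        return np.asarray(frac_xyz, float) @ self.orth_matrix.T

    def fractionalize(self, cart_xyz: np.ndarray) -> np.ndarray:
        return np.asarray(cart_xyz, float) @ self.frac_matrix.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (A) for an (n, 3) array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, float))
        # |s_vec| = |F^T h| with F the fractionalization matrix: 1/d.
        s = hkl @ self.frac_matrix
        inv_d = np.linalg.norm(s, axis=1)
        with np.errstate(divide="ignore"):
            return np.where(inv_d > 0, 1.0 / np.where(inv_d > 0, inv_d, 1.0), np.inf)


@dataclass
class ReflectionSet:
    """Observed amplitudes with esds and cross-validation flags."""

    hkl: np.ndarray          # (n, 3) int
    f_obs: np.ndarray        # (n,)  >= 0
    sigma: np.ndarray        # (n,)
    is_free: np.ndarray      # (n,)  bool

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        self.f_obs = np.asarray(self.f_obs, dtype=float).reshape(n)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(n)
        self.is_free = np.asarray(self.is_free, dtype=bool).reshape(n)
        uniq, counts = np.unique(self.hkl, axis=0, return_counts=True)
        if np.any(counts > 1):
            dup = uniq[counts > 1][0]
            raise ValueError(f"duplicate Miller index {tuple(dup)}")
        if np.any(self.f_obs < 0):
            raise ValueError("negative observed amplitude")

    def __len__(self):
        return len(self.hkl)

    @property
    def work(self) -> np.ndarray:
        return ~self.is_free
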