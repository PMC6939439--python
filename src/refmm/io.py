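"""Reading and writing of atomic models and reflection data.

PDB files are parsed and written through gemmi; only the fields the engine
uses (ATOM/HETATM with altloc, occupancy, isotropic B, CRYST1) are kept.
ANISOU records are ignored with a logged note.  Reflections travel as a
delimited text table with header ``h,k,l,f_obs,sigma,free``.  Space groups
other than P1 are supported only through an explicit operator sidecar file
(one ``x,y,z``-style triplet per line).
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .model import Atom, AtomicModel, Crystal, ReflectionSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_reflections",
    "write_reflections",
    "read_symmetry_ops",
    "assign_free_set",
]


def _prescan(path: Path) -> bool:
    """Validate fixed-column numeric fields; return whether CRYST1 exists."""
    has_cryst1 = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                has_cryst1 = True
            if rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"{path}: line {lineno}: truncated ATOM/HETATM record")
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z"),
                                     (54, 60, "occupancy"), (60, 66, "B factor")):
                    fld = line[lo:hi].strip()
                    if fld == "" and lo >= 54:
                        continue  # occupancy/B may be absent in minimal files
                    try:
                        float(fld)
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}: malformed {what} field {fld!r}"
                        ) from None
            if rec == "ANISOU":
                logger.info("%s: ANISOU records ignored (isotropic B only)", path)
    return has_cryst1


def read_pdb(path, symmetry_ops_path=None) -> tuple[AtomicModel, Crystal | None]:
    """Read a PDB file into an AtomicModel and (if CRYST1 is present) a Crystal.

    Returns ``(model, None)`` with a logged warning when CRYST1 is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    has_cryst1 = _prescan(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    atoms: list[Atom] = []
    for chain in st[0]:
        for res in chain:
            for at in res:
                altloc = at.altloc if at.altloc != "\x00" else ""
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        chain=chain.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        altloc=altloc,
                        occupancy=at.occ,
                        b_iso=at.b_iso,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    model = AtomicModel(atoms)
    crystal = None
    if has_cryst1:
        ops = read_symmetry_ops(symmetry_ops_path) if symmetry_ops_path else None
        cell = st.cell
        crystal = Crystal(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma,
                          symmetry_ops=ops or [])
    else:
        logger.warning("%s: no CRYST1 record; crystal absent", path)
    return model, crystal


def write_pdb(model: AtomicModel, crystal: Crystal | None, path) -> None:
    """Write model and cell as a fixed-column PDB file (round-trip safe)."""
    for a in model:
        if len(a.name) > 4:
            raise ValueError(f"atom name {a.name!r} longer than 4 characters")
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    if crystal is not None:
        st.cell = gemmi.UnitCell(crystal.a, crystal.b, crystal.c,
                                 crystal.alpha, crystal.beta, crystal.gamma)
        st.spacegroup_hm = "P 1"
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple, gemmi.Residue] = {}
    for a in model:
        if a.chain not in chain_map:
            st[0].add_chain(gemmi.Chain(a.chain))
            chain_map[a.chain] = st[0][len(st[0]) - 1]
        rkey = (a.chain, a.res_seq)
        if rkey not in res_map:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            chain_map[a.chain].add_residue(res)
            ch = chain_map[a.chain]
            res_map[rkey] = ch[len(ch) - 1]
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.altloc = a.altloc if a.altloc else "\x00"
        at.occ = a.occupancy
        at.b_iso = a.b_iso
        at.pos = gemmi.Position(*a.xyz)
        res_map[rkey].add_atom(at)
    st.write_pdb(str(path))


_REFL_COLUMNS = ["h", "k", "l", "f_obs", "sigma", "free"]


def read_reflections(path) -> ReflectionSet:
    df = pd.read_csv(path)
    missing = [c for c in _REFL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing reflection columns {missing}")
    hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
    uniq, inv, counts = np.unique(hkl, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        bad = uniq[counts > 1]
        rows = [int(i) for i in np.flatnonzero(np.isin(inv, np.flatnonzero(counts > 1)))]
        raise ValueError(f"{path}: duplicate Miller indices {bad.tolist()} at rows {rows}")
    if (df["f_obs"] < 0).any():
        raise ValueError(f"{path}: negative f_obs")
    return ReflectionSet(
        hkl=hkl,
        f_obs=df["f_obs"].to_numpy(float),
        sigma=df["sigma"].to_numpy(float),
        is_free=df["free"].to_numpy(int).astype(bool),
    )


def write_reflections(refl: ReflectionSet, path) -> None:
    df = pd.DataFrame(
        {
            "h": refl.hkl[:, 0],
            "k": refl.hkl[:, 1],
            "l": refl.hkl[:, 2],
            "f_obs": refl.f_obs,
            "sigma": refl.sigma,
            "free": refl.is_free.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_symmetry_ops(path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read one symmetry operator per line as an ``x,y,z`` triplet string."""
    ops = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        op = gemmi.Op(line)
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))
    return ops


def assign_free_set(refl: ReflectionSet, fraction: float = 0.05, seed: int = 0) -> ReflectionSet:
    """Flag round(n * fraction) reflections as the cross-validation set.

    Deterministic in (hkl order, fraction, seed); R_free bookkeeping needs
    a withheld test set but no particular selection rule, so a seeded
    uniform draw is used.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("free fraction must be in [0, 1)")
    n = len(refl)
    n_free = int(round(n * fraction))
    rng = np.random.default_rng(seed)
    free_idx = rng.choice(n, size=n_free, replace=False)
    is_free = np.zeros(n, dtype=bool)
    is_free[free_idx] = True
    return ReflectionSet(refl.hkl.copy(), refl.f_obs.copy(), refl.sigma.copy(), is_free)
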