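"""Structure factors by direct summation and the least-squares X-ray target.

F(h) = sum_sym sum_atoms occ * f(s) * exp(-B s^2) * exp(2 pi i h . x_frac)

with s = sin(theta)/lambda = 1/(2d).  The experimental residual is the
scale-invariant least-squares form

    T_exp = sum_work (f_obs - k |F_calc|)^2 / sum_work f_obs^2,

with k the closed-form least-squares scale; its gradient with respect to the
Cartesian coordinates is analytic (the optimal k makes the dk/dx term vanish).
Free-set reflections never enter the target or its gradient.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .model import AtomicModel, Crystal, ReflectionSet

__all__ = [
    "FormFactorTable",
    "load_form_factors",
    "calc_fcalc",
    "StructureFactorSet",
    "xray_target_grad",
    "r_factors",
]

TWO_PI = 2.0 * np.pi


@dataclass
class FormFactorTable:
    """Per-element 4-Gaussian + constant scattering-factor coefficients."""

    a: dict[str, np.ndarray]
    b: dict[str, np.ndarray]
    c: dict[str, float]

    def f(self, element: str, s2: np.ndarray) -> np.ndarray:
        """f(s) for an array of s^2 = (sin theta / lambda)^2 values."""
        if element not in self.a:
            raise KeyError(f"no scattering factors for element {element!r}")
        a, b, c = self.a[element], self.b[element], self.c[element]
        return np.exp(-np.outer(s2, b)) @ a + c

    def f0(self, element: str) -> float:
        return float(self.a[element].sum() + self.c[element])


@lru_cache(maxsize=1)
def load_form_factors() -> FormFactorTable:
    path = importlib.resources.files("refmm") / "data" / "form_factors.csv"
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p, comment="#")
    a, b, c = {}, {}, {}
    for _, row in df.iterrows():
        el = row["element"]
        a[el] = row[["a1", "a2", "a3", "a4"]].to_numpy(float)
        b[el] = row[["b1", "b2", "b3", "b4"]].to_numpy(float)
        c[el] = float(row["c"])
    tab = FormFactorTable(a, b, c)
    # sanity: f(0) must match the element electron count
    for el, z in (("H", 1), ("C", 6), ("N", 7), ("O", 8), ("S", 16)):
        assert abs(tab.f0(el) - z) < 0.1
    return tab


@dataclass
class StructureFactorSet:
    hkl: np.ndarray
    f_calc: np.ndarray  # complex
    scale: float = 1.0

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.f_calc)


def _atom_factors(model: AtomicModel, s2: np.ndarray, table: FormFactorTable) -> np.ndarray:
    """(n_refl, n_atoms) occ * f(s) * exp(-B s^2)."""
    out = np.empty((len(s2), len(model)))
    f_cache: dict[str, np.ndarray] = {}
    for j, atom in enumerate(model.atoms):
        if atom.element not in f_cache:
            f_cache[atom.element] = table.f(atom.element, s2)
        out[:, j] = atom.occupancy * f_cache[atom.element] * np.exp(-atom.b_iso * s2)
    return out


def calc_fcalc(
    model: AtomicModel,
    crystal: Crystal,
    hkl: np.ndarray,
    table: FormFactorTable | None = None,
) -> StructureFactorSet:
    """Direct-summation structure factors over all symmetry operators."""
    table = table or load_form_factors()
    hkl = np.asarray(hkl, int).reshape(-1, 3)
    d = crystal.d_spacing(hkl)
    s2 = 1.0 / (4.0 * d * d)
    A = _atom_factors(model, s2, table)
    frac = crystal.fractionalize(model.coords)
    F = np.zeros(len(hkl), dtype=complex)
    for rot, tran in crystal.symmetry_ops:
        fs = frac @ rot.T + tran
        phase = TWO_PI * (hkl @ fs.T)  # (n_refl, n_atoms)
        F += np.sum(A * np.exp(1j * phase), axis=1)
    return StructureFactorSet(hkl=hkl, f_calc=F)


def ls_scale(f_obs: np.ndarray, f_calc_amp: np.ndarray) -> float:
    """Closed-form least-squares scale k minimizing sum (f_obs - k|F|)^2."""
    denom = float(np.sum(f_calc_amp**2))
    if denom <= 0:
        raise ValueError("all calculated amplitudes vanish")
    return float(np.sum(f_obs * f_calc_amp) / denom)


def xray_target_grad(
    model: AtomicModel,
    crystal: Crystal,
    refl: ReflectionSet,
    table: FormFactorTable | None = None,
) -> tuple[float, np.ndarray, float]:
    """Least-squares experimental target, its coordinate gradient, and k.

    Returns ``(T_exp, gradient (n_atoms, 3), k)``; free reflections are
    excluded from all three.
    """
    table = table or load_form_factors()
    work = refl.work
    if not np.any(work):
        raise ValueError("no working-set reflections")
    hkl = refl.hkl
    d = crystal.d_spacing(hkl)
    s2 = 1.0 / (4.0 * d * d)
    A = _atom_factors(model, s2, table)
    frac = crystal.fractionalize(model.coords)
    fm = crystal.frac_matrix

    F = np.zeros(len(hkl), dtype=complex)
    phases = []
    hvecs = []
    for rot, tran in crystal.symmetry_ops:
        fs = frac @ rot.T + tran
        phase = TWO_PI * (hkl @ fs.T)
        phases.append(phase)
        F += np.sum(A * np.exp(1j * phase), axis=1)
        hvecs.append(TWO_PI * (hkl @ rot @ fm))  # d(phase)/d(cart xyz)

    amp = np.abs(F)
    fo = refl.f_obs
    norm = float(np.sum(fo[work] ** 2))
    k = ls_scale(fo[work], amp[work])
    resid = fo - k * amp
    t_exp = float(np.sum(resid[work] ** 2) / norm)

    # dT/d|F|_h, work only; optimal k removes the dk/dx contribution
    c = np.zeros(len(hkl))
    c[work] = -2.0 * k * resid[work] / norm
    safe_amp = np.where(amp > 1e-12, amp, 1.0)
    u = c * F.conj() / safe_amp  # complex weight per reflection

    grad = np.zeros((len(model), 3))
    for phase, hvec in zip(phases, hvecs):
        w = np.real(1j * u[:, None] * np.exp(1j * phase)) * A  # (n_refl, n_atoms)
        grad += w.T @ hvec
    return t_exp, grad, k


def r_factors(
    refl: ReflectionSet, fcalc: StructureFactorSet, k: float | None = None
) -> tuple[float, float | None]:
    """Conventional R = sum |f_obs - k |F_calc|| / sum f_obs over the work
    and free subsets, as fractions.  R_free is None when no free set exists."""
    amp = fcalc.amplitude
    work = refl.work
    if not np.any(work):
        raise ValueError("no working-set reflections")
    if k is None:
        k = ls_scale(refl.f_obs[work], amp[work])

    def _r(mask):
        denom = float(np.sum(refl.f_obs[mask]))
        if denom <= 0:
            return None
        return float(np.sum(np.abs(refl.f_obs[mask] - k * amp[mask])) / denom)

    r_work = _r(work)
    r_free = _r(refl.is_free) if np.any(refl.is_free) else None
    return r_work, r_free
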