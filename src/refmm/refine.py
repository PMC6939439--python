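"""Macrocycle refinement engine: weighted target assembly, gradient-norm
weighting, quasi-Newton coordinate minimization and weight-scale
optimization.

Each macrocycle recomputes the weight

    w = scale * ||grad T_restraints|| / ||grad T_exp||

at its starting coordinates, freezes it, and minimizes

    T_xyz = w * T_exp + T_restraints

over coordinates only (occupancies and B factors fixed).  The restraint term
is either the ideal-geometry residual or the force-field energy, selected by
``restraint_mode``.  The weight scale defaults to 0.5 for geometry restraints
and 0.2 for the force-field target, whose gradients are roughly five times
larger at matched geometry quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .geo import geo_target_grad, geometry_rmsd
from .mm import energy_grad
from .model import AtomicModel, Crystal, ReflectionSet
from .params import ParameterLibrary, load_library
from .prep import MMTopology, RestraintSet, add_hydrogens, build_mm_topology, build_restraints
from .xray import calc_fcalc, r_factors, xray_target_grad

__all__ = [
    "RefineConfig",
    "TargetBreakdown",
    "compute_weight",
    "minimize_coords",
    "refine",
    "optimize_weight",
]

DEFAULT_SCALE = {"geo": 0.5, "mm": 0.2}


@dataclass
class RefineConfig:
    restraint_mode: str = "geo"            # geo | mm
    n_macrocycles: int = 10
    weight_scale: float | None = None      # None -> mode default
    optimize_weight: bool = False
    scale_grid: tuple = (0.1, 0.25, 0.5, 1.0, 2.0)
    minimizer_steps: int = 50
    grad_tol: float = 1e-4
    weight_shake: float = 0.05  # A rms displacement for gradient-norm estimation
    seed: int = 0

    def __post_init__(self):
        if self.restraint_mode not in ("geo", "mm"):
            raise ValueError(f"unknown restraint mode {self.restraint_mode!r}")
        if self.n_macrocycles < 1:
            raise ValueError("n_macrocycles must be >= 1")
        if self.weight_scale is None:
            self.weight_scale = DEFAULT_SCALE[self.restraint_mode]
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be > 0")


@dataclass
class TargetBreakdown:
    """Per-macrocycle record: T_xyz = w * T_exp + T_restraints."""

    macrocycle: int
    t_xyz: float
    t_exp: float
    t_restraints: float
    weight: float
    r_work: float
    r_free: float | None
    rmsd_bonds: float
    rmsd_angles: float

    def __post_init__(self):
        assert abs(self.t_xyz - (self.weight * self.t_exp + self.t_restraints)) <= 1e-9 * max(
            1.0, abs(self.t_xyz)
        )

    def as_dict(self):
        return {
            "macrocycle": self.macrocycle,
            "t_xyz": self.t_xyz,
            "t_exp": self.t_exp,
            "t_restraints": self.t_restraints,
            "weight": self.weight,
            "r_work": self.r_work,
            "r_free": self.r_free,
            "rmsd_bonds": self.rmsd_bonds,
            "rmsd_angles": self.rmsd_angles,
        }


def compute_weight(grad_restraints_norm: float, grad_xray_norm: float, scale: float) -> float:
    """Gradient-norm-ratio weight: w = scale * ||g_restr|| / ||g_xray||."""
    if grad_xray_norm <= 0:
        raise ValueError("X-ray gradient norm is zero (flat experimental target)")
    if grad_restraints_norm <= 0:
        raise ValueError("restraint gradient norm is zero")
    return scale * grad_restraints_norm / grad_xray_norm


def minimize_coords(model: AtomicModel, target_fn, step_budget: int = 50, tol: float = 1e-4):
    """L-BFGS coordinate minimization under a (value, gradient) callable.

    Returns ``(model, info)``; the returned model never has a larger target
    value than the input.  Terminates on the gradient tolerance, the step
    budget, or line-search failure, whichever comes first; deterministic for
    fixed inputs.
    """
    x0 = model.coords.ravel()
    f0, _ = target_fn(model.coords)
    if not np.isfinite(f0):
        raise ValueError("non-finite target at starting coordinates")

    def fun(x):
        v, g = target_fn(x.reshape(-1, 3))
        return v, g.ravel()

    res = _scipy_minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": step_budget, "gtol": tol, "ftol": 1e-12},
    )
    x_best, f_best = (res.x, res.fun) if res.fun <= f0 else (x0, f0)
    info = {"n_iter": int(res.nit), "converged": bool(res.success), "f0": f0, "f": float(f_best)}
    return model.with_coords(x_best.reshape(-1, 3)), info


def _restraint_backend(model, config, library):
    if config.restraint_mode == "geo":
        rs = build_restraints(model, library)

        def fn(xyz):
            rep, g = geo_target_grad(model.with_coords(xyz), rs)
            return rep.total, g

        return rs, fn
    top = build_mm_topology(model, library)

    def fn(xyz):
        rep, g = energy_grad(model.with_coords(xyz), top)
        return rep.total, g

    return top, fn


def refine(
    model: AtomicModel,
    crystal: Crystal,
    reflections: ReflectionSet,
    config: RefineConfig | None = None,
    library: ParameterLibrary | None = None,
) -> tuple[AtomicModel, list[TargetBreakdown]]:
    """Run ``n_macrocycles`` of reciprocal-space coordinate refinement.

    The model is completed (hydrogens/missing atoms) before the restraints
    are compiled.  Free reflections never enter the target, the weight, or
    the gradients.  A macrocycle that raises propagates the error after
    attaching the partial trajectory to the exception (``.trajectory``).
    """
    config = config or RefineConfig()
    library = library or load_library()
    model = add_hydrogens(model, library)
    backend, restr_fn = _restraint_backend(model, config, library)
    restraints_for_rmsd = (
        backend if isinstance(backend, RestraintSet) else build_restraints(model, library)
    )

    trajectory: list[TargetBreakdown] = []
    rng = np.random.default_rng(config.seed)
    try:
        for mc in range(1, config.n_macrocycles + 1):
            # Gradient norms for the weight are estimated at a small seeded
            # shake of the starting coordinates: at a converged macrocycle the
            # two gradients cancel exactly, so the raw ratio would decay
            # geometrically; a decorrelated nearby point gives a stable
            # curvature-based ratio instead.
            xs = model.coords
            if config.weight_shake > 0:
                delta = rng.standard_normal(xs.shape)
                delta *= config.weight_shake / np.sqrt(np.mean(np.sum(delta**2, axis=1)))
                xs = xs + delta
            _, g_x, _ = xray_target_grad(model.with_coords(xs), crystal, reflections)
            _, g_r = restr_fn(xs)
            w = compute_weight(
                float(np.linalg.norm(g_r)), float(np.linalg.norm(g_x)), config.weight_scale
            )

            def target(xyz):
                te, gx, _ = xray_target_grad(model.with_coords(xyz), crystal, reflections)
                tr, gr = restr_fn(xyz)
                return w * te + tr, w * gx + gr

            model, _ = minimize_coords(
                model, lambda xyz: target(xyz), config.minimizer_steps, config.grad_tol
            )
            t_exp, _, k = xray_target_grad(model, crystal, reflections)
            t_restr, _ = restr_fn(model.coords)
            fc = calc_fcalc(model, crystal, reflections.hkl)
            r_w, r_f = r_factors(reflections, fc, None)
            rb, ra = geometry_rmsd(model, restraints_for_rmsd)
            trajectory.append(
                TargetBreakdown(
                    macrocycle=mc,
                    t_xyz=w * t_exp + t_restr,
                    t_exp=t_exp,
                    t_restraints=t_restr,
                    weight=w,
                    r_work=r_w,
                    r_free=r_f,
                    rmsd_bonds=rb,
                    rmsd_angles=ra,
                )
            )
    except Exception as exc:
        exc.trajectory = trajectory
        raise
    return model, trajectory


def optimize_weight(
    model: AtomicModel,
    crystal: Crystal,
    reflections: ReflectionSet,
    config: RefineConfig | None = None,
    scale_grid=None,
    library: ParameterLibrary | None = None,
):
    """Grid search over weight scales, one full refinement per candidate.

    Selection rule (the named criteria are R factors, bond/angle r.m.s.d.
    and validation statistics; the decision function is this package's):

    * geo mode: among candidates with rmsd_bonds <= 0.02 A and
      rmsd_angles <= 2.5 deg, pick the lowest R_free;
    * mm mode: among candidates whose clashscore is <= the grid median,
      pick the lowest R_free;
    * ties break toward the smaller scale.  If every candidate fails the
      screen the lowest-R_free candidate is returned flagged.

    Returns ``(best_scale, summaries)`` where summaries maps scale ->
    final TargetBreakdown plus clashscore and a ``screen_pass`` flag.
    """
    from dataclasses import replace as _replace

    from .validate import clashscore

    config = config or RefineConfig()
    library = library or load_library()
    grid = list(scale_grid if scale_grid is not None else config.scale_grid)
    if not grid:
        raise ValueError("empty weight-scale grid")
    summaries = {}
    for scale in grid:
        cfg = _replace(config, weight_scale=scale, optimize_weight=False)
        refined, traj = refine(model, crystal, reflections, cfg, library)
        last = traj[-1]
        cs = clashscore(refined, library)[1]
        summaries[scale] = {
            "final": last,
            "clashscore": cs,
            "r_free": last.r_free if last.r_free is not None else last.r_work,
        }
    return select_weight(summaries, config.restraint_mode), summaries


def select_weight(summaries: dict, mode: str) -> float:
    """Apply the weight-selection rule to per-scale summaries.

    Mutates ``summaries`` to record ``screen_pass`` (and ``fallback`` on the
    chosen scale when every candidate fails the screen).
    """
    if mode == "geo":
        passes = {
            s: v for s, v in summaries.items()
            if v["final"].rmsd_bonds <= 0.02 and v["final"].rmsd_angles <= 2.5
        }
    else:
        median_cs = float(np.median([v["clashscore"] for v in summaries.values()]))
        passes = {s: v for s, v in summaries.items() if v["clashscore"] <= median_cs}
    pool = passes or summaries
    for s in summaries:
        summaries[s]["screen_pass"] = s in passes
    best = min(pool, key=lambda s: (pool[s]["r_free"], s))
    if not passes:
        summaries[best]["fallback"] = True
    return best
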