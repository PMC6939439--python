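"""Refinement engine: weighting, minimization contract, macrocycle behavior."""

import numpy as np
import pytest

from refmm import (
    RefineConfig,
    ToyCrystalSpec,
    clashscore,
    compute_weight,
    load_library,
    make_toy_crystal,
    minimize_coords,
    perturb_model,
    refine,
    simulate_fobs,
)
from refmm.refine import select_weight


def test_weight_formula():
    assert compute_weight(1.0, 1.0, 0.5) == pytest.approx(0.5)
    assert compute_weight(4.0, 2.0, 0.5) == pytest.approx(1.0)
    assert compute_weight(10.0, 2.0, 0.2) == pytest.approx(1.0)


def test_weight_rejects_flat_targets():
    with pytest.raises(ValueError, match="X-ray"):
        compute_weight(1.0, 0.0, 0.5)
    with pytest.raises(ValueError):
        compute_weight(0.0, 1.0, 0.5)


def test_default_scales_by_mode():
    assert RefineConfig(restraint_mode="geo").weight_scale == 0.5
    assert RefineConfig(restraint_mode="mm").weight_scale == 0.2


def test_minimizer_quadratic_surrogate(helix12):
    model, _ = helix12
    target = model.coords + 0.1

    def fn(xyz):
        d = xyz - target
        return float(np.sum(d * d)), 2 * d

    out, info = minimize_coords(model, fn, step_budget=200, tol=1e-10)
    assert np.allclose(out.coords, target, atol=1e-8)


def test_minimizer_at_local_minimum_is_stable(helix12):
    model, _ = helix12
    center = model.coords.copy()

    def fn(xyz):
        d = xyz - center
        return float(np.sum(d * d)), 2 * d

    out, info = minimize_coords(model, fn, step_budget=50)
    assert fn(out.coords)[0] <= 1e-12


def test_minimizer_never_increases_target(small_problem):
    truth, crystal, refl, start = small_problem
    lib = load_library()
    from refmm.geo import geo_target_grad
    from refmm.prep import build_restraints

    rs = build_restraints(start, lib)

    def fn(xyz):
        rep, g = geo_target_grad(start.with_coords(xyz), rs)
        return rep.total, g

    f0 = fn(start.coords)[0]
    out, info = minimize_coords(start, fn, step_budget=20)
    assert fn(out.coords)[0] <= f0


def test_minimizer_rejects_nonfinite_start(helix12):
    model, _ = helix12

    def fn(xyz):
        return np.inf, np.zeros_like(xyz)

    with pytest.raises(ValueError, match="non-finite"):
        minimize_coords(model, fn)


def test_refine_records_consistent_breakdown(small_problem):
    truth, crystal, refl, start = small_problem
    cfg = RefineConfig(restraint_mode="geo", n_macrocycles=2, minimizer_steps=25)
    out, traj = refine(start, crystal, refl, cfg)
    assert len(traj) == 2
    for tb in traj:
        assert tb.t_xyz == pytest.approx(tb.weight * tb.t_exp + tb.t_restraints, abs=1e-9)
        assert tb.r_work >= 0 and tb.rmsd_bonds >= 0


def test_refine_deterministic(small_problem):
    truth, crystal, refl, start = small_problem
    cfg = RefineConfig(restraint_mode="geo", n_macrocycles=2, minimizer_steps=25, seed=3)
    out1, traj1 = refine(start, crystal, refl, cfg)
    out2, traj2 = refine(start, crystal, refl, cfg)
    assert np.array_equal(out1.coords, out2.coords)
    assert [t.as_dict() for t in traj1] == [t.as_dict() for t in traj2]


def test_refine_noiseless_unperturbed_is_fixed_point(small_problem):
    truth, crystal, refl, _ = small_problem
    cfg = RefineConfig(restraint_mode="geo", n_macrocycles=2, minimizer_steps=25)
    out, traj = refine(truth, crystal, refl, cfg)
    assert out.rmsd_to(truth) < 0.01
    assert traj[-1].r_work < 0.01


def test_weight_extremes_trade_geometry_for_data(small_problem):
    """w -> 0 drives bond r.m.s.d. to zero; a huge weight buys R_work at the
    cost of looser geometry."""
    truth, crystal, refl, _ = small_problem
    start = perturb_model(truth, 0.25, seed=21)
    noisy = simulate_fobs(truth, crystal, d_min=2.5, noise_fraction=0.15, seed=22)
    lo = refine(start, crystal, noisy,
                RefineConfig(restraint_mode="geo", n_macrocycles=3,
                             minimizer_steps=40, weight_scale=1e-6))[1][-1]
    hi = refine(start, crystal, noisy,
                RefineConfig(restraint_mode="geo", n_macrocycles=3,
                             minimizer_steps=40, weight_scale=500.0))[1][-1]
    assert lo.rmsd_bonds < 0.002
    assert hi.r_work < lo.r_work
    assert hi.rmsd_bonds > lo.rmsd_bonds


def test_select_weight_prefers_smaller_scale_on_ties():
    from refmm.refine import TargetBreakdown

    def tb(rb=0.01, ra=1.0, rf=0.2):
        return TargetBreakdown(1, rf + 1.0, 1.0, rf, 1.0, rf, rf, rb, ra)

    summaries = {
        0.5: {"final": tb(), "clashscore": 0.0, "r_free": 0.2},
        1.0: {"final": tb(), "clashscore": 0.0, "r_free": 0.2},
    }
    assert select_weight(summaries, "geo") == 0.5


def test_select_weight_screens_geometry():
    from refmm.refine import TargetBreakdown

    def tb(rb, rf):
        return TargetBreakdown(1, rf + 1.0, 1.0, rf, 1.0, rf, rf, rb, 1.0)

    summaries = {
        0.5: {"final": tb(0.01, 0.25), "clashscore": 0.0, "r_free": 0.25},
        5.0: {"final": tb(0.05, 0.10), "clashscore": 0.0, "r_free": 0.10},
    }
    # the lower-R_free candidate fails the bond screen
    assert select_weight(summaries, "geo") == 0.5
    assert not summaries[5.0]["screen_pass"]


def test_select_weight_fallback_flag():
    from refmm.refine import TargetBreakdown

    def tb(rb, rf):
        return TargetBreakdown(1, rf + 1.0, 1.0, rf, 1.0, rf, rf, rb, 1.0)

    summaries = {
        1.0: {"final": tb(0.05, 0.2), "clashscore": 0.0, "r_free": 0.2},
        2.0: {"final": tb(0.06, 0.3), "clashscore": 0.0, "r_free": 0.3},
    }
    best = select_weight(summaries, "geo")
    assert best == 1.0 and summaries[1.0].get("fallback")


def test_single_element_grid_returned(small_problem):
    from refmm import optimize_weight

    truth, crystal, refl, start = small_problem
    cfg = RefineConfig(restraint_mode="geo", n_macrocycles=1, minimizer_steps=15)
    best, summaries = optimize_weight(start, crystal, refl, cfg, scale_grid=[0.7])
    assert best == 0.7 and list(summaries) == [0.7]


def test_mm_clashscore_not_worse_than_geo_paired_seeds():
    """Force-field refinement resolves at least as many severe contacts as
    geometry refinement on matched starts (paired comparison over seeds)."""
    lib = load_library()
    truth, crystal = make_toy_crystal(ToyCrystalSpec("AAAAAA", padding=6.0))
    refl = simulate_fobs(truth, crystal, d_min=2.5, noise_fraction=0.0, seed=31)
    geo_scores, mm_scores = [], []
    for seed in range(5):
        start = perturb_model(truth, 0.35, seed=100 + seed)
        for mode, acc in (("geo", geo_scores), ("mm", mm_scores)):
            cfg = RefineConfig(restraint_mode=mode, n_macrocycles=3, minimizer_steps=40)
            out, _ = refine(start, crystal, refl, cfg)
            acc.append(clashscore(out, lib)[1])
    assert np.mean(mm_scores) <= np.mean(geo_scores) + 1e-9
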