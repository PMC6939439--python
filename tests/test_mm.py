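"""Force-field target: pair terms, gradients, switching, LES identities."""

import dataclasses

import numpy as np
import pytest

from refmm import (
    AtomicModel,
    build_mm_topology,
    build_peptide,
    les_energy_grad,
    mm_energy_grad,
    perturb_model,
)
from refmm.mm import COULOMB_CONSTANT
from refmm.prep import MMTopology
from tests.conftest import fd_gradient_max_err


def _pair_model(r, elements=("C", "C")):
    from refmm.model import Atom

    return AtomicModel(
        [
            Atom("A1", elements[0], "A", "GLY", 1, "", 1.0, 10.0, np.zeros(3)),
            Atom("A2", elements[1], "A", "GLY", 2, "", 1.0, 10.0, np.array([r, 0.0, 0.0])),
        ]
    )


def _pair_topology(charges, rmin2, eps, cutoff=50.0):
    n = 2
    return MMTopology(
        n_atoms=n,
        charges=np.array(charges, float),
        lj_rmin2=np.array(rmin2, float),
        lj_eps=np.array(eps, float),
        bonds=np.zeros((0, 2), int), bond_kb=np.zeros(0), bond_b0=np.zeros(0),
        angles=np.zeros((0, 3), int), angle_k=np.zeros(0), angle_t0=np.zeros(0),
        torsions=np.zeros((0, 4), int), torsion_v2=np.zeros(0),
        torsion_n=np.zeros(0, int), torsion_gamma=np.zeros(0),
        excluded=np.eye(n, dtype=bool),
        pairs14=np.zeros((0, 2), int),
        copy_weight=np.ones(n), copy_id=np.full((n, 2), -1, int),
        cutoff=cutoff, switch_start=cutoff - 2,
    )


def test_lj_minimum_depth_and_zero_force():
    rmin2 = (1.9, 1.7)
    eps = (0.1, 0.2)
    top = _pair_topology((0.0, 0.0), rmin2, eps)
    model = _pair_model(sum(rmin2))
    report, grad = mm_energy_grad(model, top)
    assert report.total == pytest.approx(-np.sqrt(eps[0] * eps[1]), rel=1e-12)
    assert np.abs(grad).max() < 1e-8


def test_coulomb_constant_value():
    top = _pair_topology((1.0, 1.0), (1.0, 1.0), (0.0, 0.0))
    model = _pair_model(3.320637)
    report, _ = mm_energy_grad(model, top)
    assert report.subtotals["coulomb"] == pytest.approx(100.0, rel=1e-6)
    assert report.subtotals["lj"] == pytest.approx(0.0, abs=1e-12)


def test_overlapping_pair_rejected():
    top = _pair_topology((0.0, 0.0), (1.9, 1.9), (0.1, 0.1))
    with pytest.raises(ValueError, match="overlap"):
        mm_energy_grad(_pair_model(1e-9), top)


def test_gradient_matches_finite_differences_dipeptide(library):
    truth = build_peptide("AA", (-57.0, -47.0), library)
    model = perturb_model(truth, 0.08, seed=7)
    top = build_mm_topology(model, library)
    def fn(m):
        rep, g = mm_energy_grad(m, top)
        return rep.total, g

    err = fd_gradient_max_err(fn, model, n_coords=40, h=1e-5)
    assert err < 1e-6


def test_rigid_body_invariance_without_cutoff(library, mixed4):
    model, _ = mixed4
    top = build_mm_topology(model, library)
    top.cutoff, top.switch_start = 1e4, 1e4 - 2
    e0 = mm_energy_grad(model, top)[0].total
    th = 0.6
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
    )
    moved = model.with_coords(model.coords @ rot.T + np.array([3.0, -8.0, 2.0]))
    e1 = mm_energy_grad(moved, top)[0].total
    assert e1 == pytest.approx(e0, abs=1e-8 * max(1, abs(e0)))


def test_energy_smooth_at_cutoff():
    top = _pair_topology((0.5, -0.5), (1.9, 1.9), (0.1, 0.1), cutoff=12.0)
    top.switch_start = 10.0
    # value -> 0 at the cutoff and gradient continuous across it
    e_at = mm_energy_grad(_pair_model(11.9999), top)[0].total
    e_past = mm_energy_grad(_pair_model(12.0001), top)[0].total
    assert abs(e_at) < 1e-6 and e_past == 0.0
    for r in (9.995, 10.005, 11.5, 11.995):
        model = _pair_model(r)

        def fn(m):
            rep, g = mm_energy_grad(m, top)
            return rep.total, g

        err = fd_gradient_max_err(fn, model, n_coords=6)
        assert err < 1e-5, r


def _with_altloc_copy(model, res_seq, names, shift=0.0, occ=(0.5, 0.5)):
    atoms = []
    for a in model:
        if a.res_seq == res_seq and a.name in names:
            atoms.append(dataclasses.replace(a, altloc="A", occupancy=occ[0]))
            atoms.append(
                dataclasses.replace(a, altloc="B", occupancy=occ[1], xyz=a.xyz + shift)
            )
        else:
            atoms.append(a)
    return AtomicModel(atoms)


SIDE_CHAIN = ("CB", "HB1", "HB2", "HB3")


def test_les_single_copy_equals_plain_energy(library):
    model = build_peptide("AAA", (-57.0, -47.0), library)
    atoms = [
        dataclasses.replace(a, altloc="A")
        if a.res_seq == 2 and a.name in SIDE_CHAIN else a
        for a in model
    ]
    les_model = AtomicModel(atoms)
    top_plain = build_mm_topology(model, library)
    top_les = build_mm_topology(les_model, library)
    assert top_les.has_les and list(top_les.les_groups[0]["weights"].values()) == [1.0]
    e_plain, g_plain = mm_energy_grad(model, top_plain)
    e_les, g_les = les_energy_grad(les_model, top_les)
    assert e_les.total == pytest.approx(e_plain.total, abs=1e-9)
    assert np.allclose(g_les, g_plain, atol=1e-9)


def test_les_duplicated_copies_reproduce_single_energy(library):
    model = build_peptide("AAA", (-57.0, -47.0), library)
    dup = _with_altloc_copy(model, 2, SIDE_CHAIN, shift=0.0)
    top = build_mm_topology(dup, library)
    e_les = les_energy_grad(dup, top)[0]
    e_single = mm_energy_grad(model, build_mm_topology(model, library))[0]
    assert e_les.total == pytest.approx(e_single.total, abs=1e-9)
    for k in e_single.subtotals:
        assert e_les.subtotals[k] == pytest.approx(e_single.subtotals[k], abs=1e-9)


def test_les_copies_do_not_interact(library):
    """Copies of a group never see each other: with every atom in a copy,
    rigidly moving one copy (even into overlap with the other) leaves the
    energy finite and unchanged."""
    model = build_peptide("AA", (-57.0, -47.0), library)
    atoms = []
    for a in model:
        atoms.append(dataclasses.replace(a, altloc="A", occupancy=0.5))
        atoms.append(dataclasses.replace(a, altloc="B", occupancy=0.5, xyz=a.xyz + 4.0))
    dup = AtomicModel(atoms)
    top = build_mm_topology(dup, library)
    e_far = les_energy_grad(dup, top)[0].total

    atoms = []
    for a in model:
        atoms.append(dataclasses.replace(a, altloc="A", occupancy=0.5))
        atoms.append(
            dataclasses.replace(a, altloc="B", occupancy=0.5, xyz=a.xyz + 0.05)
        )
    overlapping = AtomicModel(atoms)
    e_near = les_energy_grad(overlapping, build_mm_topology(overlapping, library))[0].total
    assert np.isfinite(e_near)
    assert e_near == pytest.approx(e_far, abs=1e-9)


def test_les_weights_must_sum_to_one(library):
    model = build_peptide("AAA", (-57.0, -47.0), library)
    dup = _with_altloc_copy(model, 2, SIDE_CHAIN, shift=0.3)
    top = build_mm_topology(dup, library)
    top.les_groups[0]["weights"] = {"A": 0.5, "B": 0.4}
    with pytest.raises(ValueError, match="sum"):
        les_energy_grad(dup, top)


def test_les_requires_groups(library):
    model = build_peptide("AA", (-57.0, -47.0), library)
    top = build_mm_topology(model, library)
    with pytest.raises(ValueError, match="no LES"):
        les_energy_grad(model, top)
    dup = _with_altloc_copy(model, 2, SIDE_CHAIN, shift=0.3)
    with pytest.raises(ValueError, match="use les"):
        mm_energy_grad(dup, build_mm_topology(dup, library))


def test_minimization_preserves_helix_hydrogen_bonds(library, helix12):
    """The force field rewards backbone hydrogen bonds: minimizing an ideal
    helix must not lose any over 200 steps."""
    from refmm import minimize_coords
    from refmm.mm import energy_grad
    from refmm.validate import hbond_fraction

    model, _ = helix12
    top = build_mm_topology(model, library)

    def count_backbone(m):
        bonds, _ = hbond_fraction(m, library)
        return sum(
            1 for d, h, a in bonds
            if m.atoms[d].name == "N" and m.atoms[a].name == "O"
        )

    n0 = count_backbone(model)
    def fn(xyz):
        rep, g = energy_grad(model.with_coords(xyz), top)
        return rep.total, g

    out, _ = minimize_coords(model, fn, step_budget=200)
    assert count_backbone(out) >= n0
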