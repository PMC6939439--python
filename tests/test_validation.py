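"""Validation metrics: C-beta deviation, clashscore, hydrogen bonds."""

import dataclasses

import numpy as np
import pytest

from refmm import (
    AtomicModel,
    build_peptide,
    cbeta_deviation,
    cbeta_deviations,
    clashscore,
    hbond_fraction,
    validation_report,
)
from refmm.model import Atom
from refmm.validate import CBETA_OUTLIER_THRESHOLD, ideal_cbeta_position


def _res_map(model, seq):
    return {a.name: a.xyz for a in model if a.res_seq == seq}


def test_ideal_residues_score_zero(library, helix12):
    model, _ = helix12
    devs = cbeta_deviations(model, library)
    assert len(devs) == 12
    assert max(devs.values()) < 1e-6


def test_glycine_has_no_cbeta_deviation(library):
    model = build_peptide("AGA", (-57.0, -47.0), library)
    assert cbeta_deviation(_res_map(model, 2), library, "GLY") is None
    devs = cbeta_deviations(model, library)
    assert ("A", 2, "") not in devs


def test_missing_backbone_atom_gives_absent(library):
    assert cbeta_deviation({"N": np.zeros(3), "CA": np.ones(3)}, library, "ALA") is None


def test_displaced_cbeta_measures_displacement(library):
    model = build_peptide("AAA", (-57.0, -47.0), library)
    res = _res_map(model, 2)
    ideal = ideal_cbeta_position(res["N"], res["CA"], res["C"], library, "ALA")
    # displace perpendicular to the CA-CB direction
    v = res["CB"] - res["CA"]
    perp = np.cross(v, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    res["CB"] = ideal + 0.30 * perp
    d = cbeta_deviation(res, library, "ALA")
    assert d == pytest.approx(0.30, abs=1e-9)
    assert d >= CBETA_OUTLIER_THRESHOLD


def test_outlier_threshold_is_a_step(library, helix12):
    model, _ = helix12
    for delta, expected in ((0.249, 0), (0.251, 1)):
        atoms = []
        for a in model:
            if a.res_seq == 6 and a.name == "CB":
                res = _res_map(model, 6)
                ideal = ideal_cbeta_position(res["N"], res["CA"], res["C"], library, "ALA")
                v = np.cross(res["CB"] - res["CA"], [0.0, 0.0, 1.0])
                v /= np.linalg.norm(v)
                atoms.append(dataclasses.replace(a, xyz=ideal + delta * v))
            else:
                atoms.append(a)
        report = validation_report(AtomicModel(atoms), library)
        assert report.cbeta_outliers == expected, delta


def test_cbeta_deviation_rigid_body_invariant(library):
    model = build_peptide("ATA", (-57.0, -47.0), library)
    res = _res_map(model, 2)
    d0 = cbeta_deviation(res, library, "THR")
    th = 1.1
    rot = np.array(
        [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
    )
    moved = {k: rot @ v + np.array([4.0, -2.0, 7.0]) for k, v in res.items()}
    d1 = cbeta_deviation(moved, library, "THR")
    assert d1 == pytest.approx(d0, abs=1e-9)


def test_ideal_angles_score_zero_even_if_misplaced(library):
    """A residue with an ideal tetrahedron about CA scores zero wherever it
    sits in space."""
    model = build_peptide("AAA", (-57.0, -47.0), library)
    res = _res_map(model, 2)
    moved = {k: v * 1.0 + np.array([20.0, 15.0, -8.0]) for k, v in res.items()}
    assert cbeta_deviation(moved, library, "ALA") < 1e-6


# --- clashscore ------------------------------------------------------------

def _two_atoms(d, bonded=False):
    atoms = [
        Atom("CA", "C", "A", "GLY", 1, "", 1.0, 10.0, np.zeros(3)),
        Atom("CA", "C", "A", "GLY", 2 - int(bonded), "", 1.0, 10.0, np.array([d, 0.0, 0.0])),
    ]
    if bonded:
        atoms[1] = dataclasses.replace(atoms[1], name="C")
    return AtomicModel(atoms)


def test_two_carbon_clash_construction(library):
    # overlap = 1.70 + 1.70 - 2.9 = 0.50 >= 0.4 -> one clash in two atoms
    clashes, score = clashscore(_two_atoms(2.9), library)
    assert len(clashes) == 1
    assert score == pytest.approx(500.0)


def test_below_threshold_overlap_is_not_a_clash(library):
    clashes, score = clashscore(_two_atoms(3.1), library)
    assert clashes == [] and score == 0.0


def test_bonded_pair_excluded(library):
    clashes, score = clashscore(_two_atoms(1.5, bonded=True), library)
    assert clashes == [] and score == 0.0


def test_ideal_helix_clashscore_zero(library, helix12):
    model, _ = helix12
    assert clashscore(model, library)[1] == 0.0


def test_clashscore_invariant_to_atom_order_and_chain_name(library):
    model = build_peptide("AAAA", (-57.0, -47.0), library)
    squeezed = model.with_coords(model.coords * 0.93)  # create some clashes
    s1 = clashscore(squeezed, library)[1]
    renamed = AtomicModel(
        [dataclasses.replace(a, chain="Z") for a in reversed(squeezed.atoms)]
    )
    s2 = clashscore(renamed, library)[1]
    assert s1 > 0
    assert s2 == pytest.approx(s1)


def test_cross_altloc_pairs_not_clashes(library):
    model = build_peptide("AAA", (-57.0, -47.0), library)
    atoms = []
    for a in model:
        if a.res_seq == 2 and a.name in ("CB", "HB1", "HB2", "HB3"):
            atoms.append(dataclasses.replace(a, altloc="A", occupancy=0.5))
            atoms.append(
                dataclasses.replace(a, altloc="B", occupancy=0.5, xyz=a.xyz + 0.1)
            )
        else:
            atoms.append(a)
    clashes, _ = clashscore(AtomicModel(atoms), library)
    mdl = AtomicModel(atoms)
    for i, j, _ in clashes:
        assert not (
            mdl.atoms[i].altloc and mdl.atoms[j].altloc
            and mdl.atoms[i].altloc != mdl.atoms[j].altloc
        )


# --- hydrogen bonds --------------------------------------------------------

def _water(offset, seq, donor_toward_origin=False):
    """Water with both O-H bonds perpendicular to x, or (for the donor) one
    O-H pointing along -x toward the origin."""
    o = np.array(offset, float)
    if donor_toward_origin:
        h1 = o + [-0.9572, 0.0, 0.0]
    else:
        h1 = o + [0.0, 0.9572, 0.0]
    h2 = o + [0.24, -0.23, 0.927]
    return [
        Atom("O", "O", "W", "HOH", seq, "", 1.0, 10.0, o),
        Atom("H1", "H", "W", "HOH", seq, "", 1.0, 10.0, h1),
        Atom("H2", "H", "W", "HOH", seq, "", 1.0, 10.0, h2),
    ]


def test_water_pair_hydrogen_bond(library):
    # O...O 2.8 A with one aligned O-H donor
    model = AtomicModel(_water((0, 0, 0), 1) + _water((2.8, 0, 0), 2, donor_toward_origin=True))
    bonds, rate = hbond_fraction(model, library)
    assert len(bonds) == 1
    assert rate == pytest.approx(1000.0 / 6.0)


def test_distant_atoms_no_bond(library):
    model = AtomicModel(_water((0, 0, 0), 1) + _water((4.2, 0, 0), 2, donor_toward_origin=True))
    assert hbond_fraction(model, library)[0] == []


def test_helix_backbone_hydrogen_bond_count(library, helix12):
    model, _ = helix12
    bonds, rate = hbond_fraction(model, library)
    backbone = [
        (d, a) for d, h, a in bonds
        if model.atoms[d].name == "N" and model.atoms[a].name == "O"
    ]
    assert len(backbone) == 8  # donors 5..12 to acceptors i-4
    for d, a in backbone:
        assert model.atoms[d].res_seq - model.atoms[a].res_seq == 4


def test_validation_report_identities(library, helix12):
    model, _ = helix12
    report = validation_report(model, library)
    assert report.clashscore == pytest.approx(1000.0 * len(report.clashes) / len(model))
    assert report.cbeta_outliers == sum(
        1 for v in report.cbeta.values() if v >= CBETA_OUTLIER_THRESHOLD
    )
    assert report.hbond_rate == pytest.approx(1000.0 * len(report.hbonds) / len(model))
    import json

    json.dumps(report.as_dict())  # serializable
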