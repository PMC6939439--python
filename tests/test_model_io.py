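"""Model and reflection IO: parsing, round trips, cell math, free sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refmm import (
    Atom,
    AtomicModel,
    Crystal,
    ReflectionSet,
    assign_free_set,
    read_pdb,
    read_reflections,
    write_pdb,
    write_reflections,
)

PDB_ONE_ATOM = (
    "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1\n"
    "ATOM      1  CA  ALA A   1       1.234   5.678   9.012  1.00 20.00           C\n"
    "END\n"
)


def test_read_single_atom_record(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(PDB_ONE_ATOM)
    model, crystal = read_pdb(p)
    assert len(model) == 1
    a = model.atoms[0]
    assert a.name == "CA" and a.element == "C" and a.res_name == "ALA"
    assert np.allclose(a.xyz, [1.234, 5.678, 9.012], atol=1e-3)
    assert a.occupancy == pytest.approx(1.0) and a.b_iso == pytest.approx(20.0)
    assert crystal.volume == pytest.approx(1000.0)


def test_read_altloc_occupancy_bookkeeping(tmp_path):
    text = (
        "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1\n"
        "ATOM      1  CB AALA A   1       1.000   1.000   1.000  0.60 20.00           C\n"
        "ATOM      2  CB BALA A   1       1.300   1.000   1.000  0.40 20.00           C\n"
        "END\n"
    )
    p = tmp_path / "alt.pdb"
    p.write_text(text)
    model, _ = read_pdb(p)
    assert len(model) == 2
    assert sorted(a.altloc for a in model) == ["A", "B"]
    assert sum(a.occupancy for a in model) == pytest.approx(1.0)


def test_altloc_occupancy_sum_invariant():
    mk = lambda alt, occ: Atom("CB", "C", "A", "ALA", 1, alt, occ, 10.0, np.zeros(3))
    with pytest.raises(ValueError, match="occupanc"):
        AtomicModel([mk("A", 0.7), mk("B", 0.7)])


def test_missing_cryst1_flags_absent_crystal(tmp_path):
    p = tmp_path / "nocell.pdb"
    p.write_text(
        "ATOM      1  CA  ALA A   1       1.000   1.000   1.000  1.00 20.00           C\nEND\n"
    )
    model, crystal = read_pdb(p)
    assert len(model) == 1 and crystal is None


def test_malformed_column_names_line_number(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text(
        "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1\n"
        "ATOM      1  CA  ALA A   1       1.000   xxx..   1.000  1.00 20.00           C\n"
    )
    with pytest.raises(ValueError, match="line 2"):
        read_pdb(p)


def test_pdb_round_trip_three_residues(tmp_path, helix12):
    model, crystal = helix12
    sub = AtomicModel([a for a in model if a.res_seq <= 3])
    p = tmp_path / "tri.pdb"
    write_pdb(sub, crystal, p)
    back, cr2 = read_pdb(p)
    assert len(back) == len(sub)
    for a, b in zip(sub, back):
        assert a.key == b.key
        assert np.allclose(a.xyz, b.xyz, atol=1e-3)
        assert a.occupancy == pytest.approx(b.occupancy, abs=1e-2)
        assert a.b_iso == pytest.approx(b.b_iso, abs=1e-2)
    assert cr2.volume == pytest.approx(crystal.volume, rel=1e-4)


def test_pdb_round_trip_preserves_altlocs(tmp_path):
    atoms = [
        Atom("N", "N", "A", "SER", 1, "", 1.0, 10.0, np.array([0.0, 0, 0])),
        Atom("CB", "C", "A", "SER", 1, "A", 0.6, 10.0, np.array([1.5, 0, 0])),
        Atom("CB", "C", "A", "SER", 1, "B", 0.4, 12.0, np.array([1.2, 0.9, 0])),
    ]
    p = tmp_path / "alt.pdb"
    write_pdb(AtomicModel(atoms), Crystal(20, 20, 20), p)
    back, _ = read_pdb(p)
    assert sorted(a.altloc for a in back) == ["", "A", "B"]


def test_write_empty_model_round_trip(tmp_path):
    p = tmp_path / "empty.pdb"
    write_pdb(AtomicModel([]), Crystal(10, 10, 10), p)
    back, _ = read_pdb(p)
    assert len(back) == 0


def test_write_rejects_long_atom_name(tmp_path):
    bad = AtomicModel(
        [Atom("HG211", "H", "A", "THR", 1, "", 1.0, 10.0, np.zeros(3))]
    )
    with pytest.raises(ValueError, match="longer than 4"):
        write_pdb(bad, Crystal(10, 10, 10), tmp_path / "x.pdb")


def test_reflection_round_trip(tmp_path):
    refl = ReflectionSet(
        hkl=[(1, 0, 0), (0, 1, 0), (0, 0, 2)],
        f_obs=[25.0, 12.5, 3.25],
        sigma=[1.0, 0.5, 0.25],
        is_free=[True, False, False],
    )
    p = tmp_path / "r.csv"
    write_reflections(refl, p)
    back = read_reflections(p)
    assert np.array_equal(back.hkl, refl.hkl)
    assert np.allclose(back.f_obs, refl.f_obs)
    assert np.array_equal(back.is_free, refl.is_free)


def test_reflection_row_parsing(tmp_path):
    p = tmp_path / "r.csv"
    p.write_text("h,k,l,f_obs,sigma,free\n1,0,0,25.0,1.0,1\n")
    refl = read_reflections(p)
    assert len(refl) == 1 and refl.is_free[0]


def test_duplicate_hkl_rejected(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text("h,k,l,f_obs,sigma,free\n1,0,0,25.0,1.0,0\n1,0,0,26.0,1.0,0\n")
    with pytest.raises(ValueError, match=r"\[1, 0, 0\]"):
        read_reflections(p)


def test_negative_f_obs_rejected(tmp_path):
    p = tmp_path / "neg.csv"
    p.write_text("h,k,l,f_obs,sigma,free\n1,0,0,-1.0,1.0,0\n")
    with pytest.raises(ValueError, match="negative"):
        read_reflections(p)


# --- cell geometry ---------------------------------------------------------

def test_orthogonalize_cubic():
    cr = Crystal(10, 10, 10)
    assert np.allclose(cr.orthogonalize([0.5, 0.5, 0.5]), [5.0, 5.0, 5.0])


def test_orthogonalize_monoclinic_convention():
    # c = 10, beta = 120 under a||x, b perpendicular: (0,0,1) -> (-5, 0, 8.6603)
    cr = Crystal(7, 8, 10, 90, 120, 90)
    assert np.allclose(cr.orthogonalize([0, 0, 1]), [-5.0, 0.0, 8.66025], atol=1e-4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.floats(5, 50), b=st.floats(5, 50), c=st.floats(5, 50),
    al=st.floats(61, 119), be=st.floats(61, 119), ga=st.floats(61, 119),
    seed=st.integers(0, 1000),
)
def test_frac_orth_mutual_inverse(a, b, c, al, be, ga, seed):
    try:
        cr = Crystal(a, b, c, al, be, ga)
    except ValueError:
        return  # degenerate angle combination
    rng = np.random.default_rng(seed)
    v = rng.uniform(-2, 2, size=(20, 3))
    assert np.allclose(cr.fractionalize(cr.orthogonalize(v)), v, atol=1e-10)


def test_degenerate_cell_rejected():
    with pytest.raises(ValueError):
        Crystal(10, 10, 10, 1.0, 179.0, 90.0)


def test_symmetry_ops_must_close():
    bad_rot = np.diag([1.0, -1.0, 1.0])
    with pytest.raises(ValueError, match="closed|identity"):
        Crystal(10, 10, 10, symmetry_ops=[(bad_rot, np.zeros(3))])


# --- free-set assignment ---------------------------------------------------

def _refl(n):
    hkl = [(h, k, 0) for h in range(40) for k in range(25)][:n]
    return ReflectionSet(hkl, np.ones(n), np.ones(n), np.zeros(n, bool))


def test_free_set_count_and_reproducibility():
    refl = _refl(1000)
    out1 = assign_free_set(refl, 0.05, seed=7)
    out2 = assign_free_set(refl, 0.05, seed=7)
    assert out1.is_free.sum() == 50
    assert np.array_equal(out1.is_free, out2.is_free)


def test_free_fraction_zero():
    assert assign_free_set(_refl(100), 0.0, seed=1).is_free.sum() == 0


def test_free_fraction_one_rejected():
    with pytest.raises(ValueError):
        assign_free_set(_refl(100), 1.0, seed=1)
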