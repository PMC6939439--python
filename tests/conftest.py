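import numpy as np
import pytest

from refmm import (
    RefineConfig,
    ToyCrystalSpec,
    load_library,
    make_toy_crystal,
    perturb_model,
    simulate_fobs,
)


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def helix12():
    """12-residue poly-Ala alpha-helix ground truth in a padded P1 cell."""
    return make_toy_crystal(ToyCrystalSpec("AAAAAAAAAAAA"))


@pytest.fixture(scope="session")
def mixed4():
    """Small mixed-sequence fixture exercising Gly, side-chain O and chirality."""
    return make_toy_crystal(ToyCrystalSpec("GAST", conformation="extended", padding=6.0))


@pytest.fixture(scope="session")
def small_problem():
    """Tiny refinement problem: 4-residue helix, low-resolution noiseless data."""
    truth, crystal = make_toy_crystal(ToyCrystalSpec("AAAA", padding=6.0))
    refl = simulate_fobs(truth, crystal, d_min=2.5, noise_fraction=0.0, seed=11)
    start = perturb_model(truth, 0.15, seed=12)
    return truth, crystal, refl, start


def fd_gradient_max_err(fn, model, n_coords=25, h=1e-5, seed=0):
    """Max relative error of the analytic gradient of fn(model) -> (value,
    grad) against central finite differences on random coordinates."""
    _, grad = fn(model)
    x0 = model.coords
    rng = np.random.default_rng(seed)
    errs = []
    for flat in rng.choice(x0.size, size=min(n_coords, x0.size), replace=False):
        a, c = divmod(int(flat), 3)
        xp = x0.copy()
        xp[a, c] += h
        xm = x0.copy()
        xm[a, c] -= h
        num = (fn(model.with_coords(xp))[0] - fn(model.with_coords(xm))[0]) / (2 * h)
        errs.append(abs(num - grad[a, c]) / max(abs(num), 1e-7))
    return max(errs)
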