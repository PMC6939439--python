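"""Refine a perturbed model with both restraint targets and compare.

A 6-residue helix is perturbed by 0.25 A RMSD and refined for five
macrocycles against noiseless 2.5 A data, once with ideal-geometry
restraints and once with the force-field target.  Both should recover the
structure; the force field additionally scores hydrogen bonds and steric
contacts, at slightly higher R (it is not centered on the data's geometry).
"""

from refmm import (
    RefineConfig,
    ToyCrystalSpec,
    clashscore,
    load_library,
    make_toy_crystal,
    perturb_model,
    refine,
    simulate_fobs,
)

library = load_library()
truth, crystal = make_toy_crystal(ToyCrystalSpec("AAAAAA", padding=6.0))
refl = simulate_fobs(truth, crystal, d_min=2.5, noise_fraction=0.0, seed=7)
start = perturb_model(truth, 0.25, seed=8)
print(f"starting model: {start.rmsd_to(truth):.3f} A RMSD from truth")

for mode in ("geo", "mm"):
    cfg = RefineConfig(restraint_mode=mode, n_macrocycles=5)
    refined, traj = refine(start, crystal, refl, cfg)
    last = traj[-1]
    print(
        f"{mode:>3}: R_work={100 * last.r_work:5.2f}%  R_free={100 * last.r_free:5.2f}%  "
        f"rmsd_to_truth={refined.rmsd_to(truth):.3f} A  "
        f"clashscore={clashscore(refined, library)[1]:.1f}"
    )
# R_work/R_free are the usual crystallographic residuals (%); rmsd_to_truth
# measures how completely the perturbation was undone; clashscore counts
# serious van der Waals overlaps per 1000 atoms (0 = clean structure).
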