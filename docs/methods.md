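# Methods

`refmm` is a miniature reciprocal-space refinement engine.  It minimizes a
combined coordinate target

```
T_xyz = w * T_exp + T_restraints
```

over Cartesian coordinates (occupancies and B factors fixed), where
`T_exp` measures disagreement with observed structure-factor amplitudes and
`T_restraints` is one of two interchangeable chemistry terms: a conventional
ideal-geometry restraint residual ("geo") or a reduced molecular-mechanics
force-field energy ("mm").  This note records the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Experimental target

Structure factors are computed by direct summation,

```
F(h) = sum_sym sum_atoms occ * f(s) * exp(-B s^2) * exp(2 pi i h . x_frac),
```

with 4-Gaussian + constant scattering factors (International Tables 1992
coefficients for H, C, N, O, S; shipped as `data/form_factors.csv` and
checked against the element electron counts at s = 0) and isotropic B
attenuation, `s = sin(theta)/lambda = 1/(2d)`.  There is no FFT path, no
bulk-solvent model and no per-bin scaling: toy cells make O(atoms x
reflections) summation affordable and exact, which keeps the analytic
gradients simple enough to verify against finite differences to 1e-5
relative error.

The experimental residual is amplitude least squares,

```
T_exp = sum_work (f_obs - k |F_calc|)^2 / sum_work f_obs^2,
```

with `k` the closed-form least-squares scale recomputed at every evaluation.
The normalization by `sum f_obs^2` makes the target dimensionless and
invariant to a common rescaling of the data.  Because `k` is optimal, its
coordinate derivative drops out of the gradient (envelope theorem).
Maximum-likelihood targets, with their sigma-A machinery, are deliberately
out of scope; every macrocycle is least squares.  Free-set reflections never
enter the target, the gradients, or the weight.

## Geometry restraint target

Each restraint class contributes `sum ((value - ideal)/sigma)^2`:

* bonds (sigma 0.02 A) and angles (sigma 2 deg), ideal values measured
  per instance from the residue's rebuilt template geometry, with standard
  peptide-link values (C-N 1.329 A, CA-C-N 116.2 deg, C-N-CA 121.7 deg)
  across the link.  The O-C-N link ideal closes 360 deg with the planar
  carbonyl so that template-built models score exactly zero;
* omega torsion restraints (ideal 180 deg, sigma 5 deg, period 1), with the
  deviation wrapped into the period so the residual is continuous across
  +/-180 deg.  C-beta pseudo-torsion restraints are intentionally absent;
* chiral volumes (signed parallelepiped volume at CA, plus CB of Thr/Ile;
  sigma 0.2 A^3), which flip sign for a mirrored side chain;
* planarity groups (sp2 centers merged into rings/guanidinium/amide planes
  plus the peptide plane; sigma 0.02 A), scored as deviations from the
  least-squares plane.  The plane parameters minimize the residual, so the
  gradient treats them as fixed (envelope theorem again);
* a purely repulsive nonbonded term `sum max(0, r_i + r_j - tol - d)^2 /
  sigma_rep^2` over pairs within a 4.5 A screen, sigma_rep 0.2 A, with
  1-2/1-3/1-4, altloc cross-copy and donor-acceptor pairs excluded.  The
  onset tolerance `tol = 0.4 A` matches the serious-overlap threshold of the
  clash metric: the restraint activates exactly where validation would flag
  a clash, and universal close contacts of folded ideal geometry (e.g. the
  carbonyl O(i)...C(i+1) contact at 2.87 A) are not penalized.

## Force-field restraint target

The "mm" term is a reduced Amber-style potential

```
E = sum kb (b-b0)^2 + sum kt (theta-theta0)^2 + sum (V/2)(1 + cos(n phi - gamma))
  + sum eps [(rmin/r)^12 - 2(rmin/r)^6] + sum 332.0637 q_i q_j / r
```

with 1-2/1-3 exclusions, 1-4 scaling (elec 1/1.2, LJ 1/2), improper torsions
holding sp2 centers planar (k 10.5, period 2, phase 180 deg), and a 12 A
nonbonded cutoff with a C1 switching function from 10 A.  There is no Ewald
sum and no solvent: fixtures are padded P1 cells in which periodic images
cannot touch, and symmetry-related contacts are ignored — a documented
limitation relative to a full crystalline force-field evaluation.

Parameterization is intentionally reduced and self-consistent rather than a
reproduction of a production force field:

* nine LJ types (CT, C, CA, N, O, OH, S, HC, H) with standard rmin/epsilon
  values, plus a separate van der Waals *contact* radius column shared by
  the repulsion restraints and the validation metrics;
* fixed point charges from bond-polarity increments, summing exactly to
  each residue's formal charge (Asp/Glu -1, Lys/Arg +1, His neutral delta
  tautomer);
* type-level force constants, but per-instance equilibrium bond/angle values
  taken from the same template ideal-geometry source as the restraints.
  Type-averaged equilibria were tried first and rejected: they place the
  force-field minimum ~0.5-0.7 A away from realistic geometry, which no
  amount of weighting can hide.  A production force field earns the
  equivalent property through careful parameterization; a reduced one has to
  borrow it from the geometry library;
* X-H equilibrium lengths are nuclear in the force field (it models nuclei)
  while the geometry restraints and the template builder default to
  electron-cloud-center positions appropriate for X-ray scattering
  (C-H 0.95, N-H 0.86, O-H 0.84, S-H 1.20 A; `h_mode="nuclear"` switches
  everything to nuclear lengths for neutron-style work).

### Alternate conformers (LES)

Alternate-location groups become locally-enhanced-sampling groups: one group
per chain carrying altloc labels, one copy per label, copy weights from
renormalized occupancies.  Every term is weighted by the product of the copy
weights of the distinct (group, copy) labels it touches; terms linking two
different copies of the same group are dropped entirely, and are removed
*before* geometry evaluation so coincident copies can never produce
degenerate-dihedral NaNs.  Consequences verified by tests: a single copy at
weight 1 is the plain energy; identical duplicated copies at weight 1/2
reproduce the single-copy energy; copies never interact, so a fully
duplicated molecule has an energy independent of the separation between its
copies.  How bonded terms inside a copy should be weighted is not uniquely
determined by the averaging idea; uniform copy-weight scaling is this
package's choice.

## Weighting and macrocycles

Each macrocycle freezes

```
w = scale * ||grad T_restraints|| / ||grad T_exp||
```

and minimizes `T_xyz` with L-BFGS (default 50 iterations per macrocycle,
gradient tolerance 1e-4; ten macrocycles by default, which deliberately may
leave large rearrangements visibly unconverged).  The scale defaults to 0.5
in geo mode and 0.2 in mm mode, the force-field gradients being roughly five
times larger at matched quality.

The gradient norms are estimated at a small seeded shake (0.05 A rms,
deterministic in the run seed) of the macrocycle's starting coordinates
rather than at the coordinates themselves.  Evaluated exactly at a converged
macrocycle the two gradients cancel (`w ||g_x|| = ||g_r||`), so the
recomputed weight would decay geometrically by the scale factor each cycle
and the refinement would slide off the data — observable as R_work climbing
from 2% to 39% over ten macrocycles.  Estimating the norms at a decorrelated
nearby point, as the original gradient-ratio scheme does, yields a stable
curvature-based ratio.

Weight-scale optimization runs one full refinement per candidate scale and
selects by a documented rule: in geo mode, the lowest R_free among
candidates with rmsd_bonds <= 0.02 A and rmsd_angles <= 2.5 deg; in mm mode,
the lowest R_free among candidates with clashscore at or below the grid
median; ties break to the smaller scale, and if every candidate fails the
screen the lowest-R_free candidate is returned flagged.  The criteria
(R factors, geometry r.m.s.d., validation) are conventional; the decision
function is this package's own and the thresholds are configuration.

## Validation metrics

* **C-beta deviation**: an ideal CB is constructed from the actual backbone
  twice — through the N-C-CA-CB and C-N-CA-CB improper dihedrals with the
  residue's template-ideal internal values — the two positions are averaged
  and the CA-CB vector rescaled to the ideal length; the deviation is the
  distance to the modeled CB, with outliers at >= 0.25 A.  Glycine is
  skipped.  Per-residue ideal values come from the same template source as
  everything else, so template-built residues score ~0 by construction, and
  a residue whose angles about CA are ideal scores zero wherever it sits.
* **Clashscore**: nonbonded pairs (excluding 1-2/1-3/1-4, altloc cross-copy
  and plausible donor-acceptor pairs) with van der Waals overlap >= 0.4 A,
  normalized per 1000 atoms.  Contact radii are the shared table values
  (C 1.65-1.75, N 1.55, O 1.52, S 1.80, H 1.00-1.17 A), so scores are
  internally consistent rather than numerically identical to any external
  implementation.
* **Hydrogen bonds**: donor-heavy-to-acceptor distance <= 3.5 A and
  donor-H...acceptor angle >= 135 deg, reported per 1000 atoms; without
  hydrogens the angle criterion is dropped with a logged downgrade.

## Synthetic data and what the tests show

`make_toy_crystal` builds an all-atom peptide from the templates at class
phi/psi values (helix -57/-47, strand -119/113, extended 180/180) in a P1
box padded by >= 6 A per side; `simulate_fobs` computes the Friedel-unique
reflection set to d_min and applies multiplicative Gaussian amplitude noise
(chosen so R at fixed noise fraction is scale-invariant); `perturb_model`
applies a seeded Gaussian kick rescaled to an exact coordinate RMSD.

The headline experiment — 12-residue poly-Ala helix, d_min 2.0 A, noiseless
amplitudes, 0.3 A perturbation, ten macrocycles — recovers the truth to
< 0.05 A with R_work < 5% in geo mode, and holds R_work < 8% with a
clashscore no worse than geo mode's in mm mode.  What this shows is that the
machinery is self-consistent: the data are error-free, the truth sits at the
restraint ideal, there is no solvent, no model incompleteness, and no
experimental noise model.  It says nothing quantitative about behavior on
deposited structures; the deposited-coordinate C-beta checks (PDB entries
1bkr and 1nLs) require the archive files, which must be supplied separately
under `tests/data/deposited/`.

Problem sizes used by the test suite and the acceptance script (12-residue
recovery, 6-residue weight grid at three macrocycles, 5-seed paired
clashscore comparison at small scale) were chosen as the smallest systems
that exercise each property.

## Known limitations

* Least-squares amplitudes only; no maximum likelihood, no bulk solvent, no
  anisotropic ADPs, no occupancy/B refinement.
* Space groups beyond P1 only via explicit operator sidecar files.
* The force field is a reduced scheme: no solvent or Ewald electrostatics,
  generic force constants, increment-based charges.  Paired mm-vs-geo
  comparisons are directional, not quantitative.
* The MM term sees one asymmetric unit; crystal contacts are invisible to
  it (padded fixtures make this exact, real crystals would not be).
* Proline's template has no ring-closure special-casing beyond the bonded
  terms; N-terminal proline keeps a single amide hydrogen.
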