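# Parameter library dialect

The file `src/refmm/data/params.txt` carries residue templates, the reduced
force-field constants, restraint sigmas and peptide-link ideals in one
plain-text format.  `#` starts a comment; blank lines are ignored; fields
are whitespace-separated.

## Grammar

```
file        := { section }
section     := ff-section | geo-section | link-section | residue-section

ff-section  := "[ff]" { ff-record }
ff-record   := "scale14" FLOAT FLOAT                         ; elec, LJ
             | "improper" FLOAT INT FLOAT                    ; k, period, phase(deg)
             | "ljtype" TYPE FLOAT FLOAT FLOAT               ; rmin/2, eps, vdw radius
             | "bondtype" TYPE TYPE FLOAT FLOAT              ; kb, b0
             | "angletype" TYPE TYPE TYPE FLOAT FLOAT        ; ktheta, theta0(deg)
             | "torsiontype" T4 T4 T4 T4 FLOAT INT FLOAT     ; V/2, n, gamma(deg)
T4          := TYPE | "X"                                    ; X = wildcard end atom

geo-section := "[geo]" { geo-record }
geo-record  := "sigma_bond" FLOAT | "sigma_angle" FLOAT | "sigma_torsion" FLOAT
             | "sigma_chirality" FLOAT | "sigma_plane" FLOAT
             | "sigma_repulsion" FLOAT
             | "repulsion_screen" FLOAT | "repulsion_tolerance" FLOAT
             | "ec_bond" ELEM "H" FLOAT          ; electron-cloud X-H length

link-section := "[link" NAME "]" { link-record }
link-record  := "bond" ATOM ATOM FLOAT                       ; C(i)-N(i+1) ideal
              | "angle" ATOM ATOM ATOM FLOAT                 ; link-spanning ideal
              | "torsion" ATOM ATOM ATOM ATOM FLOAT FLOAT INT  ; omega: ideal, sigma, period
              | "plane" { ATOM | "+" ATOM }                  ; "+" = next residue

residue-section := "[residue" NAME "]" { residue-record }
residue-record  := "formal_charge" INT
                 | "root" FLOAT FLOAT FLOAT        ; N-CA, CA-C (A), N-CA-C (deg)
                 | "atom" ATOM ELEM FLOAT TYPE     ; name, element, charge(e), LJ type
                 | "bond" ATOM ATOM
                 | "ic" ATOM ATOM ATOM ATOM FLOAT FLOAT FLOAT
                   ; X r1 r2 r3: |X-r1|(A), angle X-r1-r2 (deg), torsion X-r1-r2-r3 (deg)
                 | "chiral" ATOM ATOM ATOM ATOM FLOAT   ; center, 3 neighbors, volume(A^3)
                 | "plane" ATOM { ATOM }
```

## Semantics

* A residue's ideal Cartesian geometry is rebuilt from `root` (placing N,
  CA, C) followed by the `ic` records in file order; every ideal bond/angle
  value used by the restraints, the force-field equilibria and the C-beta
  construction is *measured* from that rebuilt geometry, so the file is
  internally consistent by construction.
* `ic` lengths for hydrogens are replaced by the `ec_bond` electron-cloud
  values unless the library is loaded with `h_mode="nuclear"`.
* `bondtype`/`angletype` provide force constants; their b0/theta0 columns
  document type averages but the topology builder takes per-instance
  equilibria from the rebuilt template geometry (nuclear X-H lengths).
* `torsiontype` matches the two central types exactly and the end types with
  `X` wildcards, trying both directions.
* The link `plane` record names the peptide-plane atoms; a leading `+` marks
  atoms of the following residue, and `H` falls back to `CD` for proline.

The shipped file is generated by `scripts/make_parameter_library.py`, which
measures topology and ideal geometry from the Chemical Component Dictionary
ideal coordinates bundled with biotite and applies the package's reduced
charge/LJ/force-constant scheme (see docs/methods.md).
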