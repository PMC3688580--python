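# glkit

Tools for quantifying ligand-driven domain closure in two-domain sugar
kinases — written around the ADP-dependent glucokinase of *Thermococcus
litoralis* (TlGK), an archaeal enzyme of the ribokinase superfamily whose
small "lid" domain swings shut over the active site as Mg·ADP and then
D-glucose bind.  The package is for enzymologists and structural biologists
who want to run the complete quantitative argument for such a closure on
their own data: kinetic mechanism first, solution compactness second,
crystallographic geometry third.

Three analysis layers, plus a synthetic-data layer so everything runs and
is testable without downloads:

* **Kinetics** (`kinetics_core`, `kinetics_fit`).  Steady-state bisubstrate
  kinetics: the ordered Bi-Bi rate law
  v = Vmax·A·B/(Kia·Kb + Kb·A + Ka·B + A·B), a numeric King–Altman solver
  for arbitrary enzyme-form graphs (linear solve for the stationary
  enzyme-form distribution), double-reciprocal diagnostics
  (intersecting ⇒ sequential, parallel ⇒ ping-pong), Cleland
  product-inhibition pattern classification, direct Levenberg–Marquardt
  fits and secondary slope/intercept replots yielding Kis and Kii.
* **SAXS** (`saxs`).  Debye profiles I(q) = Σ fᵢfⱼ sin(qr)/(qr) from
  coordinates, radius of gyration by iterated Guinier fit (q·Rg < 1.3),
  by P(r) second moment, and directly from coordinates; P(r) recovery from
  a profile by regularized non-negative indirect Fourier transform.
* **Structure** (`structure`).  PDB/mmCIF loading (gemmi), domain
  partitions, inter-domain mass-center distance, Kabsch-based inter-domain
  rotation angles, and inter-domain interaction inventories (H-bonds,
  cation-π, like-charge repulsive pairs) under explicit geometric criteria.
* **Synthetic data** (`synthetic`).  Velocity datasets on the experimental
  concentration grids, two-rigid-domain bead structures with known hinge
  rotation and separation, and noisy scattering curves — each with its
  ground truth embedded, so every analysis has a generate→analyze→recover
  closure test.

## Worked example

Simulate a full kinetic study (initial-velocity grid plus four
product-inhibition designs) and analyze it:

```sh
glkit simulate --kind velocity --out sim
glkit simulate --kind inhibition --out sim
glkit kinetics --velocity sim/velocity.csv \
    --inhibition sim/inhibition_Q_vs_A.csv --inhibition sim/inhibition_Q_vs_B.csv \
    --inhibition sim/inhibition_P_vs_A.csv --inhibition sim/inhibition_P_vs_B.csv \
    --out report
```

prints

```
line family             intersecting
Ki_A                          8.6000
Km_A                          8.6000
Km_B                        218.5000
Vmax                         67.8000
P_vs_A                  mixed
P_vs_B                  mixed
Q_vs_A                  competitive
Q_vs_B                  mixed
verdict                 ordered sequential
first substrate (A)     A
last product (Q)        Q
```

Read bottom-up, that is the whole mechanistic argument: the reciprocal
line family intersects, so catalysis goes through a ternary complex
(sequential, not ping-pong); product Q (Mg·AMP) is competitive against
substrate A (Mg·ADP) and mixed against everything else, so the nucleotide
binds first and its product leaves last; and the fitted constants recover
the generator's truth — Km 8.6 µM (Mg·ADP), 218.5 µM (D-glucose), Vmax
67.8 µmol·mg⁻¹·min⁻¹ — exactly, because the data are noise-free.

The structural side runs the same way:

```sh
glkit simulate --kind structures --out sim
glkit closure --structure sim/open.pdb --structure sim/closed.pdb \
    --partition sim/partition.cfg --out report
```

```
open.pdb                    Rg=18.27  D=30.00  contacts=0
closed.pdb                  Rg=17.02  D=26.50  contacts=0
open.pdb->closed.pdb                    rotation=12.00 deg
```

The generator built the closed conformer with a 12° hinge rotation and a
30 → 26.5 Å center-of-mass approach; the analysis recovers both, and the
radius of gyration drops as the particle compacts — the same
distance/rotation/Rg triad used to argue domain closure from real apo and
ternary-complex structures.  `glkit saxs` adds the solution view (Guinier
and P(r) radii per curve or model), and each command writes a JSON report
with a config echo for reproducibility.

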