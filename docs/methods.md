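# Methods

glkit quantifies how a two-domain ADP-dependent sugar kinase closes over its
active site, combining three independent lines of evidence: steady-state
bisubstrate kinetics (which enzyme forms exist and in what order substrates
bind), small-angle X-ray scattering (how compact the molecule is in
solution), and crystal-structure geometry (how far the domains move and
which residue contacts form).  This note records the models, the defaults
and why, what the synthetic generators do and do not emulate, and the
numerical choices.

## Kinetic model

The mechanism is represented two ways, which serve as mutual oracles:

* **Closed form.** The forward initial-rate law of the ordered sequential
  Bi-Bi mechanism in Cleland notation,

      v = Vmax·A·B / (Kia·Kb + Kb·A + Ka·B + A·B),

  where A is Mg·ADP (first on), B is D-glucose, Ka and Kb are the Michaelis
  constants and Kia the dissociation constant of A from E·A.  The ping-pong
  law omits the constant Kia·Kb term, which is exactly why its
  double-reciprocal lines are parallel.

* **Enzyme-form graph.** A `KineticScheme` is a strongly connected directed
  graph of enzyme forms; each edge carries a rate constant, optionally
  multiplied by a ligand concentration.  The steady-state velocity follows
  the King–Altman construction implemented as a linear solve: the rate
  matrix with one balance row replaced by Σx = 1 gives the stationary
  distribution, and the velocity is the signed flux through the designated
  chemical step.  The minimal ordered Bi-Bi graph has four states (E, EA,
  the lumped central complex EAB≡EPQ, EQ) and eight rate constants.  The
  map from phenomenological to microscopic constants fixes the free choices
  k5 = k7 = 2·kcat and k4 = k5, which reproduces (Vmax, Ka, Kb, Kia)
  exactly; product rebinding constants come from Ki_P = k5/k6 (P on EQ) and
  Ki_Q = k7/k8 (Q on E).  The two routes agree to ~1e-15 relative over
  random draws; the packaged check requires < 1e-8.

Units are fixed: concentrations in µM, velocities in µmol·mg⁻¹·min⁻¹
(`total_enzyme` is a pure scale factor, 1.0 by default).  No unit inference
is attempted anywhere.

### Product-inhibition patterns

Patterns are classified from simulated double-reciprocal families, 8 points
with 1/[S] evenly spaced over [1/(5·Km_app), 1/(0.2·Km_app)], at four
inhibitor doses scaled automatically so the largest roughly halves the
mid-grid velocity.  The co-substrate sits at its own half-saturating level:
at saturation the uncompetitive/mixed distinction degenerates, so a
non-saturating default is the only safe one.  A replot parameter (slope or
intercept) counts as affected when its fractional change across doses
exceeds 10% **and** an F-test comparing the constrained (shared parameter)
against the free per-level linear model rejects at α = 0.05 — the two-part
rule keeps numerical noise from flipping a verdict either way.  Reciprocal
plots whose relative RMS deviation from a line exceeds 1% raise
`PatternUndefinedError` rather than silently mislabel.  Slope-only →
competitive; intercept-only → uncompetitive; both → mixed; neither → none.

For this mechanism the matrix is: Q competitive against A only, mixed
elsewhere — the classic signature that identifies the nucleotide product as
last-off and the nucleotide substrate as first-on.

### Fitting

`fit_mechanism` is weighted nonlinear least squares (Levenberg–Marquardt via
lmfit) against the chosen rate law, with uniform weights by default and
1/σ weights when a σ column is present.  Auto-initialization is scale-free
and deterministic: Vmax = 1.1·max(v), each Km at the median of its
substrate's levels, Kia = Km_A's initial value.  A seeded 8-point
multi-start runs only on convergence failure, so clean fits are exactly
reproducible.  Standard errors come from the Jacobian.  Designs holding a
substrate at a single level raise `IdentifiabilityError` naming the
unconstrained parameter.

Mechanism discrimination ranks candidates by small-sample AICc with ties
broken toward fewer parameters.  Indeterminacy, however, is judged on the
deviance term n·ln(RSS/n) alone: nested candidates differing by one
parameter show ΔAICc ≥ 2 even on data with no discriminating signal at all
(the penalty term alone), so a ΔAICc threshold cannot express "the data do
not care".  A deviance gap below 2 flags the comparison indeterminate.

The linear route (`fit_linear_inhibition`) fits per-dose reciprocal lines,
then secondary regressions of slopes and intercepts on [I]; Kis and Kii are
the intercept/slope ratios of the affected replots.  Replot linearity is
only assessed for replots the inhibitor actually moves (a flat replot has
no variance to explain); R² < 0.8 marks the single-product, no-dead-end
model untenable.

## SAXS model

Forward scattering uses the Debye sum with q-independent amplitudes
f_i = Z_i.  Below q ≈ 0.3 Å⁻¹ and at the ±0.5 Å tolerance used for
coordinate-Rg comparisons, atomic form-factor decay and the hydration shell
are second-order; both are deliberately out of scope.  The exact double sum
is used up to 1,500 centers (chunked so the (q × pairs) workspace stays
bounded); larger models run through a 0.2 Å pair-distance histogram.  The
two paths agree within 0.1% of I(0) — that agreement is the contract, the
crossover count is an implementation detail.

Guinier fitting is the standard iterated-window procedure: fit ln I against
q² starting from the 15 lowest-q points, re-trim to q·Rg < 1.3, repeat to a
fixed point (≤ 50 rounds).  Profiles whose first point already violates
q_min·Rg < 1.3 are rejected.  Note the 1.3 rule itself carries an intrinsic
~1.8% Rg overestimate for a uniform sphere; the 2% sphere tolerance in the
tests absorbs precisely that, not fit noise.

P(r) comes from coordinates as a weighted pair histogram (default bin
1.0 Å; Rg via the second-moment identity agrees with the coordinate Rg
within a bin).  The indirect transform recovers P(r) from a profile by
non-negative least squares on a quadratic B-spline basis (50 uniform knots,
first and last functions dropped to pin P(0) = P(Dmax) = 0) with a
second-difference smoothness penalty; α is chosen by a discrete L-curve
corner search over 10⁻⁸…10² unless supplied.  Curves that start beyond the
first oscillation or span less than q·Dmax = 2π attach ill-posedness
warnings to the result instead of failing.

## Structure geometry

Coordinates are parsed with gemmi (PDB and mmCIF); one altloc per atom is
kept (highest occupancy by default), waters and heteroatoms are excluded
from all mass centers.  The domain partition is a configuration file of
author-numbered residue ranges naming exactly `large` and `small`; the
shipped glucokinase partition (small = A/44–205) was fixed once from the
domain memberships of the published interaction clusters, since no residue
table is printed anywhere — every inter-domain number therefore depends on
this config, and it is the first thing to revisit if a reproduction looks
off.

Closure metrics:

* **Domain distance** — Euclidean distance of mass-weighted domain centers.
* **Inter-domain rotation** — Kabsch superposition (SVD with a det = +1
  guard) of the alternate conformer onto the reference by large-domain Cα,
  then a second Kabsch on the small-domain Cα of the aligned pair;
  θ = arccos((tr R − 1)/2), with the screw translation along the rotation
  axis reported.  Atoms pair by (chain, author residue number); fewer than
  10 common Cα per domain is an error.  Near θ = 0 the arccos halves the
  available precision, so "zero" means ~1e-6 degrees.
* **Interactions** — hydrogen bonds by the heavy-atom criterion (D–A ≤
  3.5 Å, antecedent–D–A angle ≥ 90°; donor/acceptor tables cover backbone
  plus standard side chains), cation-π by cation-group centroid to ring
  centroid ≤ 6.0 Å within 60° of the ring normal, and like-charge repulsive
  pairs by group centroids ≤ 5.0 Å.  Protonation is taken at face value
  from residue identity.  Only pairs crossing the domain boundary are
  reported, small-domain residue first, in deterministic order.  Group
  centroid conventions (guanidinium = CZ+NH1+NH2+NE, ammonium = NZ,
  phenol ring = six ring carbons, carboxylates = CD/CG+two O) are package
  declarations: the convention behind published distances is rarely stated,
  which is worth a ±0.5 Å of slack when comparing.

## Synthetic data

The velocity generator evaluates the true rate law on the experimental
factorial grids (MgADP 10–1000 µM × glucose 30–1000 µM) and applies
v·(1+σp·ε₁)+σa·ε₂ noise, clipped at zero.  Default truth is the published
constant set (Km 8.6 and 218.5 µM, Vmax 67.8 µmol·mg⁻¹·min⁻¹) with three
explicit stand-ins where no public value exists: Kia = Km_A, Ki_P =
1000 µM, Ki_Q = 500 µM (both inside the experimentally probed dose ranges).
The 2% proportional noise used in recovery tests is likewise a plausible
stand-in, not a claim about the experiment.  What the generator does *not*
emulate: coupled-assay lag, instrument drift, pipetting covariance between
rows, substrate depletion — so passing recovery tests demonstrate estimator
correctness under the stated noise model, not robustness to real assay
pathology.

The structural generator builds two uniform bead spheres (random-in-sphere
sampling, centroids re-centered exactly), an optional straight linker, and
produces the closed conformer by rotating the small domain about its
centroid by the hinge angle and translating it to the closed separation —
so the recovered rotation and distances have exact known truth.  Bead
models are single-residue Cα carbons (Z = 6), which makes them valid input
for every downstream tool including the Cα-pairing rotation analysis.  They
do not emulate side chains, so interaction detection on bead trajectories
counts proximity contacts only.  The deterministic lattice sphere
(`sphere_bead_model`) backs the analytic SAXS checks.

Every generator requires a seed whenever noise is on, routes all randomness
through one `numpy.random.default_rng`, and embeds its full truth in the
output metadata/manifest.

## Problem sizes

Defaults are desk-scale by design: 48-point kinetic grids, ≤ 5,000-bead
Debye sums on 256-point q grids, 50-knot IFT bases, 200-replicate
Monte-Carlo recovery and 100-replicate discrimination checks.  These sizes
make every pipeline stage exact or statistically stable while keeping the
full suite in tens of seconds.

## Known limitations

* Experimental solution scattering for this enzyme is not publicly
  deposited; the experimental Rg series (29.0 → 24.0 Å) is therefore
  covered by an ordering property on synthetic closing models, not
  reproduced numerically.
* The supplementary product-inhibition constants are not public; Ki
  recovery is validated against the generator's stand-ins only.
* Coordinate-based Rg omits the hydration shell, so it is expected to sit
  below solution values; comparisons to published coordinate-derived Rg
  carry ±0.5 Å.
* The rate-law solver covers single-cycle mechanisms with lumped chemistry;
  branched random-order graphs evaluate correctly but the closed-form
  constructor and Haldane bookkeeping target the ordered topology.
* Domain partitions are user/config input; there is no automatic hinge
  detection.
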