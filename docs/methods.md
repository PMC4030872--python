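# Methods

## Scope and units

`mcfold` couples two pieces of machinery: a desk-scale multicanonical
(flat-histogram) sampling engine verified against exact canonical
oracles on toy energy landscapes, and a structural ensemble-analysis
suite for coupled folding and binding of a short disordered ligand on a
rigid receptor, verified against synthetic ensembles with planted ground
truth.  Energies are kcal/mol-equivalent, temperatures kelvin, with
R = 1.987e-3 kcal/(mol K), so one temperature schedule — 700 K seed,
200 K reset, 315 K target ensemble — drives both toy and (in principle)
atomistic backends.

## Multicanonical sampling

A multicanonical run is ordinary constant-temperature dynamics on the
modified energy

    E_mc(E) = E + R T_sim ln P_c(E, T_sim),

where P_c(E, T) is the canonical energy distribution.  Since
P_c = n(E) exp(-E/RT)/Z, this is E_mc = R T_sim ln n(E) + const, and the
stationary energy distribution n(E) exp(-E_mc/R T_sim) is flat:
trajectories random-walk along the energy axis and cross barriers.
Canonical expectations at any target temperature T_tag are recovered by
assigning each sample the log-weight E_mc(E_i)/(R T_sim) - E_i/(R T_tag)
and normalising with log-sum-exp stabilisation.

**Integrator.**  BAOAB-splitting Langevin dynamics with unit masses;
`dt` (default 0.05, 0.01 for the quartic study landscape), `friction`
(default 1.0 /time).  Forces follow the chain rule,
F = -(dE_mc/dE) grad E, with the derivative from the weight polynomial.
The kinetic temperature is measured immediately after the
Ornstein-Uhlenbeck substep, where the discretisation bias is smallest.
An overflow guard (E_hi + 50 R T_sim) aborts loudly on bad weights.
Multi-trajectory runs integrate all walkers as one batch; each walker
consumes noise only from its own seeded generator, so a trajectory is
bit-identical whether it runs alone or inside a batch, and the merged
ensemble is exactly the concatenation of independent runs.

**Weight function.**  ln P_c is a least-squares polynomial (default
degree 8, default 100 bins over the validity range) of the log count
density on occupied histogram bins; empty bins are excluded, never
zero-filled.  Weights are defined up to an additive constant.

**Energy walls.**  Outside [E_lo, E_hi] the weight contributes a
harmonic wall `k_w (E - bound)^2` (default k_w = 0.25 per kcal/mol),
continuous at the bounds.  The wall slope is capped (default 4): beyond
the penetration depth where the harmonic slope reaches the cap the wall
continues linearly.  An uncapped quadratic wall multiplies the already
steep gradient of a quartic landscape and drives a numerical runaway at
practical time steps; the capped wall still confines (exponential
penetration profile) with bounded forces.

**Iterative protocol.**  (1) Canonical seed run at T_seed = 700 K; the
span of histogram bins holding at least `extension_rule` (default 20)
samples defines the initial [E_0, E_high].  (2) Multicanonical runs of
`n_traj` merged trajectories under the current weight, confined by the
walls; the soft walls let trajectories spill slightly below E_lo, and
those bins are de-biased correctly because the wall term is part of the
E_mc actually applied.  (3) Re-estimate ln n(E) = ln P_mc(E) +
E_mc(E)/(R T_sim) on occupied bins, convert to ln P_c at the next
simulation temperature, refit, and extend E_lo down to the lowest
trustworthy bin (E_lo never moves up; E_hi is fixed by the seed).
(4) After the first multicanonical iteration the weight is re-expressed
once at T_reset = 200 K: the density-of-states estimate is temperature
free, and ln P_c at low temperature is the smoother function for a
polynomial to carry.  (5) Stop when the reweighted mean energy at
T_target lies inside [E_lo + d, E_hi - d] (d = 5% of the range) and the
flatness ratio — max/min occupied-bin count over the central 90% of the
range, edges excluded to avoid wall artifacts — is either below
`flatness_threshold` (default 2.0, standard flat-histogram practice) or
has stalled (improvement below 15% over an iteration at unchanged
range).

**Why the stall rule exists.**  The density of states of a
one-dimensional double well is discontinuous at the barrier energy:
below it the two extra turning points contribute (with an integrable
1/sqrt divergence), above it they vanish, and the opening of the second
well adds another singular point.  A global polynomial cannot represent
a discontinuity, so the achievable flatness on such landscapes has a
floor well above 2 (measured ~17-30 on the study double well; the
best-possible polynomial misfit at the singular energies is 1.5-2.6 ln
units).  The iteration converges to that representational fixed point
rather than to the threshold; the stall rule recognises it.  On
landscapes whose ln P_c is polynomial-representable — the 2-D harmonic
well, whose n(E) is constant — the protocol reaches flatness <= 2.0 and
E_mc constant within fit noise, which is the regime the flat-histogram
construction was designed for (many-body energy distributions are
smooth).  None of this limits reweighting accuracy: reweighting corrects
whatever bias the realised histogram carries, exactly, through E_mc.

**Reweighting window.**  The multicanonical ensemble is the flat range
[E_lo, E_hi].  Samples recorded in the wall spill-over region receive
zero weight in `reweight`: their nominal de-biasing factor grows as
exp(wall/RT) and amplifies integrator error without adding information.
Consequently the exact estimand of a reweighted expectation is the
canonical ensemble *restricted to the window*; the quadrature oracles
expose windowed means, probabilities and CDFs for precisely this
comparison.  With a window spanning roughly 300-700 K, the truncation
matters only for target temperatures near the top of the range
(one-dimensional energy distributions are wide; at 315 K the excluded
mass is ~0.2%).

**Standard errors.**  Ensemble expectations carry a block-bootstrap
standard error whose blocks are whole trajectories, respecting both
within-trajectory correlation and the merged multi-run structure.

## Toy landscapes and oracles

* `make_harmonic(dim, k)`: E = (k/2) |x|^2; closed form, E ~
  Gamma(dim/2, RT).
* `make_double_well(a, b)`: E = a (x^2-1)^2 + b x; adaptive-trapezoid
  Boltzmann quadrature on a bracket whose neglected tail mass is
  < 1e-10, refined by doubling until the partition sum is stable to 1e-6
  relative.  The study landscape is a = 1.0, b = 0.2: its barrier
  (1 kcal/mol) lies well inside the energy range trusted by a 700 K
  seed, so well exchange is fast at every protocol stage.  (With a
  higher barrier the 1-D seed — whose mean energy is only ~RT/2 —
  cannot cover the barrier, inter-well mixing throttles, and the premise
  that the seed temperature demolishes the relevant barriers fails.)
* `make_chain_model(n_beads, helix_bias)`: a helix-coil chain described
  by its n_beads - 3 backbone dihedrals (rigid bonds).  Each dihedral
  sees a periodic double well with minima at the helical (+50 deg) and
  extended angles and barrier 2.0; `helix_bias` deepens the helical
  minimum per dihedral; a nearest-neighbour coupling (0.5) rewards
  locally uniform conformations.  The torsion-space form was chosen so
  that an exact transfer-matrix oracle exists (the Boltzmann integral
  factorises over the chain); the oracle doubles its angular grid until
  the mean energy is stable to 1e-6 relative.

## Structure analysis

Region conventions of the pKID/KIX complex (original PDB numbering):
helical regions alphaA 120-131 and alphaB 134-145, analysed span
121-144, orientation vectors CA(124)->CA(128) and CA(134)->CA(141),
phosphoserine marker residue 133.  Chain identities are configuration,
never guessed.

* **RMSD**: Kabsch superposition (proper rotation enforced) on region CA
  atoms, fit and measure on the same atoms; the "raw" variant uses the
  shared receptor-restrained frame with no fitting.  Against a
  multi-model reference the minimum over models is reported.
* **Reaction coordinates**: R_aA, R_aB are CA-centroid displacements
  from reference model 1, no superposition.  The PMF over them is
  -RT ln(count/total) on 1 A bins centred on integers, minimum set to
  zero, unoccupied bins undefined (NaN, not 0).
* **Contacts**: side-chain centre = unweighted mean of side-chain heavy
  atoms (phosphate atoms included for phosphoserine; glycine falls back
  to CA); contact iff distance strictly below 6.5 A; native contacts are
  pairs formed in >= 8 of the 17 reference models; N_nc/N_nnc count
  native/non-native contacts per conformation.
* **Helix assignment**: Kabsch-Sander backbone H-bond energy
  (27.888 kcal/mol A coupling, bond iff < -0.5 kcal/mol) with the amide
  hydrogen rebuilt 1 A from N opposite the bisector of its covalent
  bonds; a residue is helix iff it lies in the span of two consecutive
  i -> i+4 turns (the alpha "H" state only; 3-10 and pi do not count).
  Agreement with an independent DSSP implementation is >= 95% per
  residue on mixed helix/coil ensembles; the residual disagreement sits
  at helix termini, where minimal-helix boundary conventions differ.
* **ASA**: Shrake-Rupley with probe 1.4 A, 960 points per atom
  (Fibonacci point placement), per-element radii C 1.7, N 1.55, O 1.52,
  S 1.8, P 1.8 A; hydrogens excluded; region ASA is summed in the
  context of the whole model, so binding buries interface area.
  Degenerate input: exactly coincident atoms are collapsed to the one
  with the largest radius before the surface calculation.
* **Marker densities**: radial probability density (unit integral over
  r) of the marker CA about its reference position, and a voxel density
  in A^-3 (count/(N * voxel volume)) supporting iso-level queries.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume,
not the physics that produces it: thermodynamic consistency between the
generator and the sampling engine is explicitly out of scope.

Backbones are built residue by residue from ideal geometry (N-CA 1.458,
CA-C 1.525, C-N 1.329 A; helical dihedrals phi = -57, psi = -47; coil
phi ~ U(-150, -60), psi ~ U(90, 180)); side chains are a single CB
pseudo-atom (plus a phosphorus on residue 133, named SEP).  The rigid
receptor is a 48-residue ideal helix; binding-site residues point their
side-chain pseudo-atoms toward the ligand side, all others away, so
planted side-chain placements alone control the contact map.  Planted
pairs assign each ligand residue the site nearest its own axial
position, with sites spaced >= 9 A.

Reference sets are jittered copies (sigma = 0.3 A) of the native
complex; each planted contact is re-placed after jitter at exactly the
contact distance in a controlled number of models, making >=-k-of-n
support counts exact by construction.

Ensembles draw each conformation's pose from the (native, misoriented,
unbound) mixture, default (0.5, 0.3, 0.2).  Bound poses anchor the two
helical regions by Kabsch-fitting their CA atoms onto the reference
(native) or onto the reference with the alphaB frame rotated 180 deg
about an axis through its centroid (misoriented, so I_aB ~ -1 while
R_aB ~ 0); the alphaA target of the misoriented pose is offset 8 A, so
both bound poses pass the (13 A, 7 A) bound filter deterministically
and the unbound pose (displaced 60 A into the receptor-free half-space,
beyond any chain conformation's reach) fails it — which is what makes
the planted bound fraction exact.  The loop (residues 132-133) is
carried rigidly from the reference with the marker CA drawn
N(reference, sigma_m^2), sigma_m = 1 A, in bound poses.  In bound poses
alphaB is always helical (it folds upon binding); helix propensities
(defaults alphaA 0.4, alphaB 0.2, other 0.05, echoing a nascent-helix
unbound state with the N-terminal region roughly twice as helical)
govern the draws otherwise.

Helicity draws are region-cooperative: one uniform variate per region
per conformation, residue helical iff u < h_r.  For a region-interior
residue the helix flag then equals the region draw exactly, so its
expected assigned-helix content is h_r with plain binomial error — an
exact planted truth.  "Interior" excludes two residues at region ends
and four next to the loop break, where the rigidly placed loop can form
chance hydrogen bonds.  The truth record also stores per-conformation
pose labels, realised helicity draws, marker positions, and the exact
contact list from a direct double-loop enumeration (independent of the
analysis path).

What passing these tests shows — and does not.  Recovery of planted
truths demonstrates that the observable implementations measure what
they claim on data with known answers; it does not validate force
fields, real side-chain packing (one pseudo-atom per side chain), loop
continuity at segment breaks, or any thermodynamic statement about real
pKID-KIX ensembles.

## Problem sizes

The shipped test suite and the acceptance script run the double-well
protocol with 6-8 trajectories of 60k-100k steps per iteration
(converging in ~4 iterations), a 5e5-sample production run, a 16 x 20k
vs 1 x 320k merged-trajectory comparison, and 2000-conformation
synthetic ensembles against 17 jittered reference models — sizes at
which every stochastic tolerance in the tests is a 3-sigma band of the
corresponding estimator.

## Known limitations

* The flatness a polynomial weight can reach on 1-D landscapes is
  floored by density-of-states discontinuities at barrier energies (see
  above); flat-histogram quality targets of ~2 apply to the smooth-DOS
  regime.
* E_hi is fixed by the seed run, so reweighting near the seed
  temperature carries window truncation; use the windowed oracles (or a
  hotter seed) when comparing there.
* The PDB layer takes the first altloc, rejects insertion codes, and
  does not read mmCIF.
* `helix_content` on ensembles with chain breaks is only exact for
  residues away from the breaks, as quantified by the generator's
  interior-residue list.
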