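# Methods

## Scope and model

`hydrofold` analyzes snapshot ensembles of a solvated protein in two (or
more) conformational states with a fixed particle inventory.  The energy
model is the classical fixed-charge form: Coulomb `C q_i q_j / r` with
`C = 332.0636 kcal·Å/mol/e²`, plus 12-6 Lennard-Jones with
Lorentz–Berthelot combination, the LJ term multiplied by the CHARMM
energy-switching function between `vdw_switch_on = 9 Å` and
`vdw_cutoff = 11 Å` and zero beyond.  Distances use the minimum-image
convention in an orthorhombic box.

Electrostatics in all decompositions are **direct pairwise sums**
(`direct_all_pairs`, optionally `direct_cutoff`).  Mesh/Ewald methods define
a total energy but not a per-atom or per-pair attribution, and the point of
this package is attribution; the scheme is stored in `EnergyOptions` and in
every report's provenance block.  Consequently absolute totals differ from
what a PME engine would print; differences of attributions between states
are the meaningful outputs.

Every decomposition passes through one kernel, the half-weighted group
energy `E_group = ½ Σ_{i∈G} Σ_{j≠i} E_ij`: singleton groups give per-atom
energies, the full atom set gives the total (the tests assert the
conservation identity at 1e-9 relative tolerance), and contact atom sets
give per-interaction energies.  Pairs internal to a group therefore count
once and pairs with the environment at half weight.  Bonded terms (harmonic
bond `k(b−b0)²`, harmonic angle, periodic dihedral `k(1+cos(nχ−δ))`,
harmonic improper; force constants absorb the conventional ½) exist for
internal-consistency checks; CMAP and Urey–Bradley cross-terms are not
implemented, so absolute bonded totals of CHARMM systems are out of scope.

## Atom classification

Polarity is derived, not declared: an atom is polar iff `|q| ≥ 0.3 e`.  The
absolute value matters — carbonyl oxygens carry ≈ −0.51 e and must land on
the polar side for the partition to separate hydrogen-bonding groups from
aliphatic/aromatic carbons, sulfur, their hydrogens, and the proline
backbone nitrogen.  Donors are N/O atoms with a bonded hydrogen (derived
from the bond graph).  Acceptor status (an available lone pair) cannot be
inferred from connectivity — histidine tautomers are the classic
counterexample — so it is a declared column of the topology format.
Exclusions (1-2, 1-3, 1-4) are derived from the bond graph by breadth-first
walk and classified by shortest path; a brute-force graph-walk oracle checks
this on random molecules.

## Contact detection and persistence

Cutoffs are boundary-inclusive exactly as worded ("or less", "or more") and
the tests probe them at ±1e-3 Å and ±0.1°.  One wording ambiguity had to be
resolved: the water-side angle criterion at an *acceptor* lists the triple
"acceptor, bonded heavy atom, water oxygen", but placing the vertex at the
middle atom makes the criterion unsatisfiable for a carbonyl (the angle at C
between O and a water beyond O is near zero).  The vertex is therefore the
acceptor itself: the angle between acceptor→bonded-heavy and acceptor→water
must be ≥ 90°, i.e. the water approaches on the lone-pair side.  The donor
criterion keeps its written vertex (the hydrogen), matching the direct
hydrogen-bond convention.

Symmetry-equivalent atoms (built-in templates: ASP/GLU carboxylates, ARG
guanidinium N/H, LYS ammonium H, PHE/TYR ring pairs, LEU/VAL methyls,
C-terminal OT1/OT2, water H1/H2) merge into one contact.  Hydrogen-bond and
bridge contacts count once per frame if *any* alternative passes; non-polar
contacts count every simultaneously passing alternative pair, so ring–ring
persistences can exceed 1.  Persistence is the mean count per frame averaged
over replicates (mean ± sample std); "persistent" means strictly greater
than the 0.5 threshold.  Persistent contacts are defined on the native-state
replicates only and then evaluated in both states, so extended-state
sampling can never change the contact list.

Per-frame energy evaluation resolves each symmetric slot to the alternative
minimizing the defining heavy-atom distance.  For multi-hydrogen donors the
hydrogen entering a hydrogen-bond set is the one maximizing the
donor-H-acceptor angle; in a water bridge's four-atom set each donor
contributes its closest hydrogen and each acceptor its closest bonded heavy
atom, deterministic tie-breaks on otherwise equivalent atoms.  The bridging
water is *excluded* from the bridge's energy set: it belongs to the solvent
environment in both states, and including it would make the extended-state
reference ill-defined (there is no bridge there).  When several waters
bridge a pair in a frame, the one minimizing the sum of the two
oxygen–partner distances defines the record; a pair contributes at most one
bridge per frame.

## IFST hydration sites

Clustering (the literature leaves the algorithm open) is greedy density
ranking: count water-oxygen observations within 1.0 Å of each observation,
accept the densest as a site, remove its members, keep centers ≥ 2.4 Å
apart, stop when the best remaining candidate would be occupied in < 50 % of
frames.  The stored center is refined to the member centroid, which for a
Gaussian-confined planted site estimates the true center to well under
0.1 Å (the accepted observation alone is only accurate to the order of the
counting radius).  Sites are retained within 4.1 Å of a protein heavy atom
by default; occupancy = fraction of frames with a water oxygen inside the
1.0 Å site radius, and `n_eff` equals occupancy because a 1 Å site holds at
most one water.

`E_site` is the **full** (not half-weighted) interaction of the site's
water molecule with everything outside it, averaged over occupied frames,
because the bundled bulk references are per-molecule interaction energies in
the same convention; `dE = E_site − n_eff·E_bulk`.  The bulk table (TIP3P at
0–200 mM NaCl, TIP4P-2005 at 0 mM; 300 K) ships as data; each triple is
validated to close `G = E + (−TS)` within 0.15 kcal/mol, the worst case of
three independently rounded one-decimal entries.

The solute–water entropy uses the k-nearest-neighbor estimator in the
product space of minimum-image translation (Å) and rotation
(`d_orient = 2 acos(|q1·q2|)`, radians; the absolute value handles the
quaternion double cover).  Orientation quaternions are defined against a
fixed reference water: oxygen at the origin, H-O-H bisector along +z,
molecular plane xz, H1 at positive x — stated so that observations are
reproducible across readers.  The estimator is

`S_sw = n R [⟨ln(π d⁶ n F / (48 V))⟩ + γ]` with `k = 1`; for `k > 1` the
bias constant γ generalizes to `−ψ(k)`.  The constant 48 = (π³/6)·6/π³·8π²/…
reduces to the statement that the normalization embeds the full SO(3) volume
8π², so the estimator's zero point is a water uniform over the box and over
*all* orientations with both hydrogen images distinct.  Accordingly the
hydrogen-exchange symmetry reduction of the metric
(`water_symmetry_in_orientation`) defaults to **off**: switching it on
shifts the uniform sample by −R ln 2 and breaks the zero point (measured
−0.66 R).  Same-frame neighbors are excluded by default (two waters in one
frame are structurally correlated); duplicate observations (combined squared
distance < 1e-14, the scale set by rounding in the quaternion dot product)
are never used as neighbors and are dropped with a warning rather than
propagating −∞.

Estimator accuracy depends on nearest-neighbor distances staying inside the
curvature scale of the rotation group (ball volumes in SO(3) fall below
Euclidean by ~r²/20).  The calibration default for the uniform generator is
therefore a dense regime — one water per frame, 5000 frames, 2.0 Å box —
where the measured zero point is +0.02 to +0.08 R across seeds (positive
curvature bias plus sampling noise), comfortably inside the 0.1 R
acceptance band; at 2.5 Å boxes the bias grows but remains inside the band.
The volume-halving check keeps the reference volume fixed while halving the
generation box, a fully periodic construction that avoids slab boundary
bias and isolates the `−nR ln 2` shift (measured within 4 % of ln 2).

`dS = S_sw − n_eff·S_bulk` (the water–water term is assigned zero: most
first-shell correlation is already in the solute–water term),
`−T dS = −T·S_sw − n_eff·(−T S_bulk)`, `dG = dE + (−T dS)`; the accounting
identity is stored exactly.  `R = 1.9872e-3 kcal/mol/K`, `T = 300 K`.

## Synthetic data: what it does and does not show

The generators emulate the *statistical structure* of fixed-solute
simulation output, not its thermodynamics — no Monte Carlo or MD
equilibration, no realistic water structure, no conformational ensembles.

* `uniform_box` — rigid waters uniform in position and orientation;
  realizes the estimator's homogeneous zero point and the Poisson
  nearest-neighbor reference.
* `gaussian_sites` — one water per planted site per frame, isotropic
  Gaussian scatter (default σ = 0.25 Å, the scale of a well-ordered
  hydration site), orientation law uniform/fixed/concentrated; closed-form
  translational entropy.
* `two_state_toy` — carbonyl/amide/apolar groups planted in-criteria in the
  compact state and displaced 25 Å along +z in the extended state, same
  topology in both (the fixed-inventory precondition).  Bulk waters are
  identical in both states and kept 12 Å from the solute in *both*
  conformations so their random dipolar fields perturb contact energies by
  well under the planted signals; the apolar probe group carries zero
  partial charges so its planted contact is purely dispersive and
  sign-stable.  Defaults: 12 waters, 3 replicates, 0.03 Å thermal jitter.
* `bernoulli_contacts` — a planted hydrogen-bond unit toggled in/out of
  criteria per frame with probability p, default 40 replicates × 100 frames
  (the study-scale replicate structure for the persistence filter).

Passing tests on these ensembles demonstrate that the detectors, kernels,
estimators, and aggregation are correct; they say nothing about force-field
accuracy or about real villin trajectories, whose per-contact magnitudes are
not reproducible without the original simulations.  The published villin
tables bundled in `hydrofold.villin` are inputs to the aggregation layer's
worked examples, not package output.

## Problem sizes and runtimes

The test suite and the acceptance script run on one CPU in well under a
minute each.  Entropy calibrations use the study's 5000-snapshot sampling;
persistence recovery uses the full 40 × 100 replicate structure (the toy
contact unit has 5 atoms, so detection is cheap); contact/energy pipelines
use 3 replicates × 6–8 frames of the ~50-atom toy system, enough for the
planted signs and identities because the generators are nearly
deterministic by construction.  Site-center recovery uses 1000 frames of
three σ = 0.3 Å sites (expected centroid error ≲ 0.03 Å against the 0.2 Å
tolerance).

## Known limitations

* Direct-sum electrostatics: totals are not comparable to PME totals.
* No CMAP/Urey–Bradley; bonded machinery is for consistency checks only.
* The hydration-site clustering is one defensible convention among several;
  occupancy-0.5 cutoff, 1.0 Å radius, and 2.4 Å separation are tunable.
* `S_ww` is fixed at zero; solute entropy and solute–solvent coupling are
  outside the theory as implemented.
* The KNN entropy estimator inherits a positive curvature bias at sparse
  sampling; users analyzing low-occupancy sites should check convergence
  with the frame count.
* PSF reading is a convenience layer (atoms/charges/bonds only; LJ
  parameters must be supplied per atom type); binary parameter files are
  not parsed.
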