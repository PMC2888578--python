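# Methods

`pepsa` samples the conformations of a short phosphotyrosine (pTyr)
peptide bound to a rigid SH2-domain-like scaffold by restrained
simulated annealing, clusters the resulting replica ensembles, and
analyses fluorescence-polarization (FP) competition titrations.  This
note documents the model, its assumptions, the tunable parameters, the
synthetic-data generator, and the numerical choices.

## The physical model

### Energy function

The potential is a classical extended-atom (heavy-atom-only) molecular
mechanics form:

* **Bonds / angles**: harmonic, `E = k (x − x0)²`.  The force constants
  in the parameter file already contain the conventional factor ½
  (AMBER convention), which matters when comparing spring constants
  across packages.
* **Dihedrals**: Fourier terms `E = (V_n/2)(1 + cos(nφ − γ))`, looked
  up by the central bond's atom-type pair with wildcard outer atoms.
  Amide bonds carry a stiff 2-fold term (V/2 = 10 kcal/mol) that keeps
  peptide planes trans in the absence of improper torsions.
* **Lennard-Jones**: 12-6, with `r*` combined additively
  (Lorentz-Berthelot on minimum-energy distances) and well depths by
  geometric mean.
* **Electrostatics**: Coulomb under a distance-dependent dielectric
  ε = R_ij, i.e. a pair contributes `332.0636 q_i q_j / R_ij²`
  kcal/mol.  This implicit-solvent screening makes charged side chains
  interact too strongly at short range, which is why titratable
  residues are neutralized (below).
* **Cutoff**: hard atom-based truncation of the nonbonded sum at 12 Å.
  No switching function: the discontinuity is irrelevant for
  thermostatted sampling, and conservation tests (below) are run with
  the cutoff beyond the system extent.
* **Exclusions**: 1-2 and 1-3 pairs excluded; 1-4 electrostatics
  divided by 1.2 and 1-4 van der Waals by 2.0.
* **Restraints**: harmonic positional, `E = k |r − r_anchor|²` with
  k = 25 kcal/(mol·Å²) on the phosphotyrosine by default.  Note the
  convention is `k d²`, *not* `½ k d²` — the same as the bond term —
  so restraint energies are twice what a ½-convention code reports.

Atom charges and types come from a plain-text parameter file
(`pepsa/data/minimal.ff`, format documented in its header).  The
shipped set is a *reduced, internally consistent* charge/type set for
the 20 amino acids, phosphotyrosine (PTR, di-anionic phosphate by
default, mono-anionic available), the ACE/NME caps, and the synthetic
scaffold beads.  It is not a published force field; published charges
(e.g. RESP-derived phosphotyrosine parameters) can be dropped in by
replacing the residue blocks, and every consumer reads charges only
from this file.

### Extended-atom representation

Hydrogens are not represented; their steric bulk is absorbed into the
heavy-atom Lennard-Jones radii (e.g. aliphatic carbons use r* = 2.0 Å)
and masses stay elemental.  This halves the particle count, removes
the stiffest oscillators, and lets the toy studies run in minutes.
The cost is that hydrogen bonds appear only as electrostatic contacts
between partial charges, and protonation changes are charge-only
(convenient: neutralizing Asp/Glu/Lys/Arg swaps charge templates
without adding atoms).

### Charge neutralization

Because ε = R screens poorly, all titratable residues are switched to
neutral forms (protonated Asp/Glu, neutral Lys/Arg), *except* the
phosphotyrosine and the phosphate-binding pocket arginines named by
configuration, which keep full charges — these form the salt bridges
that anchor the peptide.  The peptide termini are capped with ACE and
NME, built from ideal amide geometry.

### Mobility classes

Every atom carries one of three labels: **frozen** (the scaffold —
never moved by any integrator or minimizer, and frozen-frozen
interactions are skipped as a constant), **restrained** (the pTyr
anchor and anything N-terminal of it — integrated with a harmonic
tether to its reference position), **free** (the peptide residues
C-terminal to the pTyr, including the NME cap).  Temperature is
defined by equipartition over the 3N degrees of freedom of mobile
(free + restrained) atoms only.

## The annealing protocol

1. **Initial minimization**: 250 steepest-descent steps with adaptive
   step size, then 750 conjugate-gradient steps.  The CG stage is
   scipy's CG on the mobile coordinates; the energy trace is
   monotonically non-increasing within line-search tolerance.
2. **Heating**: staged thermostat ramp, by default three equal stages
   ending at 3000 K (1000 → 2000 → 3000 K).  The thermostat is
   weak-coupling velocity rescaling (Berendsen-style, τ = 0.1 ps,
   rescaling factor clamped to [0.8, 1.25] per step).
3. **Replica generation**: one continuous 3000 K trajectory, sampled
   every `interval` ps (50 replicas at 2.5–10 ps at full scale).  An
   optional selector picks the interval from candidates by maximizing
   `minmax(mean pairwise CA-RMSD) + minmax(mean CA-RMSD to start)`,
   ties to the cheaper interval.  Sampling from one continuous
   trajectory (rather than independent restarts) is an assumption;
   replicas then differ by their stretch of high-temperature dynamics
   and by their cooling seeds.
4. **Cooling**: geometric schedule `T_{i+1} = 0.8 T_i` from 3000 K,
   clamped to end at 300 K — 12 levels.  Each replica runs a
   thermostatted segment of fixed duration at every level (10–500 ps
   per level at full scale; 0.05–1 ps in the desk-scale studies).
   Replicas are strictly independent: per-replica seeds are derived
   from (master seed, replica index), and results are invariant to
   processing order.
5. **Quench**: 200 SD + 600 CG minimization of every cooled replica.

Integration is velocity Verlet with dt = 1 fs below 1000 K and 0.5 fs
at and above (the high-temperature override keeps the stiffest bond
periods ≳ 40 timesteps at 3000 K).  No bond constraints are used.  A
guard trips on per-step displacements > 2 Å or non-finite energies; a
replica that trips it is flagged failed and excluded from statistics
without affecting the others.

**Energy conservation** is verified in NVE as *secular drift*: the
difference between the mean total energy in the first and last quarter
of a 10 ps run, relative to the mean.  Velocity Verlet also shows a
bounded energy oscillation of order (ωdt)² that is not drift and is
asserted separately (and shown to shrink ~4× when dt halves).

## Conformational analysis

* **Superposition** is closed-form least-squares (SVD with reflection
  guard); the test suite cross-checks it against an independent
  quaternion implementation.
* **CA-RMSD** defaults to *fixed-frame* (no re-superposition): because
  the scaffold is frozen, all replicas of one complex share its frame,
  and deviations "from the starting model" are directly comparable.
  Comparisons against built ideal references, which carry no frame,
  superpose over the compared CA set.
* **Pairwise-RMSD clustering** is average-linkage agglomeration with
  an automatic cut: every dendrogram level is scored with
  `minmax(average intra-cluster spread) + minmax(cluster count)` and
  the minimum wins (ties to fewer clusters; the all-singleton level is
  excluded unless forced).  A brute-force enumeration over all levels
  serves as the test oracle.
* **Joint RMSD-energy clustering** operationalizes "examine the joint
  distribution" as DBSCAN on the z-scored (RMSD, energy) plane
  (defaults: ε = 0.7, 3 minimum members), noise reported as "other".
  Standardization makes the result invariant to affine rescaling of
  either axis.
* **Representatives** are the member closest to the coordinate-wise
  mean structure (ties → lowest energy, then lowest id).
* **Labels**: clusters are named for the nearest reference
  conformation (extended φ/ψ = (−120°, 120°); ideal helix (−57°, −47°);
  type-I β-turn) when the representative's segment CA-RMSD is within
  2.5 Å, else "other".  The threshold is an artifact choice; reported
  cluster-to-reference RMSDs do not depend on it.

## Binding-affinity analysis

Competition FP titrations are reduced to inhibition percentages
`IP = 100 (FP₀ − FP)/(FP₀ − FP_b)` (blank FP₀: domain + probe;
background FP_b: probe alone).  IP is not clamped; noisy points may
fall slightly outside [0, 100].

The dose-response fit anchors the asymptotes at 0 and 100 — they are
known by construction, since the controls *define* the IP scale — and
floats the midpoint and Hill slope (the full free-asymptote 4PL is
available via `anchor_asymptotes=False`).  This matters: with free
asymptotes, the IC50 noise floor on an 8-11 point grid at 5% read
noise is a ~20-25% median error; anchored, ~8%.  The IC50 is the
concentration where the *fitted* curve crosses IP = 50, confidence
intervals come from a seeded residual bootstrap (default 1000
resamples), and a warning is raised when the measured IPs never
straddle 50% (the IC50 is then an extrapolation).

Free energies use the molar reference state,
`ΔG = RT ln(IC50 / 1 M)` at T = 298.15 K, reported in kJ/mol, and
`ΔΔG = RT ln(IC50_b / IC50_a)` (positive = b binds more weakly).  This
reconstruction reproduces 7 of the 8 published table entries it is
checked against to ±0.1 kJ/mol; the remaining entry (0.8 µM → −34.8
computed vs −35.2 printed) is internally inconsistent in the source
table and is deliberately *not* matched.

## The synthetic two-basin complex

`make_toy_complex` builds every input the pipeline needs with no
external files: a capped PTR-Glu-Glu-Ile peptide in an extended start
pose, plus a rigid scaffold of single-bead pseudo-residues —

* two cationic anchor beads (+1 e) placed 2.9 Å off the phosphate
  oxygens (the pocket-arginine analogue; they keep their charge
  through neutralization),
* four apolar pocket beads forming a cup around the Ile side-chain tip
  of the extended pose (bead r* = 1.7 Å keeps the pocket short-ranged
  and geometrically selective), and
* two weak polar shelf beads (−0.3 e) near the C-terminus of a
  compact pose built by driving the free segment's φ/ψ to (−60°, −40°)
  while the restrained anchor stays exactly in place.

The landscape has two designed basins.  Their reaction coordinate is
the **pocket engagement energy** — the peptide–pocket-bead LJ sum —
and the basin label is `pocket` when engagement < −1 kcal/mol, else
`compact`.  The pocket well depth (ε of the bead type, default
4 kcal/mol per bead) is the design dial: at depth 0 the beads are
ghosts, low-temperature quenches from *both* designed starts relax
into the compact basin, and engagement is identically zero; at the
default depth the extended start quenches into a deeply engaged pose
(engagement ≈ −8 kcal/mol).  The default well sits mid-way through the
series range below, where both basins carry weight at the study's
time scales — that is what gives the cooling-rate sweep its dynamic
range.  Basin floors are probed by
a best-of-5 seeded quench (tethered minimization toward the designed
start, 0.2 ps at 150 K, free minimization), because a single
minimization path on this rugged landscape is a noisy estimator.

The pTyr+3 hydrophobic series (Ile → Leu → Val → Ala → Gly) is
represented by scaling the pocket depth with the buried side-chain
size (6.0 / 5.2 / 4.0 / 1.5 / 0.5 kcal/mol); glycine, with no side
chain to insert, gets a near-zero well whose residual value stands for
backbone-pocket contact.  Building the
actual mutants (which `mutate_residue` fully supports, and the CLI
build path exercises) does not reproduce the occupancy ordering at
this system size — a 55-atom complex has no helical-propensity
physics, and the deep pocket attracts backbone atoms of every mutant
indiscriminately — so the series analogue dials the designed
interaction instead.  What the series study shows is therefore that
*the sampler resolves graded pocket strength into graded occupancy*,
not that the force field predicts mutant conformational preferences.

### What the toy does and does not emulate

It preserves the protocol structure (minimize → heat → sample → cool →
quench), the restraint/freeze scheme, a competition between an
anchored electrostatic site and a hydrophobic pocket, and a two-state
conformational equilibrium with a tunable gap.  It does not emulate:
real SH2 electrostatic surfaces, helical propensity (no explicit
backbone H-bond donors), solvent entropy, or the published populations
themselves — those need the real structures, a published all-atom force
field and ~5.5 ns × 50 replicas per peptide.  Tests passing on the toy
validate the machinery and the qualitative landscape physics, not
quantitative predictions for real complexes.

## Study sizes and defaults

Desk-scale studies use 8 replicas per seed-batch, heating 3 × 0.3 ps,
sampling every 0.25 ps, and cooling durations {0.02, 0.2, 1.0} ps per
level as the analogues of the 10/50/500 ps full-scale rates; the
cooling-rate study aggregates 6 batches and the series study 5
batches.  These sizes resolve the occupancy trends at ~2 binomial
standard errors while a full sweep stays in the minutes range on one
core.  The full-scale protocol (50 replicas, 2.5–10 ps sampling,
10–500 ps levels) is available as `FULL_PROTOCOL` unchanged.

## Numerical choices and degenerate inputs

* Force evaluation has two backends — a numba-compiled kernel (default)
  and a vectorized numpy path — asserted to agree to 1e-9.
* Minimization from a non-finite configuration is rejected; zero-step
  specs pass coordinates through unchanged.
* `build_schedule` requires 0 < x < 1 and T0 > T_final; an empty
  schedule with zero duration reduces annealing to the quench.
* Distance matrices for clustering must be symmetric with zero
  diagonal; a single structure is its own cluster.
* Degenerate FP controls (FP₀ = FP_b) are an error; titrations need at
  least five distinct non-zero concentrations.
* All stochastic components (velocity draws, replica seeds, titration
  noise, bootstrap) flow from explicit integer seeds; reruns are
  bit-identical.

## Known limitations

* The reduced parameter set has no improper torsions (sp² planarity is
  maintained by angles and the stiff amide dihedral only) and generic
  wildcard angle terms; it is adequate for sampling studies, not for
  quantitative energetics of real proteins.
* Hard cutoff truncation injects small energy jumps when pairs cross
  12 Å; thermostatted sampling is insensitive, but NVE work should
  raise the cutoff beyond the system extent.
* The scaled-down studies inherit sampling noise; their assertions are
  ordering/trend statements at ~2 standard errors, not population
  values.
* PDB I/O ignores alternate locations, occupancies and crystal
  symmetry by design.
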