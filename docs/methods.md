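# Methods

This note documents the models implemented in `liddock`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions a user should know before trusting a number.

## Structure model

Coordinates are in Å. Residues carry author (PDB) numbering, 1-based, with
inclusive ranges everywhere a range is accepted. The PDB reader keeps the
blank/'A' alternate location and the first MODEL unless another is
requested; insertion codes participate in residue identity. Hydrogens are
optional throughout: each analysis that needs them documents a heavy-atom
fallback (see hydrogen bonds below).

Every atom is assigned one hydrogen-bond class — donor, acceptor, both, or
nonpolar — by a deterministic lookup on (residue name, atom name) with an
element-rule fallback. The table ships as editable package data
(`data/atom_classes.yaml`) and includes phosphoserine (SEP) and the acetyl
cap (ACE) as first-class residues, since phosphorylated and capped lid
variants are the motivating use case. Unknown names warn and default to the
element rule by default; `strict=True` raises instead, listing offenders.
NMR and crystal files vary too much in naming for an abort-by-default
policy to be practical.

Superposition is least-squares rigid (Kabsch via quaternion alignment),
proper rotations only.

## Docking energy model

The composite energy of an anchored-lid pose is

```
E = E_torsion + E_vdw(soft) + E_elec(soft) + E_desolv
```

with intramolecular lid terms (torsions plus nonbonded with 1-2/1-3
exclusions, 1-4 scaled by 0.5 vdW / 1/1.2 electrostatic) and all
lid-receptor cross pairs. Units: kcal/mol; the electrostatic constant is
332.06371 kcal·Å/(mol·e²).

- **Torsions**: E(φ) = ½·V·(1 − cos n(φ − φ₀)); zero at the phase minimum.
- **Soft core** (single softness parameter α, default 0.5, applied to both
  dispersion-repulsion and electrostatics):
  E_vdw = 4ε[σ¹²/(ασ⁶ + r⁶)² − σ⁶/(ασ⁶ + r⁶)];
  the Coulomb denominator replaces r by √(ασ² + r²). Both reduce exactly
  to the 12-6 and Coulomb forms at α = 0 and are finite at r = 0 for
  α > 0. The literature motivates the concept (numerical stability of
  sampling through clashes) without fixing parameters; α is therefore
  config-exposed with the default documented here, not presented as a
  published value.
- **Electrostatic screening**: distance-dependent dielectric ε(r) = 4r by
  default (the common docking choice); a constant-dielectric model is
  selectable. These differ deliberately from the MM-GB/SA dielectrics
  below, which model a different physical regime.
- **Desolvation**: a pairwise Gaussian-envelope sum over atom classes,
  w_i·w_j·exp(−r²/2σ_s²) with σ_s = 3.5 Å and per-class weights
  (donor 0.30, acceptor 0.30, both 0.40, nonpolar −0.05). The weights are
  package defaults in the spirit of atomic-solvation-parameter models; no
  published weight set is reproduced.

Per-atom Lennard-Jones parameters are simplified per-class values carried
on the atoms themselves, not a full force-field file; full force-field
fidelity is explicitly not promised. Breakdown objects assert
total = Σ components to 1e-9 on every construction.

## Replica-exchange search

The lid is anchored at one atom: that atom's position is *exactly* invariant
under every move (the acceptance tests assert bit-identity). Sampled
variables are the orientation quaternion about the anchor and the rotatable
torsions; bond lengths and angles never change (torsion-space moves only).
Temperatures are spaced arithmetically ("uniform" spacing; a geometric
option exists), default ladder 300–5300 K. Defaults follow the documented
protocol where one exists (100 swap attempts per cycle, 1,000 replicas
supported though tests use ≤ 16); move amplitudes are package choices
(4° rotation, 10° torsion) because the source protocol calls them free
parameters. With `scale_steps_with_temperature` (default on) amplitudes
grow as √(T/T_min) capped at π, so hot replicas explore globally while cold
replicas refine — without this, mixing across a 5000 K ladder is
impractically slow at fixed small steps.

Proposals are symmetric (uniform increments); out-of-box proposals are
rejected before the Metropolis test. Swap acceptance is
min(1, exp(Δβ·ΔE)); configurations exchange, temperatures stay. Exact
transition-matrix constructors for small discrete state spaces
(`metropolis_kernel_matrix`, `remc_kernel_matrix`) let the tests verify the
stationary distribution against the Boltzmann product to 1e-10 rather than
relying on stochastic checks alone.

Rotamer optimization is the iterative single-residue argmin procedure:
passes over the listed residues continue until one pass changes no
assignment (or a pass cap is hit, reported). On two coupled residues the
result is verified against exhaustive enumeration of the rotamer product
space. The bundled χ-angle sets are a coarse gauche−/gauche+/trans library
in the spirit of curated rotamer libraries; the original penultimate
library is not redistributed.

One ambiguity is worth recording: the source material anchors the lid at
residue 25's Cα but is inconsistent about that residue's identity, so the
anchor is specified by sequence id and atom name only, never by residue
type.

## Conformational similarity and clustering

For atom *i* of conformation A against all atoms *j* of conformation B:

```
D_i(A|B) = Σ_j g(d_ij) · c(class_i, class_j)
g(d)     = exp(−d²/2σ²) for d ≤ cutoff, 0 beyond
```

σ is fixed by g(cutoff) = proximity_threshold; defaults cutoff 2.5 Å,
threshold 0.1. The compatibility table has unit diagonal and
donor–acceptor = 0 as hard constraints; the entries left open by the source
are package choices: a dual (both) atom matches either polar role at 1.0,
and nonpolar–polar pairs score 0. The similarity is the continuous Tanimoto
coefficient a·b/(|a|² + |b|² − a·b). Because the original operand pairing
cannot be recovered from the source (its formulas are unrendered), the
default compares the self-descriptor D(A|A) with the cross-descriptor
D(A|B), symmetrized by averaging both directions; a pure cross convention
(D(A|B) vs D(B|A)) is selectable. Identical conformations give exactly 1;
conformations beyond the cutoff everywhere give 0.

Clustering is the two-pass leader algorithm: assign each conformation (in
input order) to the cluster holding its most similar member if that
similarity exceeds the threshold (default 0.85), else found a new cluster;
reorder largest-cluster-first; repeat the pass once. Ties between clusters
keep the earlier-founded cluster, making the procedure order-deterministic.
The founding member of each cluster is its center.

## Binding free energies

**Minimization** uses scipy's truncated-Newton (TNC) with an L-BFGS-B
polish and a post-hoc check that the maximum gradient component is at or
below the 0.1 kcal/mol/Å cutoff; scipy's internal stopping rules do not
expose exactly that criterion, so the report records the measured value.
The output energy never exceeds the input energy; non-convergence within
the step budget returns the best-so-far structure flagged unconverged.

**Knowledge-based score** (six terms, linear in its weights): buried
nonpolar surface (hydrophobic), interface hydrogen-bond count,
intermolecular vdW, screened electrostatics, pairwise desolvation, and an
entropy penalty (rigid-body term plus a per-frozen-rotor increment). The
published weight calibration is external and unprinted, so the shipped
weights are package defaults documented in `DEFAULT_KB_WEIGHTS`;
reproducing published totals for real systems is a non-goal. At infinite
separation every interaction term is zero and the score reduces to the
entropy penalty.

**MM-GB/SA** follows the single-trajectory protocol: each frame's complex
is split into receptor and ligand parts (optionally re-minimized — the
strain this induces is exactly what ΔE_int reports, so either convention
can be inspected), Δ = complex − receptor − ligand for every term, averaged
over frames. Parameters: interior/exterior dielectrics 2/80, residue-based
cutoffs 8 Å (vdW) and 20 Å (electrostatics) — a residue pair is included
iff its minimal inter-residue atom distance is within the cutoff, a
definition stated here because "residue-based cutoff" is not standardized —
surface tension 0.0072 kcal·mol⁻¹·Å⁻², probe 1.4 Å, T = 300 K.

- *GB polar*: pairwise-descreening (HCT-style) effective Born radii with
  Bondi-type intrinsic radii (offset 0.09 Å) and the standard f_GB
  interpolation; a single ion reproduces the Born equation with the
  (1/ε_in − 1/ε_out) prefactor to 1e-6 relative.
- *Nonpolar*: surface tension × SASA, with SASA from a Shrake–Rupley
  quadrature over a deterministic 960-point Fibonacci sphere per atom
  (≈0.1% accuracy on an isolated sphere; validated against the closed form
  and a Monte-Carlo surface-point oracle).
- *Entropy*: mass-weighted central-difference Hessian; rigid-body modes are
  removed by a near-zero eigenvalue threshold (a warning reports any count
  other than 6, or 5 for linear molecules — blind removal of six would
  break the diatomic case); classical harmonic-oscillator vibrational
  entropy S = R(1 + ln k_BT/ħω) per mode, Sackur–Tetrode translation at
  1 atm, classical rigid-rotor rotation. TΔS is reported as a positive
  penalty added to ΔG. Unit conversion: a mass-weighted Hessian eigenvalue
  in kcal·mol⁻¹·Å⁻²·amu⁻¹ is multiplied by exactly 4.184 × 10²⁶ to give
  ω² in s⁻².

## Trajectory and ensemble analyses

- **Hydrogen bonds**: donor–acceptor distance ≤ 3.50 Å AND donor–H–acceptor
  angle ≥ 120.00° (boundary behavior pinned by tests: both comparisons
  inclusive). For heavy-atom-only structures the angle falls back to
  antecedent–donor–acceptor with the same cutoff; an isolated donor is
  judged on distance alone. Occupancy is the exact fraction of analyzed
  frames; no equilibration window is discarded by default (a burn-in is
  configurable by slicing the trajectory).
- **Salt bridges** use the same geometric criteria applied to the charged
  group atoms; same-sign pairs are rejected.
- **Contacts**: residues are in contact when the minimum heavy-atom
  distance is strictly below 4.2 Å; ensemble frequency is the fraction of
  members in contact.
- **ΔASA**: per-residue %ASA normalizes by extended Gly-X-Gly reference
  areas (shipped table); residues outside the table are normalized by
  their own isolated-residue SASA computed on the fly. Positive Δ means
  more exposed, negative more buried.
- **Side-chain movement**: per-residue RMSD over side-chain heavy atoms
  after a backbone superposition; residues above the threshold (default
  2 Å) are reported as movers; residues with no shared side-chain atoms
  are NaN, not errors.
- **RMSF** is computed about the mean structure after optional per-frame
  superposition. Fitting removes ~6 rigid degrees of freedom and therefore
  slightly deflates fluctuations of small systems; planted-amplitude
  recovery tests use trajectories generated in a common frame with the fit
  disabled, which is the exact setting the generator guarantees.
- **Mimicry maps** pair, per receptor residue, the interacting residues of
  two different ligands (e.g. a reference peptide and the lid) using the
  hydrogen-bond and contact criteria; receptor and partner residue numbers
  must be disjoint for the pairing to be unambiguous.

Trajectory input is multi-model PDB or in-memory `Trajectory` objects
(fixed atom set, strictly increasing times in ps). Binary trajectory
formats are intentionally not parsed here.

## Synthetic generators: what they emulate, and what not

All generators are pure functions of their spec (same seed → bit-identical
output; seeds are mandatory fields, never global state).

- **Toy complex**: a rigid "receptor" of n attraction wells (default 3,
  with well depths −4 kcal/mol each) placed at the Lennard-Jones optimum
  distance from evenly spaced atoms of a reference pose of a flexible
  CA-chain lid (default 5 residues, bond 1.5 Å, tetrahedral angles,
  anchored at residue 1). The constructed pose is refined by a
  deterministic multistart local optimization into a true local minimum of
  the full many-body energy and returned as `known_minimum`; it beats
  1,000 uniformly random poses by ≈1 kcal/mol under default parameters.
  The pockets are smooth wells over the package's own nonbonded forms, not
  amino-acid geometry: sufficient to exercise sampling and scoring, and
  nothing more. Passing docking tests on this system demonstrates sampler
  correctness, not force-field realism.
- **Planted trajectories**: per planted pair, the acceptor is placed each
  frame either inside the hydrogen-bond criterion (2.9 Å, collinear) or
  well outside (5.5 Å), so exactly round(occupancy × n_frames) frames
  qualify — planting is by exact frame counts, not Bernoulli draws, so
  recovery tests are exact. Per-residue fluctuation amplitudes a are
  realized as iid Gaussian jitter with per-component σ = a/√3 about the
  base coordinates; planted-pair atoms are exempt from jitter, and frames
  share one coordinate frame (no rigid drift). Real MD has correlated,
  anisotropic motions; the generator makes no attempt at them.
- **Planted conformers**: cluster centers are translates of the base
  conformation separated by `between_separation` (default 20 Å, far beyond
  the descriptor cutoff); members jitter by `within_spread` (default
  0.25 Å). The generator *verifies* the planted structure by exhaustive
  pairwise similarity against the clustering threshold and refuses
  incompatible specs.
- **Harmonic systems**: purely quadratic bond terms at equilibrium
  geometry; atoms carry ε = 0 so no nonbonded terms contaminate the
  spectrum. Analytic mode frequencies (assembled from exact k·ûûᵀ Hessian
  blocks) are stored in metadata and cross-checked against the numerical
  Hessian path to 1e-6 relative.

## Problem sizes and tolerances used in validation

Docking recovery runs 8 replicas × 40 cycles × 100 moves on the default
toy complex against a brute-force grid over 8×4×8 orientations × 6²
torsion values; the sampler must reach the grid optimum within
0.5 kcal/mol (it typically lands below it, the grid being coarse). The
energy-based comparison is used because the toy's pocket permutation
symmetry makes coordinate-RMSD comparisons ill-posed. Exact kernel checks
use 3-state spaces and 2-level ladders (tolerance 1e-10); empirical
sampling checks use 10⁵ steps with 3σ binomial bounds widened by a factor
3 for chain autocorrelation. Planted-parameter recovery uses 200-frame
(occupancy, exact) and 500-frame (RMSF, 5% relative) trajectories. These
sizes were chosen as the smallest that make the corresponding failure modes
visible.

## Known limitations

- The energy model is a simplified per-class parameterization; absolute
  energies are not comparable to published force-field results, and
  reproducing published binding free energies or occupancies of real
  systems is out of scope by design.
- The receptor is rigid during docking except for explicitly
  rotamer-optimized side chains; backbone flexibility is not modeled.
- No periodic boundary conditions, Ewald electrostatics, or
  Poisson–Boltzmann solver.
- mmCIF parsing, protonation-state prediction beyond fixed pH-7 rules, and
  missing-loop rebuilding are not provided.
- The leader-clustering threshold-monotonicity property (more clusters at
  higher thresholds) is asserted on planted sets; pathological orderings
  can in principle violate it for leader-style algorithms.
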