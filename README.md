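# liddock

Tools for studying **pseudo-substrate "lid" autoinhibition** of a receptor
binding cleft — the situation where a protein's own flexible terminal
segment folds back into its ligand-binding site and competes with natural
partners (the textbook case being the N-terminal lid of the MDM2 p53-binding
domain). The package implements, as a reusable and fully tested pipeline:

- **Replica-exchange Monte Carlo (REMC) docking** of a flexible peptide
  anchored at a single Cα-like atom, sampling rigid-body orientation and
  rotatable torsions against a rigid receptor, with a composite energy model
  (torsional + soft-core Lennard-Jones + screened Coulomb + pairwise
  Gaussian desolvation) and self-consistent rotamer optimization of binding
  site side chains;
- **conformational similarity clustering**: per-atom descriptors combining
  hydrogen-bond-class compatibility with Gaussian spatial proximity,
  compared by a continuous Tanimoto coefficient and grouped by a two-pass
  leader algorithm at threshold 0.85;
- **binding free-energy decomposition**: a six-term knowledge-based score
  and an MM-GB/SA decomposition (generalized-Born polar term with
  pairwise-descreening radii, surface-area nonpolar term at
  0.0072 kcal·mol⁻¹·Å⁻², residue-based 8 Å/20 Å cutoffs, normal-mode
  entropy) under the single-trajectory protocol;
- **trajectory and ensemble analyses**: RMSD/RMSF, hydrogen-bond and
  salt-bridge occupancies (3.50 Å / 120° criteria), residue contact maps
  (< 4.2 Å minimum heavy-atom distance), per-residue ΔASA, side-chain
  movement detection, and molecular-mimicry pairing of two ligands against
  a shared receptor;
- a **synthetic-data module** that generates toy receptor–lid complexes,
  trajectories with planted hydrogen-bond occupancies and fluctuation
  amplitudes, conformer sets with planted cluster structure, and harmonic
  systems with closed-form normal modes — so every pipeline stage is
  testable against known ground truth with no downloads.

## The sampling model in brief

Each replica *r* runs Metropolis Monte Carlo at its own temperature *T_r*
on the pose variables (orientation quaternion about the fixed anchor atom,
torsion vector **φ**), accepting a move with probability
min(1, exp(−ΔE / k_B T_r)). After each cycle, adjacent replica pairs
attempt configuration swaps with probability min(1, exp(Δβ·ΔE)),
β = 1/k_B T, which leaves the product of Boltzmann distributions invariant
(verified exactly in the tests by transition-matrix eigenanalysis). The
energy is

E = E_torsion + E_vdw^soft + E_elec^soft + E_desolv,

where the soft-core forms replace r⁶ by ασ⁶ + r⁶ (and r² by ασ² + r² in
the screened Coulomb denominator), removing the singularity at contact so
hot replicas can cross clashes.

## Worked example

Dock the toy lid into its three-pocket receptor and cluster the
low-temperature poses:

```python
from liddock import (make_toy_complex, make_temperature_ladder,
                     run_remc_docking, EnergyParams,
                     cluster_conformations, realize_pose)

receptor, lid, known = make_toy_complex()
ladder = make_temperature_ladder(300.0, 5300.0, 8)
result = run_remc_docking(receptor, lid, EnergyParams(), ladder,
                          cycles=40, moves_per_cycle=100,
                          swaps_per_cycle=20, seed=0)
print(f"best energy      : {result.best_energy:.3f} kcal/mol")
print(f"swap acceptance  : {result.swap_acceptance:.2f}")
poses = [realize_pose(p, lid) for p in result.cold_poses]
clusters = cluster_conformations(lid, poses, threshold=0.85)
print(f"pose clusters    : {len(clusters.clusters)} (sizes {clusters.sizes})")
```

Output:

```
best energy      : -9.336 kcal/mol
swap acceptance  : 0.81
pose clusters    : 4 (sizes [27, 8, 3, 2])
```

The best sampled energy (−9.34 kcal/mol) reaches the planted optimum of the
toy complex (the three pocket wells engaged simultaneously; compare the
brute-force grid optimum of ≈ −9.04 at the tested grid resolution), and the
40 recorded cold-level poses collapse into one dominant conformational
cluster plus a few minor ones — the same kind of summary the pipeline
produces for real receptor–lid ensembles.

A command-line interface mirrors the library for shell use:

```bash
liddock inspect structure.pdb          # chains, residues, H-bond classes
liddock dock --receptor r.pdb --lid l.pdb --out poses.pdb --seed 1
liddock cluster poses.pdb --threshold 0.85
liddock analyze hbonds trajectory.pdb
liddock score --mode gbsa --traj traj.pdb \
    --receptor-range 25-109 --ligand-range 16-24
```

## Layout

```
src/liddock/structure.py    atoms/residues/topology, PDB I/O, superposition
src/liddock/energy.py       composite soft-core docking energy model
src/liddock/remc.py         replica exchange, Metropolis/swap kernels, rotamers
src/liddock/clustering.py   descriptor similarity + two-pass leader clustering
src/liddock/freeenergy.py   minimization, KB score, MM-GB/SA, entropy
src/liddock/analysis.py     RMSD/RMSF, H-bonds, contacts, ASA, mimicry
src/liddock/synthetic.py    seeded toy-system generators with ground truth
src/liddock/cli.py          `liddock` command-line interface
docs/methods.md             model details, parameter choices, limitations
```
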