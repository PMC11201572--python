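# cuasdimer

Trajectory post-analysis for Cu²⁺-bound α-synuclein (AS) dimer ensembles.

α-Synuclein is the 140-residue intrinsically disordered protein whose
oligomerisation drives Parkinson's disease pathology, and Cu²⁺ binding at
three experimentally proposed sites — the N-terminus (Met1/Asp2/Met5),
His50, and the C-terminus (Asp119/Asp121/Asn122/Glu123) — modulates the
primary nucleation of its early dimeric species. Molecular-dynamics studies
of such systems quantify this through a standard battery of per-trajectory
observables. This package implements that battery as a tested, reusable
library for people analysing (or mocking up) two-chain dimer trajectories:

- **Cu²⁺ binding-site occupancy** — the percentage of frames in which any
  Cu²⁺ ion lies within 3.0 Å of a residue's donor atoms (carboxylate O,
  imidazole N, amide O, thioether S, the Met1 backbone amine, the terminal
  carboxylate), with sites classified *strong* (≥ 70 %) or *weak* (< 70 %),
  and per-frame coordination numbers in which water oxygens complete the
  metal shell to four or six.
- **Inter-monomer hydrophobic contact maps** — occurrence fractions of
  Cα–Cα pairs of hydrophobic residues within 10 Å; the map diagonal is the
  in-register, fibril-like pairing of the NAC domains.
- **Hydrogen-bond series** — counts of donor-H → acceptor (O/N) pairs
  across the two chains at 2.4 Å (H-to-acceptor), with a least-squares
  decay test for the loss of the initial cross-β bonding.
- **Water solvation** — mean waters within 3.0 Å of each residue, per
  monomer, normalised to percentages against the maximum over all models
  of a batch.
- **Structural metrics** — Kabsch-superposed Cα RMSD (with a convergence
  detector), per-residue RMSF about the mean structure, and per-residue
  secondary-structure percentages from a minimal Kabsch–Sander (DSSP-type)
  assignment: hydrogen bonds from
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (bond if
  E < −0.5), α-helix on runs of i→i+4 turns, strand on bridge ladders.
- **Conformer populations** — for ensembles of per-conformation energies
  E_i (e.g. 500 conformations from the last 5 ns of a 200 ns / 10 ps run),
  a Metropolis Monte Carlo walk accepts moves between conformations with
  Boltzmann factor e^−(E_j−E_i)/kT (k = 0.0019872 kcal·mol⁻¹·K⁻¹,
  T = 298 K), credits each step's conformer with a visit, and reports
  P_n = N_n/N_total after 10⁶ steps. An exact enumeration oracle
  (P_n ∝ (1/|n|)·Σ_c e^−E_c/kT, the chain's stationary distribution)
  validates the sampler. Energies come from external tables or a built-in
  surrogate score (hydrophobic SASA at 0.00592 kcal·mol⁻¹·Å⁻² plus
  screened Coulomb with ε(r) = 4r).

Because no trajectories of this system are publicly deposited, the package
ships a first-class synthetic generator (`cuasdimer.synthetic`) that emits
two-chain dimer trajectories with *planted, known* signals for every
observable above — Bernoulli Cu-binding indicators, contact occurrences,
helix/strand content, an exponentially decaying hydrogen-bond count, a
water shell — and records the realised per-frame ground truth so that
every analysis can be checked against it exactly. The 24-model study
catalog (4 polymorphs × 3 binding sites × 2 Cu:AS ratios, ids A1–D6) is
built in, and a pipeline runs the full battery over it deterministically.

## Worked example

```python
import numpy as np
from cuasdimer import coordination, energetics, synthetic

# 1. a synthetic 40-residue dimer trajectory with known Cu-binding truth
amap = synthetic.binding_site_map(40)          # full-sequence -> short chain
base = synthetic.build_dimer(n_residues=40, seed=1)
config = synthetic.SyntheticConfig(
    n_residues=40, n_frames=500,
    site_occupancy={("A", amap[2]): 0.85,      # Asp2 site, monomer A
                    ("B", amap[50]): 0.40},    # His50 site, monomer B
    seed=7,
)
traj, truth = synthetic.generate_trajectory(base, config)

# 2. per-residue occupancy and weak/strong classification
profile = coordination.compute_occupancy(traj, cutoff=3.0)
for (chain, res), planted in config.site_occupancy.items():
    pct = profile.percent(chain, res)
    print(f"monomer {chain} residue {res}: occupancy {pct:5.1f}% "
          f"({coordination.classify_binding(pct)}; planted {planted:.2f})")

# 3. Monte Carlo conformer populations vs the exact enumeration oracle
ensembles, _ = synthetic.generate_energy_ensembles(
    n_conformers=4, n_per_conformer=500,
    energy_offsets=[0.0, 0.3, 0.8, 2.0], spread=0.5, seed=11)
estimate = energetics.mc_populations(ensembles, energetics.MCConfig(seed=3))
oracle = energetics.boltzmann_oracle(ensembles)
for cid, p, q in zip(estimate.conformer_ids, estimate.populations, oracle):
    print(f"conformer {cid}: MC population {p:.4f}  exact {q:.4f}")
```

Output:

```
monomer A residue 2: occupancy  85.4% (strong; planted 0.85)
monomer B residue 14: occupancy  42.8% (weak; planted 0.40)
conformer S1: MC population 0.5141  exact 0.5117
conformer S2: MC population 0.3240  exact 0.3255
conformer S3: MC population 0.1440  exact 0.1449
conformer S4: MC population 0.0179  exact 0.0180
```

The occupancy recovered from the coordinates matches the planted Bernoulli
rates (85.4 % vs 0.85, 42.8 % vs 0.40 — within binomial fluctuation over
500 frames), Asp2 classifies as strongly bound and His50 as weakly bound,
and the 10⁶-step Metropolis populations agree with the exact stationary
distribution to a few parts in a thousand.

On a 40-residue chain the full-sequence binding positions are remapped
proportionally (`binding_site_map(40)` sends His50 → residue 14); on
140-residue chains the numbering is the native one.

## Command line

Every analysis is also a subcommand of the `cuasdimer` executable —
`simulate`, `occupancy`, `contacts`, `hbonds`, `solvation`, `ss`, `rmsd`,
`rmsf`, `energy`, `populations`, and `run-all`, which generates and
analyses the whole 24-model catalog into one output directory of TSV
files (deterministic for a fixed `--seed`, byte for byte):

```sh
cuasdimer run-all --outdir results/batch --seed 1
cuasdimer simulate --model-id B5 --outdir sim/
cuasdimer occupancy --topology sim/B5_topology.pdb \
    --trajectory sim/B5_trajectory.dcd --out occ.tsv
```

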