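# Methods

This note records what each component computes, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## System and catalog

The object of study is a two-monomer α-synuclein (AS) dimer with bound
Cu²⁺ and explicit waters. The catalog enumerates 24 models: four dimer
polymorphs (A–D) × three experimentally proposed binding sites
(N-terminus Met1/Asp2/Met5; His50; C-terminus Asp119/Asp121/Asn122/Glu123)
× two Cu:AS stoichiometries (1:2 "low", one Cu per dimer; 1:1 "high", one
Cu per monomer). Model ids encode this as A1–D6: numbers 1–3 are the low
group, 4–6 the high group, and within each triple the number selects the
site. Residue 121 is taken as aspartate, consistent with the canonical AS
sequence. Time bookkeeping follows a 200 ns run saved every 10 ps, whose
final 5 ns window holds 500 conformations; energy/population analyses are
computed per stoichiometry group and the two groups are never pooled,
because their systems differ in atom count and their energies are not on
a common scale.

## Analysis criteria and their defaults

| quantity | criterion | default |
|---|---|---|
| Cu-binding occupancy | Cu to any donor atom of the residue | ≤ 3.0 Å |
| strong vs weak site | occupancy threshold (≥ is strong) | 70 % |
| hydrophobic contact | Cα–Cα of two hydrophobic residues | ≤ 10.0 Å |
| hydrogen bond | donor-H to acceptor O/N | ≤ 2.4 Å |
| water shell | water O to any residue atom | ≤ 3.0 Å |
| MC populations | temperature, steps, k | 298 K, 10⁶, 0.0019872 kcal·mol⁻¹·K⁻¹ |
| SASA term | hydrophobic-area factor | 0.00592 kcal·mol⁻¹·Å⁻² |

All distance comparisons are inclusive (≤), so a pair at exactly the
cutoff counts. Choices that the criteria leave open:

- **"Bound" distance.** Typical Cu²⁺–O/N coordination bonds are
  1.9–2.3 Å; 3.0 Å absorbs thermal fluctuation without reaching the
  second shell. It is exposed as a flag everywhere.
- **70.0 % exactly** classifies as strong, so the two labels partition
  [0, 100] without a gap.
- **Occupancy counts "any donor atom of the residue"** and, at high
  stoichiometry, "any Cu ion"; a full-residue scan (not just the
  constructed site) surfaces binding at further residues such as Glu46,
  Glu61, Asp135 or the C-terminal carboxylate.
- **The 2.4 Å hydrogen-bond cutoff is H-to-acceptor.** 2.4 Å would be
  physically implausible for a donor–acceptor heavy-atom distance. No
  angle term is used, since the criterion is purely a distance.
- **Hydrophobic set**: Ala, Val, Leu, Ile, Met, Phe, Trp, Pro
  (configurable). The contact-map diagonal means equal residue index
  across monomers (in-register pairing).
- **Water position** is its oxygen; waters are detected by residue name
  (HOH/TIP3/WAT/SOL). Solvation normalisation divides by the single
  largest mean count over all residues of all models passed in one call,
  so exactly one residue cell of a batch reads 100 %.

## Structural metrics

RMSD and RMSF use Cα atoms of one monomer at a time, superposed by the
Kabsch algorithm (SVD with a determinant correction, so the rotation is
always proper; fewer than three or collinear points raise a degenerate-
input error). RMSF superposes all frames on frame 0, forms the mean,
re-superposes once on that mean, and measures RMS deviation about the
refined mean. Convergence of an RMSD series is declared at the first
sliding-window mean (default window 25 frames, tolerance 0.5 Å) from
which all later window means stay within the tolerance; the tail must
span at least one full window, so the trivial end of the series cannot
qualify.

Secondary structure is a minimal Kabsch–Sander assignment. Backbone
hydrogen bonds use the electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond
when E < −0.5; donors need an explicit amide H (residues lacking one
cannot donate; residues with missing backbone atoms are assigned coil
with a warning). α-helix (H) is assigned to residues i+1…i+4 of two
consecutive i→i+4 turns; strand (E) to members of parallel or
antiparallel bridges; H takes precedence; everything else — including
3₁₀/π helices and turns — is coil (C), since only the helix/strand
distinction is reported downstream. Per-residue H/E/C percentages over a
trajectory close to 100 exactly. A 5.2 Å N–O prescreen bounds the pair
search; pairs closer than 0.5 Å are treated as clashes, not bonds.

## Energies and populations

The package does not re-implement an implicit-solvent (Generalized Born)
energy model. The population machinery is energy-provider-agnostic:
first-class input is a TSV table of per-conformation energies grouped by
conformer id. For self-contained runs, a surrogate score is provided —
hydrophobic SASA (Shrake–Rupley, golden-spiral sphere sampling, default
960 points, probe 1.4 Å) times 0.00592 kcal·mol⁻¹·Å⁻², plus a screened
Coulomb term with distance-dependent dielectric ε(r) = 4r over integer
formal charges (Asp/Glu −1, Lys/Arg +1, His 0, Cu +2). It is a stand-in
scoring function for exercising the pipeline, not a solvation model, and
is labelled as such in its docstring. In the Shrake–Rupley tie-break,
test points exactly on a neighbour's solvent sphere are assigned to the
earlier atom, so coincident atoms sum to a single sphere's area.

The population estimator is a Metropolis Markov chain over the union of
all conformations. A step proposes a conformer j uniformly among the K
conformers, then one of its conformations uniformly; the move is accepted
when e^−(E_j−E_i)/kT > u with u ~ U(0,1) (factors above 1 always accept),
and the state persists on rejection — this reading makes "conformations
visited" a well-defined counter, which an independent-pair-resampling
reading would not. Each step credits the current state's conformer with
one visit; P_n = N_n/N_total. Because the proposal is uniform over
conformers (not over conformations), detailed balance gives the
stationary weight e^−E_c/kT / |ensemble(c)| for conformation c, hence

    P_n ∝ (1/|n|) · Σ_{c∈n} e^−E_c/kT .

`boltzmann_oracle` evaluates exactly this by enumeration (energies
shifted by their minimum first, so it is overflow-safe and shift-
invariant) and is the reference the sampler is validated against; the
sampler's uncertainty is estimated by batch means over 50 contiguous
visit batches, which absorbs the chain's autocorrelation. Reported
per-conformer "conformational energies" are ensemble means ± standard
error on a minimum-anchored relative scale (means rather than minima or
medians: the estimator's stationary weights are ensemble averages, so
the mean is the summary consistent with it).

## The synthetic generator

The generator replaces the study's explicit-solvent MD runs. It emits a
two-chain dimer whose backbone is built residue-by-residue from internal
coordinates (canonical bond lengths/angles, trans peptide bonds), with a
single side-chain donor atom per binding-site residue (carboxylate O,
imidazole N, amide O, thioether S at idealised Cβ-direction distances), a
Cβ elsewhere, a terminal OXT, one Cu per occupied monomer, and single-O
waters. Default per-residue dihedrals are coil (−75°, 160°) with 4°
Gaussian jitter per frame, plus 0.05 Å Gaussian coordinate noise on all
atoms. Signals are planted per frame:

- **Occupancy**: per (monomer, residue) Bernoulli draws; when bound the
  Cu is placed 2.05 Å beyond the donor atom along the outward direction
  (centroid of the targets if several residues of the monomer bind in
  the same frame), otherwise parked ≥ 8 Å from everything.
- **Contacts**: the chain-B residue of a planted pair is rigidly placed
  6 Å from (in-frames) or 14 Å beyond (out-frames) the chain-A Cα along
  an outward direction.
- **Secondary structure**: helix segments switch the planted residues'
  dihedrals to (−57°, −47°); the single strand segment forms an
  inter-chain parallel β-ladder by placing chain B's segment (plus a
  2-residue margin) at a calibrated offset from chain A's — the offset
  was chosen once so that every load-bearing Kabsch–Sander bond of the
  ladder sits far enough below −0.5 kcal/mol to survive the coordinate
  noise.
- **Hydrogen bonds**: the per-frame count follows round(N₀·e^−f/τ);
  each planted bond moves the amide H of a designated chain-B residue to
  1.9 Å beyond a chain-A carbonyl O along the C=O direction. Designated
  residues are spaced two apart so no spurious Kabsch–Sander bridge can
  form.
- **Waters**: designated shell waters sit 2.5 Å from their residue's Cα
  on the face opposite the side chain; the rest live in a far bulk grid.

The two chains share each frame's dihedral draw, so the monomers are
congruent and chain B can be placed along chain A's least-extent
principal axis at a distance that *guarantees* the configured minimum
separation (default 30 Å) — inter-chain geometry is planted, never
emergent. The ground truth records, per frame, the *realised* indicators
re-measured from the emitted coordinates with the same distance rules the
analyses use (via an independent counting path), alongside the drawn
plan, so recovery tests can assert exact equality and, separately, that
the realisation matches the plan within binomial fluctuation. Two
recorded series deserve a caveat: the hydrogen-bond count measures *all*
inter-chain bonds, so in frames where the β-ladder (or a planted contact)
is active it exceeds the planted decay count — decay-constant analyses
therefore use configurations without competing inter-chain plants — and
the per-frame secondary-structure truth for planted residues is the drawn
class, which the assigner reproduces exactly under the calibrated ladder.

Chains shorter than 140 residues carry the binding-site positions
remapped proportionally (order-preserving, strictly increasing; chains
under 24 residues keep only the core site positions, dropping the
Glu46/Glu61/Asp135 decoys); the map is part of the ground truth. What the
generator does **not** emulate: force-field physics, realistic fibril
geometry, solvent dynamics, correlated conformational kinetics, or any
dependence of the planted signals on polymorph identity beyond the
catalog-derived plan. Passing recovery tests therefore demonstrates the
*analyses* are correct and exactly invert the planted bookkeeping — not
that the generator's trajectories resemble real AS dynamics.

## Batch pipeline and problem sizes

`run-all` generates and analyses the full 24-model catalog with all
randomness derived from one seed (model-specific streams come from the
seed plus a stable byte-encoding of the model id), writes per-model and
cross-model TSVs plus a provenance log of every cutoff and seed (no
timestamps), continues past per-model failures, and is byte-reproducible.
The demo batch uses 30–36-residue chains, 12–40 frames, a 4–10-frame
energy window, reduced SASA sampling (40–60 points) and 2×10⁵ MC steps —
sizes chosen so the whole catalog runs in well under a minute while every
code path is exercised; the defaults on the analysis side (cutoffs,
298 K, 10⁶ steps) are unchanged. The acceptance script scales the same
way: full 10⁶-step chains where the sampler itself is measured, 500-frame
trajectories where the study's final-window length matters, and the
reduced batch for the determinism check.

## Known limitations

- The hydrogen-bond criterion has no angular term, so tightly packed
  polar contacts can be counted as bonds.
- The minimal DSSP distinguishes only H/E/C; π/3₁₀ helices map to coil,
  which shifts helix percentages down relative to full 8-state DSSP at
  helix termini.
- The Metropolis sampler reports batch-means errors; for fewer than ~10⁴
  steps per batch the error estimate itself is noisy.
- The surrogate energy ranks compact-hydrophobic-burial conformations
  but has no claim to thermodynamic accuracy; population comparisons on
  real systems should use externally computed energy tables.
- PDB round trips are exact only to the format's 10⁻³ Å precision; DCD
  stores float32.
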