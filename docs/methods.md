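# Methods

This note documents the models implemented in `czbkit`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the design choices made where the problem was genuinely open. No number
stated here is asserted anywhere the test suite or the acceptance script
does not itself compute.

## The ensemble picture and NOE restraints

An intrinsically disordered chaperone bound to a histone dimer is modelled
as an ensemble of conformations sharing one topology. Experimental
information enters as NOE-derived *upper bounds* d on interatomic
distances. Because the NOE intensity scales as r⁻⁶, an ensemble presents
the experiment with the effective distance

    r_eff = ( mean_j r_j⁻⁶ )^(−1/6),

which is dominated by the closest-approach members (power-mean inequality:
min ≤ r_eff ≤ arithmetic mean; property-tested). Violations are one-sided,
max(0, r − d): NOE bounds say "no farther than", never "at least".

Two preprocessing rules mirror standard practice for force fields without
aliphatic hydrogens:

1. **Aliphatic remap.** A restraint endpoint on a carbon-bonded hydrogen is
   moved to that carbon and the bound grows by 1 Å per remapped endpoint
   (the extra bond length). Hydrogens on N/O/S are untouched. Methyl
   protons collapsing onto the same carbon produce duplicate pairs; these
   merge keeping the loosest bound — the conservative NOE convention.
2. **Padding.** Every bound grows by 1 Å, absorbing the standard deviation
   of the NOE signal. Padding is additive and can only reduce violations
   (both properties tested).

Restraint tables use a plain whitespace dialect
(`chain resseq atomname chain resseq atomname upper_Å`, `#` comments); an
X-PLOR `assign` importer (upper = d + dplus) is provided as a secondary
reader. A restraint is *interface* when its endpoints span the chaperone
chain and a histone chain.

Whether published violation statistics for such systems refer to original
or modified bounds is generally ambiguous; all reporting paths here expose
both variants rather than guessing (`pad_restraints` is explicit, and the
acceptance script records the refined-ensemble violation under both).

## Sampling

The conformational sampler is replica-exchange Metropolis Monte Carlo —
deliberately not molecular dynamics. The scientific outputs consumed
downstream are restraint-consistent ensembles, not kinetics, so the
potentials are kept and the propagator is exchanged for one that is exact,
seedable and fast at desk scale. Differences from an MD treatment
(thermostatted event-driven dynamics, a molecular force field) are
acknowledged and not emulated; the surrogate energy has three terms:

* **Two-well restraint potential** per NOE bound: zero inside
  [lower_edge, d]; a step `inner_step` below lower_edge (default 1.8 Å, van
  der Waals contact); `outer_step · (1 + (r − d))` beyond the bound. The
  linear outer ramp gives Monte Carlo moves a restoring gradient while
  preserving the stepwise two-well topology; the inner step defaults to the
  outer step.
* **Harmonic tether** E = k·|x − x_ref|² per core-backbone atom, k = 0.4
  energy·atom⁻¹ at 1 Å displacement. The form is k·Δx², not ½k·Δx²,
  reading the unit "per atom" as the energy at unit displacement. The
  equilibrium variance per axis is then T/(2k) — the closed form used in
  testing.
* **Soft-sphere excluded volume** Σ (σ_ij − r)² for r < σ_ij = r_i + r_j
  (element radii), over heavy-atom pairs on different chains or more than
  5 residues apart in sequence. The sequence-separation floor exists
  because the model has no bonded-geometry terms to balance covalent and
  local secondary-structure contacts.

Temperatures are the 16-value reduced ladder 0.480, 0.495, 0.512, 0.528,
0.546, 0.563, 0.581, 0.600, 0.619, 0.638, 0.658, 0.679, 0.700, 0.722,
0.744, 0.767, used directly as Metropolis temperatures in surrogate energy
units. Moves: torsion pivots about φ/ψ of the mobile (chaperone) chain —
exact rigid rotations of the downstream atoms, the primary move (default
weight 0.8) because they preserve bond geometry without a force field;
local crankshaft rotations about a Cα–Cα axis (0.1); single-atom jiggles
(0.1). Crankshaft and jiggle slightly distort local geometry over long
runs, which is acceptable at the default weights and run lengths.
Nearest-neighbour swaps alternate even/odd pairs every `swap_interval`
steps with acceptance min(1, exp((1/T_i − 1/T_j)(E_i − E_j))); detailed
balance of the combined chain is verified against exact Boltzmann
occupancies on a two-state toy. Each replica owns an RNG stream seeded
`seed + replica_index`, so changing the replica count does not reshuffle
streams; energies are maintained incrementally and re-derived from the
coordinates at every swap and snapshot, keeping the decomposition
audit-exact.

## Refinement and centroids

Snapshots are filtered sequentially: keep the lowest `energy_percentile`
per named energy annotation (default 50%, any annotation vector is
accepted so externally computed energies can be supplied), then cap the
**per-structure** mean violation (default 0.5 Å). The per-structure plain
average is the filtering statistic; the r⁻⁶ ensemble statistic is reserved
for reporting, since it is not defined per member. These thresholds are
documented placeholders — published refinement protocols rarely state
theirs — and are exposed in `FilterSpec`.

Centroids come from PAM k-medoids (BUILD + steepest-descent SWAP, ties to
the lowest index, hence deterministic) on a pairwise superposed-RMSD
matrix, default k = 6. The clustering selector is the chaperone backbone:
the core is tethered, so chaperone conformation is the quantity that
varies.

## Interface analysis

A contact is a heavy-atom pair, one atom per group, within 6.0 Å
*inclusive* (the boundary case is pinned by test). Per-residue counts are
averaged over ensemble members; each qualifying pair increments both of its
residues, so the side sums and the total agree. SASA uses Shrake–Rupley
with golden-spiral sphere points (default 960; single-sphere and two-sphere
closed forms reproduced within 1%), probe 1.4 Å, radii C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80 (H 1.10 when present; hydrogens are excluded from
the analysis paths). Buried SASA of a chain partition is
SASA(A) + SASA(B) − SASA(AB); over an ensemble it is reported as
mean ± SD across members, with the statistic labelled explicitly. The
heat-map export writes each atom's B-factor as its residue's average
contact count (0 outside the profile) plus a TSV of the group residues.

## Mutation screen

Substitutions are enumerated per site: every standard amino acid except
proline, cysteine and the native — 17 for a non-cysteine native. Applying
the rule literally, a cysteine native yields 18; native-cysteine/proline
sites are not asserted beyond that reading.

Repacking fixes all backbone atoms (bitwise; tested) and optimises discrete
rotamer states of the site plus all rotatable residues within 8 Å of the
site Cα, by simulated annealing (geometric ladder T = 5 → 0.1 over 200
sweeps by default). The rotamer library is backbone-independent and coarse
(canonical gauche/trans wells with prior weights); each run re-draws the
library χ angles with Gaussian jitter (σ = 8°), modelling sub-rotamer
relaxation and giving the screen a finite, n^(−1/2)-scaling SEM. The
surrogate packing energy is soft-sphere vdW (weight 20, contact distances
scaled by 0.9), a distance-dependent-dielectric Coulomb term on charged
side-chain termini (±0.5/±1 unit charges, prefactor 332/4), and a rotamer
prior −0.5·ln w. Its scale is arbitrary: signs and rankings are the
meaningful outputs, and no correspondence to kcal/mol is claimed.

ΔΔG uses four arms per run — mutant/wild type × complex/dimer (the dimer
deletes the chaperone chain and repacks in its absence, the unbound
reference) — with one shared seed per (centroid, run), so annealing noise
cancels pairwise and a WT-vs-WT screen is exactly zero (algebraic identity,
tested). Records store the full (centroid × run) matrix and expose SEM
pooled, over runs, and over centroids, labelled, since the aggregation
level of a published "±S.E." is usually unstated.

## Synthetic data

The generator emulates the *geometry class* of the study system, not its
coordinates: two idealized α-helices (chains A, B; Engh–Huber-style internal
coordinates, NeRF construction) form a compact core, and an extended chain
C wraps around a configurable fraction of the core's convex outline
(default 2/3 — the lasso arrangement) at a set clearance (default 4.0 Å),
marching Cα positions at 3.8 Å spacing along the support function of the
core's cross-section so the path cannot dive into the inter-helix groove.
Core sequences are small residues (ALA/SER/THR) so the convex outline hugs
the backbone and the wrapped chain stays in contact along the whole arc;
side-chain rotamers are chosen greedily for clearance. The reference is
verified clash-free (no non-bonded heavy pair < 2.4 Å) and has zero
excluded-volume energy.

Ground-truth restraints take, per chaperone residue, its (up to) two
shortest cross-chain heavy-atom distances ≤ 5 Å, with bound r + slack
(default 0.5 Å) — so the reference violates nothing by construction.
Decoys perturb chaperone atoms with zero-mean Gaussian noise at graded σ
(Gaussian rather than torsional, because violation then grows predictably
and monotonically with σ, giving a clean oracle). The ΔΔG benchmark
selects, by construction search: a small (ALA) core residue for which
*every* tryptophan rotamer overlaps immovable chaperone atoms (expected
ΔΔG > 0), and a solvent-exposed residue with no chaperone atom within 12 Å
(expected ≈ 0), plus three jittered copies standing in for centroids.

What passing these tests shows — and does not. The fixtures exercise the
full logic (restraint bookkeeping, r⁻⁶ statistics, sampling, filtering,
clustering, contacts, SASA, screen sign/scaling) on geometry whose ground
truth is known exactly. They do not show force-field-level realism:
idealised internal coordinates, a surrogate energy and desk-scale sampling
cannot reproduce the absolute numbers of a microsecond-scale
molecular-dynamics study of the real complex (ensemble sizes in the
thousands, buried surfaces of ~2500 Å², kcal/mol ΔΔG values). Problem
sizes used by the tests and the acceptance script (toy of ~290 atoms,
10³–10⁶ MC steps, tens of repack runs) were chosen as the package's own
desk-scale study conditions.

## Numerical choices and degenerate inputs

* Altloc: highest occupancy wins, ties prefer blank/'A'. Element falls
  back to the atom-name leading character when the PDB element column is
  absent. Author residue numbering is preserved; no renumbering.
* Superposition uses SVD (Kabsch); collinear or <3-atom selections raise
  an alignment error rather than returning an arbitrary rotation.
* r_eff is singular when any member has coincident restraint atoms (r = 0);
  this raises rather than returning infinity.
* Empty filter results, overlapping contact groups, incomplete chain
  partitions, non-adjacent swap attempts, chaperone-side mutations and
  k > n clustering are contract errors with diagnostics, not silent
  defaults.
* The sampler's tethered atoms are outside the default move set (the core
  is constrained); the tether term still prices any move that touches them.

## Known limitations

* No bonded-geometry energy: long unsupervised runs with jiggle/crankshaft
  moves drift local geometry.
* Backbone-independent rotamers and a surrogate energy limit the screen to
  sign/rank conclusions.
* PDB writing only (no mmCIF), upper-bound distance restraints only (no
  dihedral/RDC), no hydrogen placement.
* The published-NMR-ensemble comparison path (multi-model PDB + deposited
  restraint list → r⁻⁶ interface violation under both bound conventions)
  is implemented and tested on synthetic stand-ins; it requires the
  external deposition files to run on the real complex.
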