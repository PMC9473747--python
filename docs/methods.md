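# Methods

This note records the models, conventions and design choices behind
`oligotraj`, at the level a maintainer or reviewer needs to interpret its
output.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and numbering

Coordinates are Angstrom everywhere inside the package; the single point of
conversion to nanometres is report output (Rg columns, the landscape's y
axis, the CLI's cluster-cutoff flag).  Residues are indexed 0-based
internally; every report uses the biological numbering of the fragment, which
starts at 105 (`SystemModel.residue_numbering_offset`).  Chains are labelled
A, B, C, … in file order.

## Geometric detectors

**Hydrogen bonds** (`geometry.detect_hbonds`): donor backbone amide N–H,
acceptor carbonyl O (OXT included); a bond requires N–O distance
≤ `hbond_max_dist` (default 3.5 Å, inclusive) and N–H···O angle at the
hydrogen ≥ `hbond_min_angle` (default 120°, inclusive).  Proline has no amide
hydrogen and never donates.  When the input file carries no amide H it is
reconstructed in the standard planar-amide geometry: 1.01 Å from N, opposite
the bisector of C(prev)–N–CA.  The first residue of a chain has no preceding
carbonyl; if it also has no explicit H it is skipped as a donor with a
warning.  Covalently linked N/O pairs (same residue, or donor N against the
preceding residue's carbonyl) are never counted.  Scope `all-NO` additionally
admits side-chain oxygens as acceptors.

**Contacts** (`geometry.residue_contacts`): a residue pair is in contact when
its minimum heavy-atom distance is ≤ `contact_max_dist` (5.4 Å).
"Discontinuous" is interpreted as |i−j| ≥ `min_seq_separation` (2) within a
chain — the standard contact-map convention that drops trivially touching
sequence neighbours; interchain pairs are never excluded.

**Rg**: mass-weighted over all peptide heavy atoms of all chains by default.
Whether published Rg curves for this system use all atoms or Cα only is not
derivable from the typical figure caption; both the selection and the mass
weighting are exposed as arguments.

**SASA**: Shrake–Rupley with Bondi radii (C 1.70, N 1.55, O 1.52, S 1.80 Å),
probe 1.4 Å, 960 deterministic golden-spiral sphere points.  Hydrophobic
total = C + S atoms, hydrophilic = N + O.  Hydrogens carry no surface.  An
isolated sphere reproduces 4π(r+probe)² exactly up to the point-fraction
granularity; two-sphere cases are checked against the analytic
spherical-cap formula in the tests.

## Secondary structure

`secondary_structure.assign_ss` implements the Kabsch–Sander algorithm: the
electrostatic H-bond model E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol, bond iff E < −0.5; 3/4/5-turns; helices G/H/I from consecutive
turns; parallel/antiparallel bridge patterns, ladders, bulge-linked ladders
→ E, isolated bridges → B; turns → T; bend (κ > 70°) → S.  Two conventions
follow the reference implementation exactly, because agreement with it is a
package guarantee:

- the amide hydrogen is always *computed* (1 Å from N along the previous
  residue's C→O direction); explicit H atoms in the file are ignored by this
  module (the geometric detector above does use them);
- bridge partners must be interior residues of their chain — a chain's first
  and last residue can donate and accept H-bonds inside bridge patterns but
  never form a bridge themselves.

Assignment precedence mirrors the reference: 4-turn helices overwrite
strands; G/I/T/S only fill unassigned residues.  Helices and turns never span
a chain terminus; inter-chain bridges are permitted.

Category collapse (Fig-1-style statistics): E → β-sheet, H → α-helix,
T → turn, S → bend, everything else (G, I, B, '-') → coil.  Isolated bridges
count as coil because a sheet, by the pairing rule below, needs two or more
coherent strand residues — a single bridge cannot satisfy it; G and I map to
coil so that "α-helix" means genuine 4-turn helix.  The table is an ordinary
dict argument and can be remapped.

## Sheet topology

A **strand** is a maximal run of ≥ `sheet_min_run` (2) E residues in one
chain.  Two strands are **sheet-paired** when ≥ `sheet_min_hbonds` (2)
backbone hydrogen bonds (geometric criterion) join their residues; the edge
is parallel/antiparallel by the sign of the dot product of strand direction
vectors, with |dot| ≤ 0.5 reported as `indeterminate` rather than forced.
A **β-sheet contact** — the x coordinate of the landscape — is a pair of E
residues in paired strands linked by ≥ 1 backbone H-bond; a second mode
counts all residue pairs of paired strands regardless of direct bonding (the
published figure ranges are consistent with either; the H-bond-linked count
is the default).

The classifier reads connected components of the pairing graph, in this
precedence order:

1. **closed_barrel(n)** — a component whose graph contains a simple cycle of
   ≥ 3 strands; n = strands in the component.
2. **open_barrel(n)** — an acyclic component of ≥ 3 strands that curls:
   terminal strands approach within 8.0 Å (min Cα–Cα) *or* the accumulated
   angle between successive strand-pair planes (SVD plane fits along the
   sheet path) reaches 90°.  "Open barrel" has no standard printed
   definition; this curl criterion separates curled pentamer-style sheets
   from flat ones and both thresholds are arguments.
3. **bilayer[m, n]** — two sheet components stacked face to face: ≥ 3
   inter-component residue contacts (5.4 Å rule) and no pairing edge between
   them; layer sizes sorted descending.  Three contacts is the smallest count
   that reads as a packed interface rather than a grazing touch.
4. **single_sheet(n)** — one flat component (largest, if several).
5. **disordered** — no component of ≥ 2 strands.

Chains without strands never block a call: a three-stranded sheet plus a coil
spectator chain is `single_sheet(3)`.  A `mixed_orientation` flag is set when
edges of both orientations occur anywhere in the frame.

## Clustering

Cα-RMSD after optimal superposition (Kabsch, SVD route, proper rotation
enforced; cross-checked against the quaternion characteristic-polynomial
method to 1e-9 Å).  gromos/Daura clustering: repeatedly take the frame with
the most neighbours at RMSD strictly below the cutoff (ties → lowest frame
index), remove it with its neighbours as one cluster.  Default cutoff 0.4 nm
on Cα of all residues.  Identical peptide copies are physically
interchangeable; the default keeps the file's chain order (the standard
gromos behaviour), and `permute_chains=True` minimizes the RMSD over all
chain relabelings (≤ 6! = 720 permutations for the systems this package
targets).

## Landscapes and ensemble statistics

PMF(x, y) = −RT ln H(x, y), R = 8.314462×10⁻³ kJ/(mol·K), T default 310 K
(RT = 2.5775 kJ/mol), shifted so the occupied minimum is 0; empty bins are
+∞.  Default binning: integer bins on the β-sheet-contact axis, 0.025 nm on
the Rg axis — no published binning exists for this observable, and these
resolve single contacts without starving typical frame counts.  The
convergence check is the histogram overlap coefficient Σ min(pA, pB) between
two disjoint windows of an observable.  Ion counts use the full cubic box
volume, round(c·V·N_A) — full volume (not solvent-excluded) reproduces all
three printed pair counts for the 0.15 mol/L systems, which validates the
choice.

## Synthetic data

`build_peptide` grows a chain by internal-coordinate (NeRF) placement with
standard backbone geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; trans ω;
τ(N–Cα–C) 111.2°), giving Cα–Cα ≈ 3.80 Å and an α-helix rise ≈ 1.5 Å/residue.
Atoms per residue: N, H, CA, CB, C, O (+OXT); side chains beyond Cβ are
omitted from 3D builds — full rosters, hydrogens included, live in
`RESIDUE_ROSTERS` and feed only the composition accounting (the charged
fragment's 172 atoms).  Consequences: SASA tests on synthetic structures
assert qualitative hydrophobic/hydrophilic ordering, not side-chain-accurate
areas.

Sheets are posed by composing one optimized strand-pair transform per
junction: an antiparallel neighbour is the template rotated 180° about the
stacking axis, a parallel neighbour a pure translation; the translation (and
for barrels a per-strand twist about the strand axis) is chosen by grid
search maximizing the number of *near-ideal* geometric H-bonds (≤ 3.1 Å,
≥ 150°), tie-broken by the nominal criterion and validated so each chain
carries one coherent ladder (this avoids registries that split strands around
the proline).  Barrels place strands on a cylinder of radius
d/(2 sin(π/n_slots)) with zero shear; alternating flips create two junction
types, optimized jointly on the weaker one.  Closed barrels therefore require
an even strand count — with alternating antiparallel strands an odd cycle
cannot close — and very tight cylinders (4-slot) have no clash-free
H-bonded geometry, so `closed_barrel` supports n ∈ {6, 8, …}.  Open barrels
use n+2 slots (gentler options tried automatically) so the sheet curls
without completing the cycle.  Bilayers stack two antiparallel sheets rotated
90° (orthogonal packing) at the smallest clash-free separation, which yields
inter-layer side-chain contacts but no inter-layer backbone H-bonds.  Coils
draw self-avoiding random dihedrals from a broad φ<0 region and scatter
chains with ≥ 4 Å minimum intermolecular separation, mirroring how
oligomerization runs are set up.

**Noise.** `noise_sigma` adds an isotropic Gaussian displacement of exactly
that per-atom standard deviation, *spatially correlated* with a 4 Å Gaussian
kernel.  The correlation is deliberate: thermal fluctuation in a condensed
structure is smooth below the nonbonded scale (bonded neighbours move
together, domains drift apart), whereas independent per-atom noise shreds
covalent and hydrogen-bond geometry at amplitudes far below any real
conformational change — a Monte Carlo check shows individual Kabsch–Sander
bonds of −2.4 kcal/mol surviving independent 0.3 Å noise only ~83 % of the
time, which no assignment implementing the published rules can compensate.
With correlated noise the generated label remains the physically correct
description of the frame at σ = 0.3 Å, which is what a robustness dial is
for.  What this does **not** emulate: anharmonic side-chain rearrangement,
register slips, partial unfolding — real MD ensembles contain frames no
noise dial reaches, so detector accuracy on synthetic data bounds, but does
not guarantee, accuracy on real trajectories.

**Self-consistency.**  Every noise-free assembly is pushed through the full
detector stack (DSSP → strands → H-bonds → pairing graph → classifier) before
being returned; a mismatch with the intended label is an error (for coil
states, a resample).  Ground-truth sidecars record the requested state, the
verified class and strand counts, the per-residue noise-free assignment, σ
and the seed.  All randomness flows through one integer seed; identical seeds
give bit-identical files.

## Problem sizes

Defaults used by the test suite and acceptance script: ~10 noise-free frames
for the reference-DSSP comparison (≈ 360 residues), 9 topology classes × 12
frames at σ = 0.3 Å (plus 5 noise-free each), 100 random matrices ≤ 100
frames for the clustering cross-check, and a 24-frame six-chain
coil → sheet → barrel trajectory for the end-to-end run.  These sizes give
binomial resolution well below the 95 % thresholds they check while keeping
a full run in tens of seconds; they are generator settings, not limits of
the implementation.

## Known limitations

- Side-chain-level observables (salt bridges, steric-zipper interface
  classes, side-chain SASA) are out of scope; SASA on reduced models is
  qualitative.
- The DSSP module ignores explicit hydrogens by design (reference fidelity);
  files with experimentally meaningful amide-H positions are not treated
  specially.
- Closed-barrel generation requires even n; odd closed barrels (which exist
  in nature via nonzero shear) are not constructible by this generator,
  though the *classifier* handles any cycle length.
- `pmf2d` reports +∞ for empty bins rather than extrapolating; basin
  comparisons across differently-binned landscapes are the caller's
  responsibility.
- Alternate locations keep the first altLoc; insertion codes are rejected.
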