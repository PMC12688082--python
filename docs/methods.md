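# Methods

This note records the models, parameter choices and numerical conventions
behind cgkit, and what the synthetic fixtures do and do not establish.

## CG models of P1 and DiI

P1 monomers map heavy atoms onto Martini-3-style beads at 4:1 (regular),
3:1 (small) and 2:1 (tiny).  The disordered backbone is uniformly coil-type
P2.  Side chains:

* **M1** — ester linker (P2, regular) + short alkyl bead (C2, small).
* **M2** — ester linker (P2) + two OEG beads (SN3r, small).
* **M3** — secondary-amide linker, then two OEG beads, then the split amide
  (TN4a nitrogen bead + carbonyl folded into the ring-conjugated bead), a
  three-bead benzene ring (TC5, TC5, TN6d) and the terminal sulfonamide as a
  single highly polar P6 bead.  The amide linker bead absorbs six heavy
  atoms — the one deliberate exception to the mapping ratios — so the OEG
  segment keeps its own beads and its hydrophilic-layer role.  The terminal
  P6 bead is flagged as the specific bCA-II binding site; the TN6d ring bead
  as the benzene-sulfonamide group.

Two typing variants are built from one override table and differ in nothing
else: the *nonstandard* variant uses P3 for the M3 amide (more hydrophilic
than the guideline P2, distinguishing it from the M1 ester), TN6d for the
benzene-sulfonamide ring bead and for DiI's conjugated bridge and first tail
beads; *strict_standard* replaces exactly those with P2 / TC5 / TC1.

**DiI reading.** The figure-level bead assignment of DiI is a documented
package choice: per indolenine half, three TC5 benzene beads, one SC3
gem-dimethyl bead and one SQ2 bead carrying +0.5 (the resonant carbocyanine
charge split across the two nitrogens); one conjugated-bridge bead joins the
halves (11 head beads total, the SASA-tracked `headgroup` group).  Each C18
tail is five beads: a conjugated first bead plus four C1.  With the
idealized reference geometry (ring bonds 2.9 Å, planar head, extended
tails), the isolated headgroup SASA evaluates to ≈ 501 Å² under the default
radii below — consistent with the solution-state value this architecture is
expected to show, with the caveat that any such number depends on the radii
convention.

**Bonded parameters.** Bond lengths default to a size-class table
(regular–regular 3.9 Å down to tiny–tiny 2.9 Å), force constants to
2.99 kcal·mol⁻¹·Å⁻² (≈1250 kJ·mol⁻¹·nm⁻²) with stiffer ring bonds
(11.95), angles to 150° / 5.98 kcal·mol⁻¹·rad⁻², dihedrals to
180° / 11.95 kcal·mol⁻¹.  These are idealized-geometry / analog-group
defaults standing in for distances measured on energy-minimized atomistic
structures; callers can override any bond with reference geometry (a
distance table or a coordinate set).  Force-constant values are assumptions:
no reference values exist for this chemistry, and downstream equilibration
relaxes them.  Bead masses follow Martini size-class convention (72/54/36 u).

**Chain generation.** Per-chain composition bounds are 5–6 M1, exactly 4 M2,
1–2 M3; monomer order is a uniform permutation (random copolymer — no block
structure is enforced).  The default 4-chain set cycles through
{(5,4,1), (6,4,2), (5,4,2), (6,4,1)} so its mean length is exactly 11
monomers, matching the synthesized material's 11 ± 4; sampling mode draws
counts uniformly within the bounds instead.

## Force-field patches

* **Protein–water scaling**: every protein bead type X is duplicated as WX
  with all LJ rows copied (X–X as WX–WX and WX–X, X–Y as WX–Y); only
  ε(WX–W) is multiplied by the factor (default 1.10).  Only ε is scaled, not
  σ — the modification targets interaction *strength*, and touching σ would
  change excluded volume.  Patches are idempotent and never modify
  untargeted base rows.
* **Zn–sulfonamide cross term**: one LJ override row, σ = 5 Å,
  ε = 15 kcal/mol (62.76 kJ/mol in file units), between the Zn bead (type
  SD — the Ca²⁺ bead type, since no Zn default exists) and the M3 terminal
  P6 bead.  The potential minimum sits at 2^(1/6)·σ ≈ 5.6 Å and the well
  depth is commensurate with benzene-sulfonamide binding free energies
  (10–12 kcal/mol).
* **Zn coordination**: three harmonic bonds of 2.4 Å from the Zn bead to the
  His93/His95/His188 side-chain beads.  The force constant
  (23.9 kcal·mol⁻¹·Å⁻², ≈10⁴ kJ·mol⁻¹·nm⁻²) is an assumption chosen stiff
  enough that equilibrium fluctuations stay far below the 2.4 Å bond length.
* Zn mass defaults to 65.4 u (elemental value; no reference states one).

A minimal synthetic Zn-protein stand-in (a labeled bead cloud with the three
histidines at coordination distance) ships for testing and docking without
any structure download.  The base nonbonded table shipped for patch tests is
likewise a synthetic representative subset, not the published force-field
matrix; real work should load an actual parameter file.

## System construction

Unimers are placed at uniform random positions and orientations, chain
identities in a 2:1:1:1 ratio over the four default sequences, with every
intermolecular bead distance ≥ 3.5 Å under periodic minimum image (a default;
no reference value exists) and a retry budget of 10⁴ placements per molecule.
Cargo is inserted outside the convex region of the existing aggregate — the
stated initial condition is dye in the bulk.  Proteins are docked with the
Zn bead a uniform 5–10 Å from a distinct exposed ligand bead, body oriented
away from the aggregate; "exposed" means ligand-bead SASA > 10 Å² (a
package criterion — exposure is stated qualitatively in the protocol this
reproduces).  Solvation is bookkeeping: the water-bead count comes from free
volume at bulk CG density (one bead per four waters, 8.35 beads/nm³),
lattice coordinates are provided, and counter ions neutralise the net solute
charge exactly.

Run parameters are emitted field-for-field: 10 fs timestep, neighbour list
every 20 steps, 1.1 nm LJ and reaction-field cutoffs with ε_r = 15,
Berendsen thermostat at 303 K (τ_T = 0.5 ps) — kept as Berendsen for
protocol fidelity despite its known ensemble artifacts — Parrinello-Rahman
at 1 bar (4.5×10⁻⁵ bar⁻¹, τ_p = 4.0 ps), 5000 steepest-descent minimisation
steps, and 200 ps restrained equilibration at 0.1 kcal·mol⁻¹·Å⁻²
(41.84 kJ·mol⁻¹·nm⁻² in file units, no barostat during restraints).

## Analyses

**Clustering.** Entities are whole P1 peptides or M1 side-chain groups; the
metric is the minimum bead–bead distance between entities under periodic
minimum image, computed via a KD-tree neighbour search and fed to DBSCAN
(eps = 8 Å, min_samples = 5) as a sparse precomputed graph.  Pairs absent
from the graph are farther than eps by construction, so the sparse form is
exact.  Entities outside any dense neighbourhood are noise; a dispersed
frame has zero clusters.  Clusters spanning the periodic boundary merge
automatically because the metric is minimum-image.  Tie-breaking for border
entities follows entity index order (sklearn's processing order),
deterministic by construction.

**Gyration shape.** The tensor is the unweighted coordinate second-moment
sum about the centroid, exactly as the defining formula states (no 1/N — the
shape descriptors depend only on eigenvalue ratios, so normalisation is
immaterial), applied to whatever selection is passed: one polymer or a whole
assembly.  Eigenvalues are sorted ascending.  When the spectrum is fully
degenerate the prolateness expression is 0/0; the package returns 0 with a
`degenerate` flag (a sphere is neither prolate nor oblate).  The degeneracy
threshold is 10⁻¹² relative to the squared trace.

**Density profiles.** A cylinder of 6 Å diameter through the aggregate
centre of mass, aligned with a coordinate axis; beads within 3 Å radial
distance are histogrammed along the axis in 0.5 Å bins and averaged over a
trailing window (default 50 ns when timestamps span it, all frames
otherwise).  Bin edges are symmetric about the COM and wide enough for every
frame, so the bin sum equals the mean in-cylinder population exactly.

**SASA.** Shrake–Rupley on CG beads: each bead is a sphere of half its
size-class σ (regular 2.35 Å, small 2.05 Å, tiny 1.7 Å), the probe defaults
to 1.4 Å, and 960 Fibonacci-lattice points per sphere give ≲1% quadrature
error on an isolated bead (4π(r+ρ)² closed form).  All beads in the frame
occlude.  No SASA convention is standard for CG beads, hence the wide
tolerance quoted for absolute headgroup areas; radii and probe are
configurable.

## Fixtures: what they are and are not

Fixtures are geometric constructions that realise the structural motifs —
three-layer micelles (M1 core within 15 Å, backbone shell to 22 Å, M3
surface at 27 Å, ligands at 30 Å; radii chosen for the ~5 nm micelle scale),
multicore aggregates (cores > 8 Å apart, shells interpenetrating, explicit
interface bridges guaranteeing single-aggregate connectivity), stepwise
disassembly series (whole micelles detach 150 Å away), exact-eigenvalue
shape clouds (whitened Gaussian clouds rescaled along principal axes, so
degeneracies are exact to machine precision), and buried/exposed cargo
states (close-packed 2.5 Å-grid filler beads enclose the dye or its tails).
They satisfy, by construction, the geometric predicates their consumer tests
assert, and the tests validate them against brute-force oracles (threshold-
graph components, pairwise distance scans, dense-grid SASA) rather than
against the code under test.

They are **not** thermodynamically realistic: chains within a fixture
interpenetrate freely, there is no excluded volume, no solvent, and no
energetics.  Passing analyses on fixtures therefore establishes the
correctness of the measurement machinery (clustering, profiles, shape, SASA)
on known geometry — not that the physical model reproduces μs-scale assembly
statistics, which require actual MD and are out of scope here.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: shape-metric
sweeps use 10⁴ random clouds of ~10 points; clustering oracle comparisons
use 50 constructed instances and disassembly series of 80→20 polymers
(~3600 beads/frame); density statistics use 20–25 frames of 2–4 × 10⁴
beads; SASA fixtures contain ~2×10³ occluder beads.  The acceptance script
evaluates the three shape archetypes at 400 points each; the exact
degeneracy of the constructions makes its outputs seed-independent.

## Known limitations

* The bonded-parameter table is idealized; users with atomistic reference
  structures should pass measured distances.
* GRO round-trips lose cgkit-specific metadata (bead typing, roles, flags);
  the internal plain-text frame format is lossless.
* SASA ignores periodic images (targets are expected compact and far from
  the box boundary).
* The conformation grower satisfies a spanning tree of the bond graph;
  ring-closure bonds start strained and rely on minimisation.
* DBSCAN border-point assignment can differ from plain threshold-graph
  components in borderline geometries; the equivalence tests use
  constructions without such chains, as the equivalence claim requires.
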