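# Methods

This note records the models, conventions, and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Data model and units

Coordinates and box lengths are stored in nanometres, times in
nanoseconds, charges in elementary charges, Lennard-Jones parameters in
nm and kJ/mol, masses in amu.  PDB Å values are converted at the I/O
boundary; indices are 0-based internally and 1-based in files.  Only
orthorhombic periodic boxes are supported; the minimum-image convention
is `d − box·round(d/box)` per axis, valid for any separation.

Molecules are classified from residue codes: the 20 amino acids →
protein; `AAH`/`AAD` (protonated / deprotonated acrylic-acid monomer) →
polyelectrolyte; `HOH`-like → water; `NA`/`CL` → monovalent ions.
Unknown codes load with a warning into a generic class.  Covalent bonds
are carried explicitly by synthetic topologies and perceived by distance
(X–H ≤ 0.125 nm, heavy–heavy ≤ 0.18 nm, same molecule) for file input.

## Composition and charge arithmetic

Each deprotonated monomer carries −1; a chain with deprotonation
fraction f = 0.5 charges every second monomer (the pattern
`floor((m+1)f) − floor(mf)`).  Counterion counts restore exact
electroneutrality with a single monovalent species: the mixture of one
+8 protein and 5×40 monomers at f = 0.5 carries −92 net and takes 92
Na⁺; the protein alone takes 8 Cl⁻.  The charge-neutral mass ratio is
r_m = (q_P/M_P)/(f/M_m) = (8/14000)/(0.5/70) = 0.08.  The Bjerrum length
e²/(4πε₀ε_r k_BT) uses CODATA constants; with ε_r = 78.4 at 298 K it is
0.715 nm (0.7 to one decimal).  Ionic strength is computed from explicit
ion counts and box volume only; no attempt is made to reproduce a
nominal molarity whose bookkeeping is not specified.  The Coulomb
prefactor used throughout energetics is fixed at
138.935458 kJ·mol⁻¹·nm·e⁻² for bit-stable sums.

## Stability metrics

RMSD is computed on Cα atoms after optimal rigid superposition.  The
superposition delegates to `scipy.spatial.transform.Rotation.align_vectors`
(proper rotation guaranteed; the reflection branch is rejected there),
wrapped to return rotation, translation, and RMSD; degenerate inputs
(< 3 points, collinear sets) are rejected.  RMSF superposes each window
frame onto the window-mean structure, iterated once (first frame → mean
→ re-superpose), and reports per-residue √⟨|r−⟨r⟩|²⟩; a `reference="first"`
switch is available since the choice of reference is a convention.  The
analysis window is specified as trajectory fractions; the default
(0.5, 1.0) is the steady-state convention of keeping the last half of a
run.  Mass weighting is off by default — irrelevant for Cα-only
selections.

## Secondary structure

The classifier follows the Kabsch–Sander construction.  A backbone
hydrogen bond from the carbonyl of residue i to the amide of residue j
exists when E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5
kcal/mol (distances in Å, clash guard at 0.5 Å).  Missing amide
hydrogens are rebuilt at 1.01 Å on the bisector of the N→C(prev) and
N→Cα directions.  n-turns (i→i+3,4,5) give 3₁₀/α/π helices when two
consecutive turns overlap; parallel and antiparallel bridge patterns
(|i−j| ≥ 3) give β-bridges, extended to β-sheet when a neighboring
residue pair also bridges; turn marks interior residues of any n-turn;
bend marks a Cα-trace kink above 70°.  When patterns overlap, the
priority is α > β > 3₁₀ > π > turn > bend > coil (the classical
convention; a `prefer_pi` flag promotes π above α, since later
implementations differ).  Chain breaks (consecutive Cα > 0.45 nm, or a
molecule boundary) terminate pattern propagation.  Distances here use
raw coordinates — the protein is assumed whole, which the generator
guarantees and file input should too.

Window summaries report mean ± sd residue counts per class (means sum to
the residue count exactly, since labels partition residues).  The
variation table is the elementwise (V2−V1)/V1 between two condition
summaries, NaN where V1 = 0.  Grouped percentages pool class means
(e.g. all three helix flavors) as 100·Σmeans/n_residues, the coarse
grouping used when comparing against low-resolution spectroscopy.

## Association analysis

Per frame, the single globally closest (protein atom, polymer atom)
pair is found under minimum image — one attribution per frame, not one
per chain.  All atoms participate by default (a heavy-atom-only flag
exists).  The search uses a periodic k-d tree (`scipy.spatial.cKDTree`
with `boxsize`); exact ties break to the lowest (protein, polymer)
index pair.  Frames whose minimum distance is ≤ the contact cutoff
(default 0.35 nm, the hydrogen-bond length scale) increment the count of
the amino-acid type owning the protein atom.  Rates are reported raw,
as a percentage of analysed frames, and normalized by the number of
residues of the type and the frame count (×100).  Both the
frame-fraction and the type-normalized rate are emitted, since
published "association rate" tables are ambiguous between the two; the
histogram counts only frames meeting the criterion.

## Hydrogen bonds

Donors are N/O atoms with at least one covalently bound H (from the
bond list); acceptors are all N/O atoms.  A bond requires
r(D···A) ≤ 3.5 Å and the angle at the donor ∠(H–D–A) ≤ 30°, both
inclusive (the criteria's source does not state strictness; inclusive
is chosen and boundary-tested), with a 10⁻⁹ tolerance absorbing float
representation at the exact boundary.  Intra-residue pairs are
excluded; the minimum image applies to both distance and angle
geometry.  Every qualifying (D, H, A) triple is returned — detection is
exhaustive and oracle-tested against full enumeration.  The census
attributes each bond to the unordered class pair of its donor and
acceptor — polymer–polymer (PP), polymer–water (PW), protein–protein
(LL), protein–water (LW), polymer–protein (PL) — and reports mean ± sd
per pair over the window; per-residue-type counts against the polymer
divide the frame-mean bond count by the number of residues of the type.

## Spatial statistics

Group centers of mass unwrap each group around its first atom (minimum
image) before mass-weighted averaging, so groups straddling the
boundary get the wrapped-consistent center.  g(r) is the shell-normalized
histogram of minimum-image center distances: counts divided by
N_A·ρ_B·V_shell per frame, with ρ_B = (N_B − δ_AB)/V (the −1 makes the
identical-group case unbiased, so an ideal gas gives g = 1).  r_max
defaults to 0.49× the smallest box edge and may not exceed half of it.
Default bin width 0.005 nm, configurable.

SASA is Shrake–Rupley quadrature: for each atom, test points on the
probe-expanded sphere (Bondi radii + 0.14 nm probe by default) are
checked against all neighbors' expanded spheres; the exposed fraction
times 4π(r_i+r_p)² sums over the group.  Test points come from a
deterministic golden-spiral placement (960 by default) — no seed
involved.  Occluders are the group's own atoms (the convention of
computing a species' surface against itself); the group is made whole
across the boundary first, making the result exactly
translation-invariant and rotation-invariant to quadrature error
(< 0.5% at 960 points, verified against the two-sphere closed form).

## Energetics

Non-bonded energies between two molecule classes sum minimum-image pair
terms with spherical truncation at 1 nm (both terms, configurable):
Coulomb 138.935458·q_iq_j/r and Lennard-Jones
4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] with Lorentz–Berthelot mixing.  For a
class against itself, each pair counts once and 1–2/1–3 bonded pairs
are excluded; 1–4 pairs enter at full strength (force-field-specific
1–4 scaling is out of scope).  No tail corrections.  This is a
real-space truncated decomposition intended for comparing class pairs
across conditions; it does not reproduce reciprocal-space (Ewald)
totals, whose group decomposition is solver-defined.  Neighbor search
uses the periodic k-d tree; results are oracle-tested against the
double loop.

## Synthetic systems

The generator builds what the analyses need and nothing more:

- **Protein** — one chain of five backbone atoms (N, H, Cα, C, O) plus a
  pseudo side-chain carbon per residue, constructed by NeRF extension
  with standard bond lengths/angles and per-residue (φ, ψ) from the
  secondary-structure plan: α (−57°, −47°), 3₁₀ (−49°, −26°),
  π (−57°, −70°), strand (−139°, 135°), coil (−75°, 150°).  Interior
  residues of planted helices are recovered by the classifier at ≥ 95%
  under jitter σ ≤ 0.01 nm.
- **Antiparallel sheets** — consecutive strand runs in the plan are
  paired: the second run becomes a rigid copy of the first, rotated
  180° about the amide-face axis and offset 0.42 nm, which produces
  mutual backbone hydrogen bonds on every paired residue.  The face
  axis is defined on a freshly built canonical strand and transferred
  by Kabsch superposition, because an embedded run's first amide H
  depends on the preceding residue.  Pseudo side chains of paired
  residues pack closer than a real pleated sheet; backbone H-bond
  geometry, which the classifiers consume, is canonical.  Run termini
  cannot form bridges (the pattern needs i±1 context), so a planted
  n-strand recovers n−1 to n−2 sheet residues.
- **Polyelectrolyte** — linear chains, 0.25 nm monomer spacing, three
  backbone carbons plus a carboxyl (O/O⁻ or O/OH) alternating sides
  along the chain; deprotonation −1 on the evenly spread pattern
  (alternate monomers at f = 0.5).  Chains lie radially outside the
  protein.
- **Planted contacts** — a designated chain is laid along the outward
  axis of a chosen residue so its first carboxyl oxygen sits exactly at
  the target distance and every other polymer atom is farther; the
  build verifies the global minimum and fails loudly if periodic
  wrapping defeats the construction.
- **Planted hydrogen bonds** — hydroxyl-like donor/acceptor sites are
  grafted radially outward on protein residues (fanned when one residue
  hosts several), or taken from carboxyl groups / 3-site waters; the
  acceptor is moved onto the D–H axis at 3.0 Å (HDA = 0°).
- **Solvent and ions** — water as single beads (mass 18.015) or an
  optional 3-site variant for donor tests; counterions inserted at
  uniform random clash-free positions to exact neutrality.
- **Box** — explicit boxes are validated against the protein bounding
  sphere + 2 nm; auto-sized boxes are fitted around protein and chains
  with 2 nm clearance per side, so radially laid chains cannot wrap
  onto the protein.
- **Dynamics** — frame 0 is the constructed geometry; subsequent frames
  add i.i.d. isotropic Gaussian jitter (σ configurable).  This is
  sufficient for averaging, fluctuation, and recovery statistics, and
  deliberately nothing like real dynamics: no correlations, no
  diffusion, no conformational kinetics.  Same seed ⇒ byte-identical
  output.

Passing tests on these systems demonstrate the *analysis machinery* —
classification, attribution, counting, normalization, periodic
geometry — not the physics of real complexation; trajectory-dependent
published numbers are not reproduced here, by design.

LJ defaults (σ 0.32/0.11 nm, ε 0.50/0.065 kJ/mol for heavy/H atoms) are
generic single-site values so that energetics has non-trivial input;
they are not a fitted force field.

## Analysis scripts

The `analysis/` drivers run two seeded conditions differing only in
jitter (0.004 vs 0.012 nm), 40 frames each, a 28-residue protein (one
10-residue helix, 6+6 antiparallel strands), two 10-monomer chains with
contacts planted on ARG (0.30 nm) and TYR (0.34 nm), 40 waters, and
counterions — sizes chosen so every script runs in seconds on one CPU.
The energy decomposition driver uses a helix/coil-only variant because
the idealized sheet packing would dominate intramolecular LJ sums with
a construction artifact.

## Known limitations

- The Coulomb decomposition is truncated real-space, not Ewald; absolute
  values are not comparable to mesh-Ewald group energies.
- DSSP here implements the classical pattern definitions; variants
  differ in π-helix precedence (flag provided) and PPII extensions (not
  implemented).
- SASA orientation dependence is bounded by quadrature (< 0.5% at 960
  points); per-atom decompositions beyond group totals are not exposed.
- The generator's bead water cannot donate hydrogen bonds unless the
  3-site variant is enabled; its geometry is rigid and random per
  molecule.
- GRO/XYZ readers accept concatenated frames with constant atom count;
  binary trajectory formats and triclinic cells are out of scope.
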