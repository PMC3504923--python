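# Methods

## Model and assumptions

`blindsurf` treats both molecules as rigid bodies.  The receptor is a fixed
set of typed point atoms; the ligand is an origin-centred reference
structure whose pose is a centroid translation plus a unit quaternion
(scalar-first `(w, x, y, z)`, right-handed active rotation, applied before
the translation).  Rigidity means intra-molecular energies are constants
and are excluded from the score; only receptor–ligand terms are evaluated.
Flexibility is supported only as an *ensemble* of rigid conformations
supplied by the user (a directory of MOL2/PDBQT files), screened
independently and aggregated by the element-wise per-spot minimum.

Blind search is organised around **spots**: one sphere per residue, centred
on its alpha carbon, default radius 10 Å.  No pruning is applied by
default — buried residues keep their spots and simply score poorly; an
optional greedy thinning (`min_spot_separation`) exists for very large
receptors.  External site predictors can replace the spot list entirely via
a plain `x y z [radius]` text file.

## Scoring function

Energies are kcal/mol, distances Å, charges elementary units.

* **ES** `Σ k·q_i·q_j/(ε(r)·r)` with `k = 332.06 kcal·Å/(mol·e²)`.  The
  dielectric is configurable: distance-dependent `ε(r) = 4r` (default, the
  convention in grid-based docking scoring) or constant.  This choice
  changes absolute energies; rank-based results are robust to it.
* **VDW** 12-6 Lennard-Jones, `σ_ij = √(σ_i σ_j)`, `ε_ij = √(ε_i ε_j)`
  (OPLS-style geometric means), summed over *all* receptor–ligand pairs in
  the DIRECT backend.
* **HBOND** a distance-only 12-10 well `ε_hb[5(r_eq/r)¹² − 6(r_eq/r)¹⁰]`
  between donor hydrogens and acceptor heavy atoms, defaults
  `r_eq = 1.9 Å`, `ε_hb = 5 kcal/mol`.  No angular factor: the term is a
  per-pair accumulation by design, and the pair set is *additional* to the
  VDW sum (both terms are evaluated for a donor/acceptor pair).
* Pair distances are clamped at a hard floor of 1e-6 Å, so coincident atoms
  produce huge-but-finite clash energies instead of infinities.

The packaged receptor parameter table (`data/oplslike.json`) is a
*simplified OPLS-like* set keyed by `(residue, atom name)` covering the
heavy atoms of the 20 standard amino acids, with generic element-based
types for ligands (SYBYL and AutoDock type names).  It is explicitly
swappable; lookups of unknown atoms raise rather than defaulting, with an
opt-in `skip_unknown` that drops and counts them.  Absolute energies from
this table are not comparable to other programs' scores — hotspot ranks,
poses and enrichment are the meaningful outputs.

## Grids

The GRID backend precomputes two lattices over a box enclosing the receptor
plus every reachable posed ligand atom (box = receptor/spot extents plus a
12 Å default padding):

* **ES grid** (default spacing d = 0.5 Å): the direct-summation potential
  tabulated at each node, with distances clamped below `r_min = 0.5 Å` so
  nodes inside atoms stay finite.  Poses are scored as
  `Σ_i q_i · φ(x_i)` with trilinear interpolation φ (scipy
  `RegularGridInterpolator`).  Interpolation is exact for affine fields;
  on random clash-free poses of the test systems the mean |grid − direct|
  ES error at d = 0.5 Å is ~3e-4 kcal/mol and the worst-case relative error
  is below 15%, shrinking monotonically with spacing (1.0 → 0.5 → 0.25 Å is
  asserted in the tests).  Near hard clashes the clamp, not interpolation,
  dominates — those poses are rejected by the VDW term anyway.
* **VDW neighbour-list grid** (default cell 2.0 Å, cutoff 8 Å): per cell,
  the indices of receptor atoms within `cutoff + half cell diagonal` of the
  cell centre — a superset of the atoms within the cutoff of *any* point in
  the cell, so the lists have no false negatives.  VDW/HBOND terms are then
  exact pairwise sums restricted to the query cell's list.  The gathered
  index matrix has a fixed width (the grid-wide maximum list length), which
  keeps per-pose floating-point reductions identical for every batch size —
  this is what makes batch results bit-reproducible.

Grid files (`.npz` with a JSON header) store the spec plus receptor and
force-field fingerprints; loading against a changed receptor or table is
refused unless forced.

## Monte Carlo engine

Defaults: 500 steps, 128 replicas per spot, max shift 1.0 Å per move, max
rotation 0.3 rad per move, temperature 0 (greedy).  Steps alternate move
types with rotation first (odd steps rotate, even steps translate).
Translation proposals are componentwise uniform in ±max_shift with the
centroid clamped back into the spot sphere by radial projection — this
preserves the attribution of results to spots.  Rotation proposals compose
a uniform-axis, uniform-angle (±max_rot) increment onto the pose quaternion
and renormalize.  Acceptance: ΔE ≤ 0 always (ties accepted); for T > 0,
uphill moves accepted with probability exp(−ΔE/T).  T = 0 reproduces pure
descent; the Metropolis limit is verified against the Boltzmann ratio on a
two-basin toy landscape.

Randomness is counter-addressable.  Each replica owns three private uniform
streams seeded by `SeedSequence(seed, spawn_key=(spot index, replica,
stream))`: initialization draws, proposal draws (a fixed 3-uniform slice
per step) and acceptance draws (one per step, consumed every step at
T > 0).  A rejected proposal's draws are discarded, never reused: reusing
them (a literal transcription of GPU random-state semantics, where the
global state is only updated on acceptance) makes each rejected replica
re-propose the same deterministic move and freeze under greedy acceptance,
so the engine advances the stream every step.  Consequences: runs are
bit-reproducible given (seed, config) and independent of `batch_spots`
partitioning and evaluation order, which is asserted in the tests.

Initialization draws centroids uniformly in the sphere and orientations
uniformly on SO(3) (Shoemake's method).  States above the `energy_cutoff`
clash threshold (default 100 kcal/mol) are re-drawn up to 20 times, then
kept but flagged.  The "500 steps" count proposals per replica (one move
per step), and the knob is exposed.

Per spot, the result is the exact arg-min over replica energies (ties break
to the lowest replica index), its pose, the full replica energy vector and
the acceptance rate.  Re-scoring the best pose reproduces its energy
bit-exactly with the same backend.

## Post-processing

Hotspots are ranked ascending by minimum total energy (stable ties).
Histograms default to Freedman–Diaconis binning with a fixed-bin override;
bins are recorded in the TSV header.  Pose RMSD is computed in the receptor
frame *without* superposition — docking RMSD must penalize placement error —
with an optional atom-map hook for symmetry-equivalent mappings.
Enrichment is ROC/AUC with lower energy = more active; ties are handled by
threshold grouping, making the AUC equal to the Mann–Whitney pair statistic
(cross-checked against a pair-counting oracle in the tests).  Exports:
best-pose PDBs for the top-k spots, a PyMOL bead script (one pseudoatom per
spot coloured by rank; `red_low` default maps red to the strongest spot,
`blue_low` inverts — both conventions appear in the literature), histogram
TSV, and a versioned JSON of all per-spot results.  All outputs are
byte-deterministic for a given run.

## Synthetic study systems

The fixture generator builds pseudo-atom receptors whose binding physics is
fully explicit, so tests exercise the real parsers and the search without
depending on protonation or typing heuristics.  Twelve residues (alpha
carbon + one weakly charged side atom, ±0.15 e alternating) sit on a 24 Å
ring with alternating ±1.5 Å z displacement — far enough apart that only
the pocket residue's sphere reaches the planted pose.  The pocket residue
carries a linear complementary site for a 3-atom dipolar probe (end charges
±0.6 e, 1.5 Å half-length): two charges of ±0.9 e placed 2.8 Å beyond the
designed tip positions, a neutral wall ring (radius 3 Å, 8 atoms) in each
charge's plane to block sideways contact, and axial caps shielding both
charges' outer faces, leaving the designed axial funnel as the only
low-energy approach.  The residue's alpha carbon sits 4.5 Å beside the
pocket mouth so its 10 Å spot covers every pocket atom.  Build-time
verification sweeps the analogous pose over every other spot and requires
the planted pose to win by ≥ 3 kcal/mol.  Decoy sets keep each active's
charge multiset but permute it onto the wrong spacing (the active pattern
and its end-to-end flip are excluded); actives jitter the charge magnitude
by ±15%.

What these fixtures do *not* emulate: real protein shape and chemistry
(desolvation, directional H-bond networks, torsional strain, tautomers),
crowded competing sub-sites, and score scales comparable to experimental
affinities.  Passing tests therefore demonstrate that the machinery —
surface decomposition, grids, scoring, stochastic search, ranking — is
correct and deterministic, not that the packaged parameter table is
predictive on real complexes.

## Problem sizes and defaults used in the shipped checks

The test-suite and `scripts/acceptance.py` run the full study conditions
(500 steps, 128 replicas/spot, d = 0.5 Å) on the 12-spot default fixture:
20 seeded recovery runs in the suite (10 in the script), a 5-active /
15-decoy enrichment screen, 100-pose grid-accuracy comparisons, and a 1e5
proposal Metropolis check with 8 replicas (burn-in 20%, error estimated
across independent replicas).  These sizes were chosen to give stable
statistics at desk scale.

## Known limitations

* No solvation, metals or aromatic-interaction terms; no receptor
  flexibility; no internal torsional conformer generation.
* The HBOND term is distance-only; heavy-atom-only receptors (no polar
  hydrogens) score zero HBOND by construction.
* The distance-dependent dielectric plus node clamping makes grid ES
  inaccurate inside clash regions (by design, those poses are rejected by
  VDW).
* The packaged parameter table is a pragmatic reconstruction; for serious
  use supply your own table via `[forcefield] table`.
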