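# blindsurf

Blind virtual screening over a whole receptor surface on the CPU.

Most docking tools require you to say *where* the binding site is.
`blindsurf` does not: it decomposes the entire surface of a rigid receptor
into spherical search regions ("spots"), one per residue, centred on each
alpha carbon with a 10 Å cutoff radius, and runs an independent batch of
Monte Carlo rigid-body docking replicas in every spot simultaneously.  The
per-spot energy minima rank candidate binding hotspots; the arg-min replica
of each spot is its best-scoring ligand pose.  Typical uses: binding-site
hypothesis generation for targets with unknown or multiple sites, and fast
pre-screening of ligand libraries before a more detailed docking method is
applied at the discovered site.

## Method

A pose of a rigid ligand is a translation **s** of its centroid plus a unit
quaternion **q** (scalar-first, active rotation about the centroid):
atom *i* sits at `x_i = R(q)·c_i + s`, where `c_i` are the origin-centred
reference coordinates.  Poses are scored by a three-term interaction energy
(kcal/mol, lower = stronger predicted binding):

    E = ES + VDW + HBOND
    ES    = Σ_ij  k·q_i·q_j / (ε(r_ij)·r_ij)          k = 332.06 kcal·Å/(mol·e²)
    VDW   = Σ_ij  4·ε_ij [ (σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶ ]
    HBOND = Σ_{donor-H, acceptor}  ε_hb [ 5(r_eq/r)¹² − 6(r_eq/r)¹⁰ ]

with geometric-mean combining rules and, by default, the distance-dependent
dielectric ε(r) = 4r.  Two scoring backends are provided: **DIRECT** (exact
all-pairs summation) and **GRID** — the production path — which tabulates
the receptor's electrostatic potential on a 0.5 Å lattice once (queried by
trilinear interpolation, one lookup per ligand atom) and restricts VDW/HBOND
sums to precomputed per-cell receptor-atom neighbour lists.

In each spot, 128 replicas are initialized uniformly in the sphere and
minimized for 500 steps, alternating random rotations (odd steps) and
translations (even steps, centroid clamped into the sphere).  Moves that
lower the energy are always accepted; at temperature T > 0 uphill moves are
accepted with the Metropolis probability exp(−ΔE/T) (default T = 0, greedy).
Replica random streams are keyed by (seed, spot, replica), so results are
bit-reproducible and independent of how spots are batched.

## Worked example

The package ships a generator for synthetic pseudo-atom receptors with a
*planted* pocket whose location and ligand pose are known by construction —
every stage (PDB/MOL2 parsing, typing, grids, search) runs on real files:

```
blindsurf fixture --out fix                 # receptor.pdb, probe_active.mol2, ...
blindsurf screen --receptor fix/receptor.pdb --ligand fix/probe_active.mol2 \
                 --config conf.toml --seed 4 --out out
blindsurf report --results out/results.json --top 3
```

where `conf.toml` points `[forcefield] table` at the fixture's parameter
file.  This prints:

```
probe_active: best spot A:FXP1 total -11.398 kcal/mol -> out
ligand probe_active (grid kernel, seed 4)
  1  A:FXP1           total   -11.398 (es -9.524, vdw -1.874, hb 0.000)
  2  A:FXB12          total    -1.814 (es -1.001, vdw -0.813, hb 0.000)
  3  A:FXB2           total    -1.785 (es -1.016, vdw -0.769, hb 0.000)
```

Spot `A:FXP1` is the pocket residue: the planted site is found as the
clear hotspot, ~9.6 kcal/mol below every other spot, with the electrostatic
complementarity dominating the score.  The output directory holds the
best-pose PDB per top-ranked spot, a PyMOL bead script colouring every spot
by rank, the score histogram as TSV and a machine-readable `results.json`.

For real structures, `read_receptor` types atoms from a packaged simplified
OPLS-like table keyed by residue and atom name (swappable via
`[forcefield] table`); ligands are MOL2 (with charges) or PDBQT.

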