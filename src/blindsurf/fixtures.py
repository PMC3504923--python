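"""Deterministic synthetic receptors and ligands with a planted binding pocket.

The generator builds pseudo-atom "proteins" that exercise every stage of the
pipeline — PDB/MOL2 parsing, typing from a parameter table, spot
generation, grids, scoring and the Monte Carlo search — with a binding site
whose location and pose are known by construction:

* Residues sit on a ring (alternating z) far enough apart that only the
  pocket residue's spot sphere can reach the planted pose.
* The pocket residue carries two charges complementary to a linear dipolar
  probe ligand, placed symmetrically about the designed pose so the energy
  funnel is centred on it, plus neutral "wall" atoms for lateral packing.
* All other residues are neutral or weakly charged, so the pocket is the
  designed global minimum; this is verified at build time by an exhaustive
  direct-summation sweep over all spot centres.

These are not chemically valid proteins; every scoring input (coordinates,
charges, LJ parameters, H-bond roles) is explicit in the emitted files, so
tests depend only on the physics implemented here, not on protonation or
typing heuristics.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import geometry
from .forcefield import ForceField
from .molecules import read_ligand, read_receptor, write_mol2
from .scoring import score_direct
from .spots import generate_spots

__all__ = [
    "FixtureSpec",
    "FixturePaths",
    "fixture_forcefield",
    "make_receptor",
    "make_probe",
    "make_decoy_set",
    "make_fixture_set",
    "FixtureError",
]


class FixtureError(RuntimeError):
    """The generated fixture failed its built-in complementarity check."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-pocket toy system.

    ``n_residues`` pseudo-residues on a ring of radius ``ring_radius`` Å with
    alternating z displacement; the residue at ``pocket_index`` carries the
    complementary site, with the designed probe centroid ``pocket_offset`` Å
    outward from its alpha carbon.  The probe is a linear 3-atom dipole of
    half-length ``probe_half_length`` Å and end charges ±``probe_charge`` e.
    ``margin`` is the minimum energy gap (kcal/mol) the planted pose must
    have over every other spot centre, verified at build time.
    """

    n_residues: int = 12
    ring_radius: float = 24.0
    z_amplitude: float = 1.5
    pocket_index: int = 0
    pocket_offset: float = 5.0
    probe_charge: float = 0.6
    probe_half_length: float = 1.5
    pocket_charge: float = 0.9
    pocket_gap: float = 2.8     # Å from probe tip to its complementary charge
    margin: float = 3.0
    seed: int = 0


@dataclass(frozen=True)
class FixturePaths:
    receptor: Path
    forcefield: Path
    reference_pose: Path
    probe: Path


def fixture_forcefield(spec: FixtureSpec) -> ForceField:
    """Explicit parameter table for the pseudo-atom residues and probes."""
    lj = {
        "FCA": (3.5, 0.05),   # alpha-carbon pseudo atom
        "FSD": (3.2, 0.05),   # side pseudo atom
        "FPK": (2.0, 0.05),   # pocket charge atom (small radius: sits close)
        "FWL": (3.2, 0.12),   # pocket wall atom
        "PRB": (3.4, 0.10),   # probe ligand atom
    }
    q = spec.pocket_charge
    residue_atoms = {
        "FXA:CA": ["FCA", 0.0, "none"],
        "FXA:SD": ["FSD", 0.15, "none"],
        "FXB:CA": ["FCA", 0.0, "none"],
        "FXB:SD": ["FSD", -0.15, "none"],
        "FXP:CA": ["FCA", 0.0, "none"],
        # P1 is the outer site (faces the probe's -q tip), P2 the inner one
        "FXP:P1": ["FPK", q, "none"],
        "FXP:P2": ["FPK", -q, "none"],
    }
    for w in range(1, 19):
        residue_atoms[f"FXP:W{w}"] = ["FWL", 0.0, "none"]
    return ForceField(
        lj_params=lj,
        residue_table=residue_atoms,
        ligand_type_map={"Prb": ("PRB", "none")},
        hb_params=(1.90, 5.0),
        dielectric_model="distance",
    )


def _pocket_geometry(spec: FixtureSpec):
    """Alpha carbons, outward unit at the pocket, and the designed pose.

    The pocket residue's alpha carbon sits beside the pocket mouth (offset
    out of the ring plane) rather than on the ring, so its 10 Å spot sphere
    covers every pocket atom while staying clear of the probe's entry path.
    """
    theta = 2.0 * np.pi * np.arange(spec.n_residues) / spec.n_residues
    z = spec.z_amplitude * np.where(np.arange(spec.n_residues) % 2 == 0, 1.0, -1.0)
    ca = np.stack([spec.ring_radius * np.cos(theta),
                   spec.ring_radius * np.sin(theta), z], axis=1)
    p = spec.pocket_index % spec.n_residues
    u = np.array([np.cos(theta[p]), np.sin(theta[p]), 0.0])
    anchor = np.array([spec.ring_radius * np.cos(theta[p]),
                       spec.ring_radius * np.sin(theta[p]), 0.0])
    centroid = anchor + spec.pocket_offset * u
    ca[p] = centroid + np.array([0.0, 0.0, 4.5])
    # quaternion rotating the probe's reference axis (+z) onto u
    zaxis = np.array([0.0, 0.0, 1.0])
    axis = np.cross(zaxis, u)
    axis /= np.linalg.norm(axis)
    angle = float(np.arccos(np.clip(np.dot(zaxis, u), -1.0, 1.0)))
    quat = geometry.axis_angle_quat(axis, angle)
    return ca, p, u, centroid, quat


def _probe_ref_coords(spec: FixtureSpec) -> np.ndarray:
    h = spec.probe_half_length
    return np.array([[0.0, 0.0, -h], [0.0, 0.0, 0.0], [0.0, 0.0, h]])


def _probe_charges(spec: FixtureSpec) -> np.ndarray:
    # +q at the -z end, -q at the +z end: the pose quaternion maps +z to the
    # outward pocket axis, so the -q tip faces the outer (+q-complementary) site.
    return np.array([spec.probe_charge, 0.0, -spec.probe_charge])


def _pdb_atom_line(serial, name, resname, resseq, coord, element="C"):
    return (f"ATOM  {serial:>5}  {name:<3} {resname:>3} A{resseq:>4}    "
            f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}  1.00  0.00"
            f"          {element:>2}")


def make_receptor(spec: FixtureSpec, out_dir) -> FixturePaths:
    """Write the fixture receptor PDB, parameter table, probe MOL2 and the
    ground-truth pose, verifying the planted pocket is the designed global
    minimum by a brute-force sweep over all other spot centres."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ca, p, u, centroid, quat = _pocket_geometry(spec)

    lines = []
    serial = 1
    for i in range(spec.n_residues):
        if i == p:
            resname = "FXP"
            atoms = [("CA", ca[i])]
            sign_gap = spec.pocket_gap + spec.probe_half_length
            p1 = centroid + sign_gap * u
            p2 = centroid - sign_gap * u
            atoms.append(("P1", p1))
            atoms.append(("P2", p2))
            # a neutral wall ring in each charge's plane blocks sideways
            # contact with the charge while leaving the axial funnel open;
            # the cap shields the outer charge's solvent face
            v = np.array([-u[1], u[0], 0.0])
            w = np.array([0.0, 0.0, 1.0])
            ring = [v, -v, w, -w]
            ring += [(a + b) / np.sqrt(2.0) for a in (v, -v) for b in (w, -w)]
            k = 1
            for site in (p1, p2):
                for d in ring:
                    atoms.append((f"W{k}", site + 3.0 * d))
                    k += 1
            atoms.append((f"W{k}", p1 + 3.2 * u))
            atoms.append((f"W{k + 1}", p2 - 3.2 * u))
        else:
            resname = "FXA" if i % 2 == 0 else "FXB"
            outward = np.array([np.cos(2 * np.pi * i / spec.n_residues),
                                np.sin(2 * np.pi * i / spec.n_residues), 0.0])
            atoms = [("CA", ca[i]), ("SD", ca[i] + 2.0 * outward)]
        for name, coord in atoms:
            lines.append(_pdb_atom_line(serial, name, resname, i + 1, coord))
            serial += 1
    lines.append("END")
    receptor_path = out / "receptor.pdb"
    receptor_path.write_text("\n".join(lines) + "\n")

    ff = fixture_forcefield(spec)
    ff_path = out / "fixture_ff.json"
    ff.to_json(ff_path)

    probe_path = out / "probe_active.mol2"
    planted_coords = geometry.rotate_vectors(quat, _probe_ref_coords(spec)) + centroid
    write_mol2(probe_path, planted_coords, _probe_charges(spec),
               ["Prb"] * 3, names=["P1", "P2", "P3"], mol_name="PROBE")

    ref_path = out / "reference_pose.json"
    ref_path.write_text(json.dumps({
        "shift": [float(x) for x in centroid],
        "quat": [float(x) for x in quat],
        "coords": [[float(x) for x in row] for row in planted_coords],
        "pocket_spot_index": int(p),
    }, indent=1, sort_keys=True) + "\n")

    _verify_complementarity(spec, receptor_path, ff, probe_path, planted_coords, p)
    return FixturePaths(receptor=receptor_path, forcefield=ff_path,
                        reference_pose=ref_path, probe=probe_path)


def _verify_complementarity(spec, receptor_path, ff, probe_path, planted_coords, p):
    """Brute-force sweep: at every other spot, try the analogous offset pose in
    both axial orientations; the planted pose must win by the stated margin."""
    receptor = read_receptor(receptor_path, ff)
    probe = read_ligand(probe_path, ff)
    planted = score_direct(receptor, planted_coords, probe, ff).total
    spots = generate_spots(receptor)
    zaxis = np.array([0.0, 0.0, 1.0])
    for i, spot in enumerate(spots):
        if i == p:
            continue
        u = spot.center * np.array([1.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        centroid = spot.center + spec.pocket_offset * u
        best = np.inf
        for sign in (1.0, -1.0):
            axis = np.cross(zaxis, sign * u)
            axis /= np.linalg.norm(axis)
            angle = float(np.arccos(np.clip(np.dot(zaxis, sign * u), -1.0, 1.0)))
            quat = geometry.axis_angle_quat(axis, angle)
            coords = geometry.rotate_vectors(quat, probe.ref_coords) + centroid
            best = min(best, score_direct(receptor, coords, probe, ff).total)
        if planted > best - spec.margin:
            raise FixtureError(
                f"planted pose ({planted:.2f} kcal/mol) is not at least "
                f"{spec.margin} kcal/mol below spot {spot.spot_id} ({best:.2f})"
            )


def make_probe(spec: FixtureSpec, path, charges=None, mol_name="PROBE") -> Path:
    """Write a probe MOL2 at the origin with the given (or active) charges."""
    path = Path(path)
    q = _probe_charges(spec) if charges is None else np.asarray(charges, dtype=float)
    write_mol2(path, _probe_ref_coords(spec), q, ["Prb"] * 3,
               names=["P1", "P2", "P3"], mol_name=mol_name)
    return path


def make_decoy_set(spec: FixtureSpec, n_actives: int, n_decoys: int, out_dir):
    """Actives (pocket-complementary dipoles) and charge-scrambled decoys.

    Actives keep the designed ``(+q, 0, -q)`` charge order with the magnitude
    jittered; decoys permute the same charge multiset so the dipole no longer
    matches the pocket's charge spacing.  Returns (ligand paths, labels,
    label-file path); labels are 1 for actives, 0 for decoys.
    """
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    # permutations of (+q, 0, -q) whose charge spacing mismatches the pocket:
    decoy_patterns = [(0, 1, -1), (1, -1, 0), (-1, 1, 0), (0, -1, 1)]
    paths, labels = [], []
    for k in range(n_actives):
        q = spec.probe_charge * (0.85 + 0.3 * rng.random())
        p = make_probe(spec, out / f"active_{k:02d}.mol2",
                       charges=[q, 0.0, -q], mol_name=f"ACT{k}")
        paths.append(p)
        labels.append(1)
    for k in range(n_decoys):
        q = spec.probe_charge * (0.85 + 0.3 * rng.random())
        pat = decoy_patterns[int(rng.integers(len(decoy_patterns)))]
        p = make_probe(spec, out / f"decoy_{k:02d}.mol2",
                       charges=[q * s for s in pat], mol_name=f"DEC{k}")
        paths.append(p)
        labels.append(0)
    label_path = out / "labels.tsv"
    label_path.write_text(
        "file\tlabel\n" + "\n".join(f"{p.name}\t{l}" for p, l in zip(paths, labels)) + "\n"
    )
    return paths, labels, label_path


def make_fixture_set(out_dir, spec: FixtureSpec = FixtureSpec()):
    """Convenience: receptor + parameter table + probe; returns loaded objects."""
    paths = make_receptor(spec, out_dir)
    ff = ForceField.from_json(paths.forcefield)
    receptor = read_receptor(paths.receptor, ff)
    probe = read_ligand(paths.probe, ff)
    reference = json.loads(paths.reference_pose.read_text())
    return receptor, probe, ff, reference, paths
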