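"""Molecular structure I/O and the rigid ligand pose model.

Receptors are read from PDB (first MODEL, protein ATOM records only) and
typed/charged from a :class:`~blindsurf.forcefield.ForceField` table keyed by
residue and atom name.  Ligands are read from MOL2 (``@<TRIPOS>ATOM`` block,
charges column required) or the PDBQT dialect, and are re-centred so the
search engine can represent any pose as *(translation of the centroid, unit
quaternion about the centroid)*.

Both the receptor and the ligand are rigid: the receptor's coordinate arrays
are frozen after load, and a pose never mutates the ligand model — it maps
the origin-centred reference coordinates to absolute coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from . import geometry
from .forcefield import ForceField, ForceFieldError

__all__ = [
    "Atom",
    "Receptor",
    "LigandModel",
    "read_receptor",
    "read_ligand",
    "write_mol2",
    "apply_pose",
    "apply_poses",
    "MoleculeError",
]

_CENTROID_TOL = 1e-9


class MoleculeError(ValueError):
    """Unreadable or inconsistent molecular input."""


@dataclass(frozen=True)
class Atom:
    """One typed, charged atom."""

    element: str
    coord: np.ndarray          # (3,) Å
    charge: float              # e
    lj_type: str
    hb_role: str               # "donor-H" | "acceptor" | "none"
    residue_id: str            # chain + resseq + icode
    name: str

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise MoleculeError(f"atom {self.name}: bad coordinate {self.coord!r}")
        if not np.isfinite(self.charge):
            raise MoleculeError(f"atom {self.name}: non-finite charge")
        object.__setattr__(self, "coord", coord)


def _frozen(a: np.ndarray) -> np.ndarray:
    a = np.ascontiguousarray(a)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class Receptor:
    """Rigid receptor: typed atoms plus per-residue alpha-carbon coordinates.

    The parallel numeric arrays (``coords``, ``charges``, ``sigmas`` ...) are
    resolved once at construction and marked read-only; scoring code indexes
    them directly.
    """

    atoms: tuple
    coords: np.ndarray         # (N, 3)
    charges: np.ndarray        # (N,)
    sigmas: np.ndarray         # (N,)
    epsilons: np.ndarray       # (N,)
    is_acceptor: np.ndarray    # (N,) bool
    is_donor_h: np.ndarray     # (N,) bool
    calpha_coords: np.ndarray  # (n_res, 3)
    calpha_ids: tuple          # residue id per alpha carbon
    n_skipped: int = 0

    @classmethod
    def from_atoms(cls, atoms, ff: ForceField, calpha_coords, calpha_ids,
                   n_skipped: int = 0) -> "Receptor":
        atoms = tuple(atoms)
        if len(calpha_ids) == 0:
            raise MoleculeError("receptor has no alpha carbons")
        se = np.array([ff.sigma_epsilon(a.lj_type) for a in atoms], dtype=float).reshape(-1, 2)
        roles = [a.hb_role for a in atoms]
        return cls(
            atoms=atoms,
            coords=_frozen(np.array([a.coord for a in atoms], dtype=float).reshape(-1, 3)),
            charges=_frozen(np.array([a.charge for a in atoms], dtype=float)),
            sigmas=_frozen(se[:, 0]),
            epsilons=_frozen(se[:, 1]),
            is_acceptor=_frozen(np.array([r == "acceptor" for r in roles])),
            is_donor_h=_frozen(np.array([r == "donor-H" for r in roles])),
            calpha_coords=_frozen(np.array(calpha_coords, dtype=float).reshape(-1, 3)),
            calpha_ids=tuple(calpha_ids),
            n_skipped=n_skipped,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.calpha_ids)

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.round(self.coords, 6).tobytes())
        h.update(np.round(self.charges, 6).tobytes())
        h.update(np.round(self.sigmas, 6).tobytes())
        h.update(np.round(self.epsilons, 6).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class LigandModel:
    """Origin-centred rigid ligand: reference coordinates plus parameters.

    ``ref_coords`` have zero centroid; the original input centroid is kept so
    absolute poses in the receptor frame can be reproduced from file input.
    """

    ref_coords: np.ndarray     # (n, 3), centroid == origin
    charges: np.ndarray        # (n,)
    lj_types: tuple
    hb_roles: tuple
    sigmas: np.ndarray
    epsilons: np.ndarray
    is_acceptor: np.ndarray
    is_donor_h: np.ndarray
    names: tuple
    elements: tuple
    input_centroid: np.ndarray  # (3,) centroid of the source file coordinates
    source: str = ""

    def __post_init__(self):
        c = self.ref_coords.mean(axis=0)
        if not np.all(np.abs(c) < 1e-6):
            raise MoleculeError(f"ligand model not centred: centroid {c}")
        n = self.nlig
        for name in ("charges", "lj_types", "hb_roles", "names", "elements"):
            if len(getattr(self, name)) != n:
                raise MoleculeError(f"ligand field {name} length != {n}")

    @property
    def nlig(self) -> int:
        return int(self.ref_coords.shape[0])

    @classmethod
    def from_arrays(cls, coords, charges, lj_types, hb_roles, ff: ForceField,
                    names=None, elements=None, source: str = "") -> "LigandModel":
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        centroid = coords.mean(axis=0)
        ref = coords - centroid
        # re-centre exactly: remove any residual from the subtraction
        ref = ref - ref.mean(axis=0)
        n = ref.shape[0]
        names = tuple(names) if names is not None else tuple(f"A{i+1}" for i in range(n))
        elements = tuple(elements) if elements is not None else tuple(t.split(".")[0][:2] for t in lj_types)
        se = np.array([ff.sigma_epsilon(t) for t in lj_types], dtype=float).reshape(-1, 2)
        roles = tuple(hb_roles)
        return cls(
            ref_coords=_frozen(ref),
            charges=_frozen(np.asarray(charges, dtype=float)),
            lj_types=tuple(lj_types),
            hb_roles=roles,
            sigmas=_frozen(se[:, 0]),
            epsilons=_frozen(se[:, 1]),
            is_acceptor=_frozen(np.array([r == "acceptor" for r in roles])),
            is_donor_h=_frozen(np.array([r == "donor-H" for r in roles])),
            names=names,
            elements=elements,
            input_centroid=_frozen(np.asarray(centroid, dtype=float)),
            source=source,
        )


# ---------------------------------------------------------------------------
# Receptor input
# ---------------------------------------------------------------------------

def read_receptor(path, ff: ForceField, *, skip_unknown: bool = False) -> Receptor:
    """Read a PDB receptor, typing and charging every atom from *ff*.

    Only protein ``ATOM`` records of the first MODEL are used; HETATM ligands
    and waters are excluded.  An atom absent from the parameter table is
    fatal (naming residue and atom) unless ``skip_unknown`` is set, in which
    case it is dropped and counted in ``Receptor.n_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(path))
    models = list(structure)
    if not models:
        raise MoleculeError(f"{path}: no MODEL in PDB file")
    model = models[0]

    atoms, calpha_coords, calpha_ids = [], [], []
    n_skipped = 0
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag.strip():  # HETATM (ligands, waters, ions)
                continue
            resname = residue.get_resname().strip()
            rid = f"{chain.id}:{resname}{resseq}{icode.strip()}"
            ca = None
            for atom in residue:
                # altloc: keep the first/blank location only
                if atom.get_altloc() not in (" ", "A", ""):
                    continue
                name = atom.get_name().strip()
                try:
                    lj_type, charge, hb_role = ff.residue_atom(resname, name)
                except ForceFieldError as exc:
                    if skip_unknown:
                        n_skipped += 1
                        continue
                    raise ForceFieldError(
                        f"{path.name}: residue {rid}: {exc.args[0]} "
                        "(pass skip_unknown=True to drop untyped atoms)"
                    ) from None
                a = Atom(
                    element=(atom.element or name[:1]).strip(),
                    coord=atom.get_coord().astype(float),
                    charge=float(charge),
                    lj_type=lj_type,
                    hb_role=hb_role,
                    residue_id=rid,
                    name=name,
                )
                atoms.append(a)
                if name == "CA":
                    ca = a.coord
            if ca is not None:
                calpha_coords.append(ca)
                calpha_ids.append(rid)
            else:
                warnings.warn(f"{path.name}: residue {rid} has no alpha carbon; "
                              "no surface spot will be generated for it")
    if not calpha_ids:
        raise MoleculeError(f"{path}: no alpha carbons found")
    return Receptor.from_atoms(atoms, ff, calpha_coords, calpha_ids, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Ligand input / output
# ---------------------------------------------------------------------------

def read_ligand(path, ff: ForceField) -> LigandModel:
    """Read a MOL2 or PDBQT ligand into an origin-centred rigid model.

    Charges are taken from the file (MOL2 charge column / PDBQT partial
    charge field); a file without charges is an error, since the parameter
    table does not assign ligand charges.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        return _read_mol2(path, ff)
    if suffix == ".pdbqt":
        return _read_pdbqt(path, ff)
    raise MoleculeError(f"{path}: unsupported ligand format {suffix!r} (use .mol2 or .pdbqt)")


def _read_mol2(path: Path, ff: ForceField) -> LigandModel:
    coords, charges, lj_types, hb_roles, names, elements = [], [], [], [], [], []
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("@<TRIPOS>"):
                section = line[9:].upper()
                continue
            if section != "ATOM" or not line:
                continue
            parts = line.split()
            if len(parts) < 6:
                raise MoleculeError(f"{path.name}:{lineno}: unparseable MOL2 atom line: {line!r}")
            if len(parts) < 9:
                raise MoleculeError(
                    f"{path.name}:{lineno}: MOL2 atom line has no charge column "
                    "and the force field cannot supply ligand charges"
                )
            name, x, y, z, atype = parts[1], parts[2], parts[3], parts[4], parts[5]
            try:
                coords.append((float(x), float(y), float(z)))
                charges.append(float(parts[8]))
            except ValueError:
                raise MoleculeError(f"{path.name}:{lineno}: bad numeric field in {line!r}") from None
            lj_type, hb_role = ff.ligand_type(atype)
            lj_types.append(lj_type)
            hb_roles.append(hb_role)
            names.append(name)
            elements.append(atype.split(".")[0])
    if not coords:
        raise MoleculeError(f"{path.name}: no @<TRIPOS>ATOM records")
    return LigandModel.from_arrays(coords, charges, lj_types, hb_roles, ff,
                                   names=names, elements=elements, source=str(path))


def _read_pdbqt(path: Path, ff: ForceField) -> LigandModel:
    coords, charges, lj_types, hb_roles, names, elements = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                name = line[12:16].strip()
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                charge = float(line[70:76])
                atype = line[77:79].strip()
            except (ValueError, IndexError):
                raise MoleculeError(f"{path.name}:{lineno}: unparseable PDBQT atom line") from None
            lj_type, hb_role = ff.ligand_type(atype)
            coords.append(xyz)
            charges.append(charge)
            lj_types.append(lj_type)
            hb_roles.append(hb_role)
            names.append(name)
            elements.append(atype[:1])
    if not coords:
        raise MoleculeError(f"{path.name}: no ATOM/HETATM records")
    return LigandModel.from_arrays(coords, charges, lj_types, hb_roles, ff,
                                   names=names, elements=elements, source=str(path))


def write_mol2(path, coords, charges, sybyl_types, names=None, mol_name="LIG") -> None:
    """Write a minimal MOL2 file (atoms only, no bonds).

    Coordinates keep format precision (4 decimals); charges are written with
    shortest-exact decimal representation so they round-trip bit-exactly.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    names = names or [f"A{i+1}" for i in range(n)]
    lines = [
        "@<TRIPOS>MOLECULE",
        mol_name,
        f"{n} 0 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i in range(n):
        q = np.format_float_positional(float(charges[i]), unique=True, trim="0")
        lines.append(
            f"{i+1:>5} {names[i]:<4} {coords[i,0]:>10.4f} {coords[i,1]:>10.4f} "
            f"{coords[i,2]:>10.4f} {sybyl_types[i]:<6} 1 {mol_name} {q}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Poses
# ---------------------------------------------------------------------------

def apply_pose(model: LigandModel, shift, quat) -> np.ndarray:
    """Absolute atom coordinates for one pose: ``R(quat)·ref + shift``.

    The rotation acts about the origin (the ligand centroid), then the shift
    translates the centroid to ``shift``.  *quat* must be unit length within
    1e-9.
    """
    quat = np.asarray(quat, dtype=float)
    geometry.check_unit(quat)
    return geometry.rotate_vectors(quat, model.ref_coords) + np.asarray(shift, dtype=float)


def apply_poses(model: LigandModel, shifts, quats) -> np.ndarray:
    """Vectorized :func:`apply_pose`: ``(P, 3)`` shifts + ``(P, 4)`` quats -> ``(P, n, 3)``."""
    shifts = np.asarray(shifts, dtype=float).reshape(-1, 3)
    quats = np.asarray(quats, dtype=float).reshape(-1, 4)
    geometry.check_unit(quats)
    return geometry.rotate_vectors(quats, model.ref_coords) + shifts[:, None, :]
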