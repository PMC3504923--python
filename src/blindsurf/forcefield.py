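"""Force-field parameter tables for the ES + VDW + HBOND scoring function.

The scoring function ranks rigid ligand poses against a rigid receptor by a
sum of three non-bonded terms:

* **ES** — Coulomb electrostatics ``k·q_i·q_j / (ε(r)·r)`` with a selectable
  dielectric model: constant ``ε`` or the distance-dependent screening
  ``ε(r) = 4r`` conventional in grid-based docking scoring.
* **VDW** — 12-6 Lennard-Jones with geometric-mean combining rules for both
  ``σ`` and ``ε`` (OPLS convention).
* **HBOND** — a distance-only 12-10 well between donor hydrogens and
  acceptor heavy atoms, ``ε_hb·[5(r_eq/r)^12 − 6(r_eq/r)^10]``.

The packaged parameter table (``data/oplslike.json``) is a simplified
OPLS-like set keyed by ``(residue name, atom name)`` for receptor atoms and
by SYBYL/AutoDock atom types for ligand atoms.  It is deliberately
swappable: any table with the same JSON schema can be supplied, and lookups
of unknown atoms raise instead of defaulting silently.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["ForceField", "ForceFieldError", "COULOMB_CONSTANT"]

#: Conventional biomolecular Coulomb constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.06


class ForceFieldError(KeyError):
    """An atom or atom type has no entry in the loaded parameter table."""


@dataclass(frozen=True)
class ForceField:
    """Immutable parameter set resolving atoms to charges and LJ/H-bond terms.

    Parameters
    ----------
    lj_params
        Map atom-type key -> ``(sigma [Å], epsilon [kcal/mol])``.
    residue_table
        Map ``"RESNAME:ATOMNAME"`` -> ``(lj_type, charge [e], hb_role)`` for
        receptor atoms read from PDB files.
    ligand_type_map
        Map input atom type (SYBYL ``C.3`` ... or AutoDock ``OA`` ...) ->
        ``(lj_type, hb_role)`` for ligand atoms.
    hb_params
        ``(r_eq [Å], well depth [kcal/mol])`` of the 12-10 H-bond term.
    dielectric_model
        ``"distance"`` for ``ε(r) = 4r`` or ``"constant"``.
    """

    lj_params: dict = field(default_factory=dict)
    residue_table: dict = field(default_factory=dict)
    ligand_type_map: dict = field(default_factory=dict)
    hb_params: tuple = (1.90, 5.0)
    dielectric_model: str = "distance"
    dielectric_constant: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT

    def __post_init__(self):
        for key, (sigma, eps) in self.lj_params.items():
            if not sigma > 0:
                raise ValueError(f"LJ type {key!r}: sigma must be > 0, got {sigma}")
            if eps < 0:
                raise ValueError(f"LJ type {key!r}: epsilon must be >= 0, got {eps}")
        if self.dielectric_model not in ("distance", "constant"):
            raise ValueError(f"unknown dielectric model {self.dielectric_model!r}")
        r_eq, depth = self.hb_params
        if not (r_eq > 0 and depth >= 0):
            raise ValueError(f"invalid hb_params {self.hb_params!r}")

    # -- lookups ----------------------------------------------------------

    def residue_atom(self, resname: str, atomname: str):
        """``(lj_type, charge, hb_role)`` for a receptor atom; raises if absent."""
        key = f"{resname.upper()}:{atomname.upper()}"
        try:
            return tuple(self.residue_table[key])
        except KeyError:
            raise ForceFieldError(
                f"no force-field entry for receptor atom {atomname!r} "
                f"in residue {resname!r} (table key {key!r})"
            ) from None

    def ligand_type(self, atom_type: str):
        """``(lj_type, hb_role)`` for a ligand atom type; raises if absent."""
        for key in (atom_type, atom_type.split(".")[0]):
            if key in self.ligand_type_map:
                return tuple(self.ligand_type_map[key])
        raise ForceFieldError(f"no force-field entry for ligand atom type {atom_type!r}")

    def sigma_epsilon(self, lj_type: str):
        try:
            return tuple(self.lj_params[lj_type])
        except KeyError:
            raise ForceFieldError(f"unknown LJ atom type {lj_type!r}") from None

    # -- physics helpers --------------------------------------------------

    def dielectric_times_r(self, r):
        """``ε(r)·r`` so the Coulomb energy is ``k·q_i·q_j / dielectric_times_r(r)``."""
        if self.dielectric_model == "distance":
            return 4.0 * r * r
        return self.dielectric_constant * r

    # -- identity ---------------------------------------------------------

    def fingerprint(self) -> str:
        """Stable hash of the full parameter set, used to invalidate cached grids."""
        payload = json.dumps(
            {
                "lj": {k: list(v) for k, v in sorted(self.lj_params.items())},
                "res": {k: list(v) for k, v in sorted(self.residue_table.items())},
                "lig": {k: list(v) for k, v in sorted(self.ligand_type_map.items())},
                "hb": list(self.hb_params),
                "diel": [self.dielectric_model, self.dielectric_constant],
                "k": self.coulomb_constant,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        diel = d.get("dielectric", {})
        return cls(
            lj_params={k: tuple(v) for k, v in d["lj_types"].items()},
            residue_table={k: tuple(v) for k, v in d.get("residue_atoms", {}).items()},
            ligand_type_map={k: tuple(v) for k, v in d.get("ligand_types", {}).items()},
            hb_params=tuple(d.get("hbond", (1.90, 5.0))),
            dielectric_model=diel.get("model", "distance"),
            dielectric_constant=float(diel.get("constant", 1.0)),
            coulomb_constant=float(d.get("coulomb_constant", COULOMB_CONSTANT)),
        )

    @classmethod
    def from_json(cls, path) -> "ForceField":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "lj_types": {k: list(v) for k, v in self.lj_params.items()},
            "residue_atoms": {k: list(v) for k, v in self.residue_table.items()},
            "ligand_types": {k: list(v) for k, v in self.ligand_type_map.items()},
            "hbond": list(self.hb_params),
            "dielectric": {
                "model": self.dielectric_model,
                "constant": self.dielectric_constant,
            },
            "coulomb_constant": self.coulomb_constant,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def default(cls) -> "ForceField":
        """The packaged simplified OPLS-like table."""
        ref = resources.files("blindsurf.data").joinpath("oplslike.json")
        return cls.from_dict(json.loads(ref.read_text()))

    def replace(self, **kw) -> "ForceField":
        from dataclasses import replace as _replace

        return _replace(self, **kw)
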