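"""TOML run configuration mirroring the classic four-section input file:
molecular data, force-field data, Monte Carlo minimization parameters and
output settings.  Every key has a default; the file only overrides."""
from __future__ import annotations

import tomllib
from dataclasses import dataclass

from .engine import MCParams
from .forcefield import ForceField

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # [molecules]
    receptor: str = ""
    ligand: str = ""
    ligand_dir: str = ""        # optional rigid-conformer ensemble directory
    # [forcefield]
    ff_table: str = ""          # path to a JSON table; empty = packaged OPLS-like
    dielectric: str = "distance"
    dielectric_constant: float = 1.0
    # [spots]
    spot_radius: float = 10.0
    spots_file: str = ""
    min_spot_separation: float = 0.0
    # [grids]
    es_spacing: float = 0.5
    vdw_spacing: float = 2.0
    neighbour_cutoff: float = 8.0
    padding: float = 12.0
    grid_cache: str = ""
    # [montecarlo]
    n_steps: int = 500
    replicas_per_spot: int = 128
    max_shift: float = 1.0
    max_rot: float = 0.3
    temperature: float = 0.0
    energy_cutoff: float = 100.0
    batch_spots: int = 16
    seed: int = 0
    # [output]
    out_dir: str = "blindsurf_out"
    top_k: int = 5
    colormap: str = "red_low"
    kernel: str = "grid"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        kw = {}
        sections = {
            "molecules": {"receptor": "receptor", "ligand": "ligand",
                          "ligand_dir": "ligand_dir"},
            "forcefield": {"table": "ff_table", "dielectric": "dielectric",
                           "dielectric_constant": "dielectric_constant"},
            "spots": {"radius": "spot_radius", "file": "spots_file",
                      "min_separation": "min_spot_separation"},
            "grids": {"spacing": "es_spacing", "vdw_spacing": "vdw_spacing",
                      "neighbour_cutoff": "neighbour_cutoff", "padding": "padding",
                      "cache": "grid_cache"},
            "montecarlo": {"steps": "n_steps", "replicas": "replicas_per_spot",
                           "max_shift": "max_shift", "max_rot": "max_rot",
                           "temperature": "temperature",
                           "energy_cutoff": "energy_cutoff",
                           "batch_spots": "batch_spots", "seed": "seed"},
            "output": {"dir": "out_dir", "top_k": "top_k", "colormap": "colormap",
                       "kernel": "kernel"},
        }
        for section, keys in sections.items():
            for key, attr in keys.items():
                if section in doc and key in doc[section]:
                    kw[attr] = doc[section][key]
        unknown = set(doc) - set(sections)
        if unknown:
            raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
        return cls(**kw)

    def mc_params(self, seed: int | None = None) -> MCParams:
        return MCParams(
            n_steps=self.n_steps, replicas_per_spot=self.replicas_per_spot,
            max_shift=self.max_shift, max_rot=self.max_rot,
            temperature=self.temperature, batch_spots=self.batch_spots,
            seed=self.seed if seed is None else seed,
            clash_threshold=self.energy_cutoff,
        )

    def forcefield(self) -> ForceField:
        ff = ForceField.from_json(self.ff_table) if self.ff_table else ForceField.default()
        if (self.dielectric != ff.dielectric_model
                or self.dielectric_constant != ff.dielectric_constant):
            ff = ff.replace(dielectric_model=self.dielectric,
                            dielectric_constant=self.dielectric_constant)
        return ff
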