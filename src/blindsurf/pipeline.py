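"""End-to-end screen orchestration: grids -> spots -> replica MC -> results."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import MCParams, SpotResult, run_spot_batch
from .forcefield import ForceField
from .grids import (
    DEFAULT_ES_SPACING,
    DEFAULT_NEIGHBOUR_CUTOFF,
    DEFAULT_PADDING,
    DEFAULT_VDW_SPACING,
    GridSpec,
    build_es_grid,
    build_vdw_grid,
    load_grids,
    save_grids,
)
from .molecules import LigandModel, Receptor
from .scoring import DirectScorer, GridScorer
from .spots import DEFAULT_SPOT_RADIUS, generate_spots, load_spots

__all__ = ["ScreenResult", "run_screen", "prepare_grids", "make_scorer"]


@dataclass(frozen=True)
class ScreenResult:
    """Full outcome of screening one ligand over every surface spot."""

    ligand_name: str
    spot_results: list          # list[SpotResult], one per spot, in spot order
    params: MCParams
    backend: str
    spot_radius: float

    @property
    def min_total(self) -> float:
        return min(r.min_energy.total for r in self.spot_results)

    @property
    def best_spot(self) -> SpotResult:
        return min(self.spot_results, key=lambda r: (r.min_energy.total,))


def _grid_box(receptor: Receptor, spots, ligand: LigandModel, spacing: float,
              padding: float) -> GridSpec:
    """Box enclosing the receptor and every reachable posed ligand atom."""
    lig_extent = float(np.linalg.norm(ligand.ref_coords, axis=1).max(initial=0.0))
    pts = [receptor.coords]
    reach = np.array([s.radius for s in spots])[:, None] + lig_extent + 1.0
    centers = np.array([s.center for s in spots])
    pts.append(centers - reach)
    pts.append(centers + reach)
    return GridSpec.enclosing(np.vstack(pts), spacing, padding)


def prepare_grids(receptor: Receptor, spots, ligand: LigandModel, ff: ForceField,
                  es_spacing: float = DEFAULT_ES_SPACING,
                  vdw_spacing: float = DEFAULT_VDW_SPACING,
                  neighbour_cutoff: float = DEFAULT_NEIGHBOUR_CUTOFF,
                  padding: float = DEFAULT_PADDING,
                  cache: str | None = None, force: bool = False):
    """Build the ES and VDW grids, or reload them from *cache* when fresh."""
    if cache and Path(cache).exists():
        return load_grids(cache, receptor=receptor, ff=ff, force=force)
    es_spec = _grid_box(receptor, spots, ligand, es_spacing, padding)
    vdw_spec = _grid_box(receptor, spots, ligand, vdw_spacing, padding)
    es = build_es_grid(receptor, es_spec, ff)
    vdw = build_vdw_grid(receptor, vdw_spec, neighbour_cutoff)
    if cache:
        save_grids(cache, es, vdw, receptor, ff)
    return es, vdw


def make_scorer(backend: str, receptor: Receptor, ligand: LigandModel,
                ff: ForceField, es_grid=None, vdw_grid=None):
    if backend == "direct":
        return DirectScorer(receptor, ligand, ff)
    if backend == "grid":
        if es_grid is None or vdw_grid is None:
            raise ValueError("grid backend requires prebuilt grids")
        return GridScorer(receptor, ligand, es_grid, vdw_grid, ff)
    raise ValueError(f"unknown scoring backend {backend!r} (use 'direct' or 'grid')")


def run_screen(receptor: Receptor, ligand: LigandModel, ff: ForceField,
               params: MCParams, *, spots=None, spots_file=None,
               spot_radius: float = DEFAULT_SPOT_RADIUS, backend: str = "grid",
               es_spacing: float = DEFAULT_ES_SPACING,
               vdw_spacing: float = DEFAULT_VDW_SPACING,
               neighbour_cutoff: float = DEFAULT_NEIGHBOUR_CUTOFF,
               padding: float = DEFAULT_PADDING,
               grids=None, grid_cache: str | None = None,
               ligand_name: str | None = None) -> ScreenResult:
    """Screen one rigid ligand over the whole receptor surface.

    Spots come from the receptor's alpha carbons unless an explicit list or
    spots file is supplied.  Grids are built (or loaded from ``grid_cache``)
    for the grid backend; the direct backend needs none.  Deterministic in
    ``params.seed``.
    """
    if spots is None:
        spots = load_spots(spots_file, spot_radius) if spots_file \
            else generate_spots(receptor, spot_radius)
    if backend == "grid":
        if grids is None:
            grids = prepare_grids(receptor, spots, ligand, ff,
                                  es_spacing=es_spacing, vdw_spacing=vdw_spacing,
                                  neighbour_cutoff=neighbour_cutoff, padding=padding,
                                  cache=grid_cache)
        es_grid, vdw_grid = grids
    else:
        es_grid = vdw_grid = None
    scorer = make_scorer(backend, receptor, ligand, ff, es_grid, vdw_grid)
    results = run_spot_batch(spots, ligand, scorer, params)
    name = ligand_name or (Path(ligand.source).stem if ligand.source else "ligand")
    return ScreenResult(ligand_name=name, spot_results=results, params=params,
                        backend=backend, spot_radius=float(spots[0].radius))
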