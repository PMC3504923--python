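"""Precomputed interaction grids over a box enclosing the receptor.

Two lattices are built once per receptor and reused for every pose
evaluation:

* :class:`ESGrid` tabulates the receptor's electrostatic potential
  (kcal/(mol·e)) on a regular lattice (default spacing 0.5 Å) by direct
  summation over all receptor atoms, with the interatomic distance clamped
  below ``r_min`` so nodes inside atoms stay finite.  Pose evaluation then
  needs only one trilinear interpolation per ligand atom.
* :class:`VDWGrid` stores, for every cell of a coarser lattice, the list of
  receptor atoms within ``neighbour_cutoff`` of *any* point of the cell
  (a superset built from the cell centre plus half the cell diagonal), so
  Lennard-Jones and H-bond terms are exact pairwise sums restricted to the
  cell's list — no false negatives by construction.

Grid files carry the grid spec plus receptor and force-field fingerprints,
so a stale grid is refused when the structure or parameters change.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .forcefield import ForceField
from .molecules import Receptor

__all__ = [
    "GridSpec",
    "ESGrid",
    "VDWGrid",
    "build_es_grid",
    "build_vdw_grid",
    "interpolate_es",
    "save_grids",
    "load_grids",
    "GridError",
    "StaleGridError",
]

#: Distance clamp (Å) applied when tabulating the potential at lattice nodes.
R_MIN_CLAMP = 0.5
DEFAULT_ES_SPACING = 0.5    # Å
DEFAULT_VDW_SPACING = 2.0   # Å (cell edge of the neighbour-list lattice)
DEFAULT_NEIGHBOUR_CUTOFF = 8.0  # Å
DEFAULT_PADDING = 12.0      # Å around the receptor bounding box

GRID_FORMAT_VERSION = 1


class GridError(ValueError):
    pass


class StaleGridError(GridError):
    """Saved grid does not match the current receptor/force field."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lattice: origin, spacing and node (or cell) counts per axis."""

    origin: np.ndarray   # (3,) Å
    spacing: float       # Å
    dims: tuple          # (nx, ny, nz)

    def __post_init__(self):
        if not self.spacing > 0:
            raise GridError("grid spacing must be > 0")
        if any(d < 2 for d in self.dims):
            raise GridError("grid needs at least 2 nodes per axis")
        o = np.asarray(self.origin, dtype=float)
        o.setflags(write=False)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @classmethod
    def enclosing(cls, coords: np.ndarray, spacing: float, padding: float) -> "GridSpec":
        lo = coords.min(axis=0) - padding
        hi = coords.max(axis=0) + padding
        dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
        return cls(origin=lo, spacing=spacing, dims=dims)

    @property
    def max_corner(self) -> np.ndarray:
        return self.origin + self.spacing * (np.array(self.dims) - 1)

    def axes(self):
        return tuple(
            self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)
        )

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.origin) & (p <= self.max_corner), axis=-1)

    def to_dict(self) -> dict:
        return {"origin": list(map(float, self.origin)), "spacing": self.spacing,
                "dims": list(self.dims)}

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(origin=np.array(d["origin"]), spacing=float(d["spacing"]),
                   dims=tuple(d["dims"]))


class ESGrid:
    """Electrostatic potential tabulated on lattice nodes, queried trilinearly."""

    def __init__(self, spec: GridSpec, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != spec.dims:
            raise GridError(f"values shape {values.shape} != dims {spec.dims}")
        if not np.all(np.isfinite(values)):
            raise GridError("non-finite potential values after clamping — build bug")
        values.setflags(write=False)
        self.spec = spec
        self.values = values
        self._interp = None

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                self.spec.axes(), self.values, method="linear", bounds_error=True
            )
        return self._interp


class VDWGrid:
    """Per-cell receptor-atom neighbour lists on a coarse lattice (CSR layout).

    ``padded`` is a fixed-width index matrix (pad value −1) so batched pose
    scoring can gather neighbours with one fancy index; the fixed width keeps
    per-pose floating-point reductions identical across batch sizes.
    """

    def __init__(self, spec: GridSpec, offsets: np.ndarray, indices: np.ndarray,
                 cutoff: float):
        self.spec = spec
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.indices = np.asarray(indices, dtype=np.int64)
        self.cutoff = float(cutoff)
        ncells = int(np.prod(spec.dims))
        if self.offsets.shape != (ncells + 1,):
            raise GridError("neighbour-list offsets inconsistent with grid dims")
        counts = np.diff(self.offsets)
        self.max_neighbours = int(counts.max()) if counts.size else 0
        padded = np.full((ncells, self.max_neighbours), -1, dtype=np.int64)
        for c in range(ncells):
            row = self.indices[self.offsets[c]:self.offsets[c + 1]]
            padded[c, : row.size] = row
        self.padded = padded

    def cell_of(self, points: np.ndarray) -> np.ndarray:
        """Flat cell index for each query point (clipped into the lattice)."""
        p = np.atleast_2d(points)
        ijk = np.floor((p - self.spec.origin) / self.spec.spacing).astype(np.int64)
        ijk = np.clip(ijk, 0, np.array(self.spec.dims) - 1)
        nx, ny, nz = self.spec.dims
        return (ijk[:, 0] * ny + ijk[:, 1]) * nz + ijk[:, 2]

    def neighbours_of_cell(self, flat_index: int) -> np.ndarray:
        return self.indices[self.offsets[flat_index]:self.offsets[flat_index + 1]]


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_es_grid(receptor: Receptor, spec: GridSpec, ff: ForceField,
                  r_min: float = R_MIN_CLAMP) -> ESGrid:
    """Tabulate the direct-summation Coulomb potential on the lattice.

    Node value = Σ_j k·q_j / (ε(r_j)·r_j) over receptor atoms j, with each
    distance clamped below *r_min* to keep nodes inside atoms finite.
    Deterministic: a fixed accumulation order over atoms.
    """
    if receptor.n_atoms == 0:
        raise GridError("empty receptor")
    if not (np.all(receptor.coords.min(axis=0) >= spec.origin)
            and np.all(receptor.coords.max(axis=0) <= spec.max_corner)):
        raise GridError("grid box does not enclose the receptor")
    ax, ay, az = spec.axes()
    X = ax[:, None, None]
    Y = ay[None, :, None]
    Z = az[None, None, :]
    values = np.zeros(spec.dims)
    k = ff.coulomb_constant
    for j in range(receptor.n_atoms):
        q = receptor.charges[j]
        if q == 0.0:
            continue
        x0, y0, z0 = receptor.coords[j]
        r = np.sqrt((X - x0) ** 2 + (Y - y0) ** 2 + (Z - z0) ** 2)
        np.maximum(r, r_min, out=r)
        values += k * q / ff.dielectric_times_r(r)
    return ESGrid(spec, values)


def build_vdw_grid(receptor: Receptor, spec: GridSpec,
                   neighbour_cutoff: float = DEFAULT_NEIGHBOUR_CUTOFF) -> VDWGrid:
    """Build per-cell neighbour lists with no false negatives.

    A receptor atom joins a cell's list when it lies within
    ``cutoff + half cell diagonal`` of the cell centre, which covers every
    point of the cell; lists may contain extra atoms (false positives),
    whose pairwise terms are still evaluated exactly.
    """
    if not neighbour_cutoff > 0:
        raise GridError("neighbour_cutoff must be > 0")
    if receptor.n_atoms == 0:
        raise GridError("empty receptor")
    nx, ny, nz = spec.dims
    ax = spec.origin[0] + spec.spacing * (np.arange(nx) + 0.5)
    ay = spec.origin[1] + spec.spacing * (np.arange(ny) + 0.5)
    az = spec.origin[2] + spec.spacing * (np.arange(nz) + 0.5)
    centers = np.stack(np.meshgrid(ax, ay, az, indexing="ij"), axis=-1).reshape(-1, 3)
    slack = 0.5 * np.sqrt(3.0) * spec.spacing
    tree = cKDTree(receptor.coords)
    lists = tree.query_ball_point(centers, neighbour_cutoff + slack)
    counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
    offsets = np.concatenate([[0], np.cumsum(counts)])
    indices = np.concatenate([np.sort(l) for l in lists if l] or [np.empty(0, dtype=np.int64)])
    return VDWGrid(spec, offsets, indices.astype(np.int64), neighbour_cutoff)


def interpolate_es(grid: ESGrid, points) -> np.ndarray:
    """Trilinear interpolation of the potential at Cartesian points (in-box)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(grid.spec.contains(p)):
        raise GridError("query point outside the grid box (poses must be clamped in-box)")
    out = grid.interpolator()(p)
    return out if np.asarray(points).ndim > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_grids(path, es_grid: ESGrid, vdw_grid: VDWGrid, receptor: Receptor,
               ff: ForceField) -> None:
    """Write both grids plus provenance hashes to one ``.npz`` container."""
    header = {
        "format_version": GRID_FORMAT_VERSION,
        "es_spec": es_grid.spec.to_dict(),
        "vdw_spec": vdw_grid.spec.to_dict(),
        "cutoff": vdw_grid.cutoff,
        "receptor_hash": receptor.fingerprint(),
        "ff_hash": ff.fingerprint(),
        "units": {"potential": "kcal/(mol*e)", "length": "angstrom"},
    }
    np.savez_compressed(
        path,
        header=np.frombuffer(json.dumps(header, sort_keys=True).encode(), dtype=np.uint8),
        es_values=es_grid.values,
        vdw_offsets=vdw_grid.offsets,
        vdw_indices=vdw_grid.indices,
    )


def load_grids(path, receptor: Receptor = None, ff: ForceField = None,
               force: bool = False):
    """Load grids; refuse if provenance hashes mismatch unless *force*."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header.get("format_version") != GRID_FORMAT_VERSION:
            raise GridError(f"{path}: unsupported grid file version")
        mismatches = []
        if receptor is not None and header["receptor_hash"] != receptor.fingerprint():
            mismatches.append("receptor")
        if ff is not None and header["ff_hash"] != ff.fingerprint():
            mismatches.append("force field")
        if mismatches and not force:
            raise StaleGridError(
                f"{path}: cached grids were built for a different "
                f"{' and '.join(mismatches)}; rebuild or pass force=True"
            )
        if mismatches:
            import warnings

            warnings.warn(f"{path}: loading stale grids ({', '.join(mismatches)} changed)")
        es = ESGrid(GridSpec.from_dict(header["es_spec"]), data["es_values"])
        vdw = VDWGrid(GridSpec.from_dict(header["vdw_spec"]), data["vdw_offsets"],
                      data["vdw_indices"], header["cutoff"])
    return es, vdw
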