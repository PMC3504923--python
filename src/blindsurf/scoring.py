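"""The ES + VDW + HBOND scoring function, with two interchangeable backends.

* **DIRECT** — exact all-pairs summation over every (ligand atom, receptor
  atom) pair.  Slow but closed-form; it is also the independent oracle the
  grid backend is validated against.
* **GRID** — electrostatics by trilinear interpolation of the precomputed
  potential lattice (one lookup per ligand atom, multiplied by its charge),
  and Lennard-Jones/H-bond terms as exact pairwise sums restricted to the
  receptor-atom neighbour list of the cell containing each ligand atom.

Functional forms (see :mod:`blindsurf.forcefield` for parameters):

    ES     = Σ k·q_i·q_j / (ε(r_ij)·r_ij)
    VDW    = Σ 4·ε_ij·[(σ_ij/r)^12 − (σ_ij/r)^6],  σ_ij, ε_ij geometric means
    HBOND  = Σ_{donor-H · acceptor} ε_hb·[5·(r_eq/r)^12 − 6·(r_eq/r)^10]

The VDW sum runs over all pairs and the HBOND sum additionally over
donor/acceptor pairs; intra-ligand and receptor–receptor terms are constant
for rigid molecules and excluded.  Distances are clamped at a hard floor of
1e-6 Å so coincident atoms yield huge-but-finite clash energies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import ForceField
from .grids import ESGrid, VDWGrid, interpolate_es
from .molecules import LigandModel, Receptor, apply_poses

__all__ = [
    "EnergyBreakdown",
    "EnergyBatch",
    "score_direct",
    "score_grid",
    "score_batch",
    "DirectScorer",
    "GridScorer",
]

R_FLOOR = 1e-6  # Å — hard clamp for coincident atoms


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components of one pose, kcal/mol. ``total == es + vdw + hbond``."""

    es: float
    vdw: float
    hbond: float
    total: float

    def __post_init__(self):
        if abs(self.total - (self.es + self.vdw + self.hbond)) > 1e-9:
            raise ValueError("total != es + vdw + hbond")

    @classmethod
    def make(cls, es: float, vdw: float, hbond: float) -> "EnergyBreakdown":
        return cls(es=float(es), vdw=float(vdw), hbond=float(hbond),
                   total=float(es) + float(vdw) + float(hbond))


@dataclass(frozen=True)
class EnergyBatch:
    """Component arrays for a batch of poses (element i = pose i)."""

    es: np.ndarray
    vdw: np.ndarray
    hbond: np.ndarray
    total: np.ndarray

    def __len__(self):
        return self.total.shape[0]

    def __getitem__(self, i) -> EnergyBreakdown:
        return EnergyBreakdown(es=float(self.es[i]), vdw=float(self.vdw[i]),
                               hbond=float(self.hbond[i]), total=float(self.total[i]))

    @classmethod
    def make(cls, es, vdw, hbond) -> "EnergyBatch":
        es = np.asarray(es, dtype=float)
        vdw = np.asarray(vdw, dtype=float)
        hbond = np.asarray(hbond, dtype=float)
        return cls(es=es, vdw=vdw, hbond=hbond, total=es + vdw + hbond)

    @classmethod
    def from_total(cls, total) -> "EnergyBatch":
        """A batch with everything in ``es`` — used by toy-landscape scorers."""
        total = np.asarray(total, dtype=float)
        z = np.zeros_like(total)
        return cls(es=total, vdw=z, hbond=z, total=total.copy())


class _PairTables:
    """Precombined per-(ligand atom, receptor atom) parameter matrices."""

    def __init__(self, receptor: Receptor, ligand: LigandModel, ff: ForceField):
        self.sigma = np.sqrt(np.outer(ligand.sigmas, receptor.sigmas))       # (n, N)
        self.eps4 = 4.0 * np.sqrt(np.outer(ligand.epsilons, receptor.epsilons))
        self.qq = ff.coulomb_constant * np.outer(ligand.charges, receptor.charges)
        self.hb_mask = (
            np.outer(ligand.is_donor_h, receptor.is_acceptor)
            | np.outer(ligand.is_acceptor, receptor.is_donor_h)
        )
        self.hb_req, self.hb_depth = ff.hb_params
        self.ff = ff


def _vdw_term(eps4, sigma, r):
    sr6 = (sigma / r) ** 6
    return eps4 * (sr6 * sr6 - sr6)


def _hbond_term(depth, r_eq, r):
    x10 = (r_eq / r) ** 10
    x12 = x10 * (r_eq / r) ** 2
    return depth * (5.0 * x12 - 6.0 * x10)


# ---------------------------------------------------------------------------
# DIRECT backend
# ---------------------------------------------------------------------------

class DirectScorer:
    """Exact all-pairs scoring; the reference backend and test oracle."""

    def __init__(self, receptor: Receptor, ligand: LigandModel, ff: ForceField):
        self.receptor = receptor
        self.ligand = ligand
        self.tables = _PairTables(receptor, ligand, ff)

    def score_coords(self, coords: np.ndarray) -> EnergyBatch:
        """Score already-posed coordinates, shape ``(P, n, 3)``."""
        coords = np.asarray(coords, dtype=float)
        squeeze = coords.ndim == 2
        if squeeze:
            coords = coords[None]
        P, n, _ = coords.shape
        t = self.tables
        diff = coords[:, :, None, :] - self.receptor.coords[None, None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        np.maximum(r, R_FLOOR, out=r)
        es_pairs = t.qq[None] / t.ff.dielectric_times_r(r)
        vdw_pairs = _vdw_term(t.eps4[None], t.sigma[None], r)
        hb_pairs = np.where(t.hb_mask[None], _hbond_term(t.hb_depth, t.hb_req, r), 0.0)
        es = es_pairs.reshape(P, -1).sum(axis=1)
        vdw = vdw_pairs.reshape(P, -1).sum(axis=1)
        hb = hb_pairs.reshape(P, -1).sum(axis=1)
        return EnergyBatch.make(es, vdw, hb)

    def __call__(self, shifts, quats) -> EnergyBatch:
        return self.score_coords(apply_poses(self.ligand, shifts, quats))


def score_direct(receptor: Receptor, ligand_coords, ligand: LigandModel,
                 ff: ForceField) -> EnergyBreakdown:
    """Exact all-pairs energy of one already-posed ligand (coords ``(n, 3)``)."""
    return DirectScorer(receptor, ligand, ff).score_coords(np.asarray(ligand_coords))[0]


# ---------------------------------------------------------------------------
# GRID backend
# ---------------------------------------------------------------------------

class GridScorer:
    """Grid-accelerated scoring: interpolated ES + neighbour-list VDW/HBOND.

    Neighbour gathers use the grid's fixed-width padded index matrix, so the
    floating-point reduction for each pose is identical regardless of how
    poses are batched — batches of any size are bit-reproducible.
    """

    def __init__(self, receptor: Receptor, ligand: LigandModel,
                 es_grid: ESGrid, vdw_grid: VDWGrid, ff: ForceField):
        self.receptor = receptor
        self.ligand = ligand
        self.es_grid = es_grid
        self.vdw_grid = vdw_grid
        self.tables = _PairTables(receptor, ligand, ff)

    def __call__(self, shifts, quats) -> EnergyBatch:
        coords = apply_poses(self.ligand, shifts, quats)
        return self.score_coords(coords)

    def score_coords(self, coords: np.ndarray) -> EnergyBatch:
        coords = np.asarray(coords, dtype=float)
        squeeze = coords.ndim == 2
        if squeeze:
            coords = coords[None]
        P, n, _ = coords.shape
        pts = coords.reshape(-1, 3)
        t = self.tables

        phi = interpolate_es(self.es_grid, pts)  # raises if out of box
        es = (self.ligand.charges[None, :] * phi.reshape(P, n)).sum(axis=1)

        W = self.vdw_grid.max_neighbours
        if W == 0:
            zeros = np.zeros(P)
            return EnergyBatch.make(es, zeros, zeros)
        cells = self.vdw_grid.cell_of(pts)
        nbr = self.vdw_grid.padded[cells]                 # (Q, W)
        mask = nbr >= 0
        safe = np.where(mask, nbr, 0)
        diff = pts[:, None, :] - self.receptor.coords[safe]
        r = np.sqrt(np.sum(diff * diff, axis=-1))
        np.maximum(r, R_FLOOR, out=r)
        la = np.tile(np.arange(n), P)                     # ligand atom of each query row
        sigma = t.sigma[la[:, None], safe]
        eps4 = t.eps4[la[:, None], safe]
        vdw_pairs = np.where(mask, _vdw_term(eps4, sigma, r), 0.0)
        hbm = t.hb_mask[la[:, None], safe] & mask
        hb_pairs = np.where(hbm, _hbond_term(t.hb_depth, t.hb_req, r), 0.0)
        vdw = vdw_pairs.reshape(P, -1).sum(axis=1)
        hb = hb_pairs.reshape(P, -1).sum(axis=1)
        return EnergyBatch.make(es, vdw, hb)


def score_grid(es_grid: ESGrid, vdw_grid: VDWGrid, receptor: Receptor,
               ligand: LigandModel, shift, quat, ff: ForceField) -> EnergyBreakdown:
    """Grid-backend energy of a single pose ``(shift, quat)``."""
    scorer = GridScorer(receptor, ligand, es_grid, vdw_grid, ff)
    return scorer(np.asarray(shift)[None], np.asarray(quat)[None])[0]


def score_batch(shifts, quats, scorer) -> EnergyBatch:
    """Score a batch of poses with any backend scorer (DIRECT or GRID)."""
    return scorer(shifts, quats)
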