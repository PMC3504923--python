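"""Replica Monte Carlo minimization over surface spots.

For every spot, a batch of independent replicas (default 128) of the rigid
ligand is initialized uniformly inside the spot sphere and minimized for a
fixed number of steps (default 500), alternating random rigid-body moves:
odd steps propose a rotation (random axis, angle uniform in ±max_rot about
the ligand centroid), even steps propose a translation (componentwise
uniform in ±max_shift, the centroid then clamped back into the spot sphere
by radial projection).  A proposal is accepted when it lowers the energy
(ties accepted); at temperature T > 0 an uphill move is also accepted with
the Metropolis probability ``exp(-ΔE/T)``.  T = 0 (the default) reproduces
the pure greedy acceptance of the original kernels.

Randomness is counter-addressable: each replica owns private uniform
streams keyed by ``(seed, spot index, replica index)``, and the draws for
step *n* are a fixed slice of the replica's stream — a rejected proposal's
draws are simply discarded, never reused.  Results are therefore
bit-reproducible and independent of how spots are partitioned into batches
or of evaluation order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .molecules import LigandModel
from .scoring import EnergyBreakdown
from .spots import Spot

__all__ = [
    "MCParams",
    "ReplicaState",
    "SpotResult",
    "initialize_replicas",
    "make_batch",
    "mc_step",
    "run_spot_batch",
    "find_minima",
]

_DRAWS_PER_MOVE = 3  # uniforms consumed by one proposal (shift or rotation)
_DRAWS_PER_INIT_TRY = 6


@dataclass(frozen=True)
class MCParams:
    """Monte Carlo minimization parameters.

    ``temperature`` is in kcal/mol (energy units; 0 means greedy descent).
    ``clash_threshold`` is the energy cutoff above which an initial state is
    considered invalid and re-drawn (up to ``init_max_tries`` times).
    ``batch_spots`` controls how many spots are minimized per vectorized
    batch; it affects speed only, never results.
    """

    n_steps: int = 500
    replicas_per_spot: int = 128
    max_shift: float = 1.0      # Å per translation proposal
    max_rot: float = 0.3        # rad per rotation proposal
    temperature: float = 0.0    # kcal/mol; 0 => greedy
    batch_spots: int = 16
    seed: int = 0
    clash_threshold: float = 100.0  # kcal/mol ("energy cutoff")
    init_max_tries: int = 20

    def __post_init__(self):
        if self.n_steps < 1 or self.replicas_per_spot < 1:
            raise ValueError("n_steps and replicas_per_spot must be >= 1")
        if not (self.max_shift > 0 and self.max_rot > 0):
            raise ValueError("max_shift and max_rot must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass(frozen=True)
class ReplicaState:
    """Externally visible snapshot of one replica."""

    shift: np.ndarray
    quat: np.ndarray
    energy: EnergyBreakdown
    spot_id: str
    replica_index: int
    clash_flagged: bool = False


@dataclass(frozen=True)
class SpotResult:
    """Outcome of one spot's replica batch."""

    spot_id: str
    min_energy: EnergyBreakdown
    best_pose: tuple            # (shift (3,), quat (4,))
    best_replica: int
    replica_energies: np.ndarray  # (R,) totals at the end of the run
    acceptance_rate: float
    n_clash_flagged: int = 0


def _replica_stream(seed: int, spot_index: int, replica: int, stream: int,
                    n: int) -> np.ndarray:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(spot_index, replica, stream))
    return np.random.Generator(np.random.PCG64(ss)).random(n)


class _BatchState:
    """Vectorized state of all replicas of one batch of spots."""

    def __init__(self, spots, spot_indices, params: MCParams, scorer):
        R = params.replicas_per_spot
        M = len(spots) * R
        self.spots = list(spots)
        self.R = R
        self.centers = np.repeat(np.array([s.center for s in spots], dtype=float), R, axis=0)
        self.radii = np.repeat(np.array([s.radius for s in spots], dtype=float), R)
        self.params = params
        self.scorer = scorer

        # Private streams per replica, keyed by (seed, spot index, replica).
        n_prop = _DRAWS_PER_MOVE * (params.n_steps + 1)
        init_u = np.empty((M, _DRAWS_PER_INIT_TRY * params.init_max_tries))
        self.prop_u = np.empty((M, n_prop))
        self.acc_u = np.empty((M, params.n_steps))
        for b, gi in enumerate(spot_indices):
            for r in range(R):
                m = b * R + r
                init_u[m] = _replica_stream(params.seed, gi, r, 0, init_u.shape[1])
                self.prop_u[m] = _replica_stream(params.seed, gi, r, 1, n_prop)
                self.acc_u[m] = _replica_stream(params.seed, gi, r, 2, params.n_steps)

        # Initialization: uniform pose in the sphere, re-drawn while clashing.
        shifts = geometry.uniform_in_sphere(init_u[:, 0:3], self.centers, 1.0)
        shifts = self.centers + (shifts - self.centers) * self.radii[:, None]
        quats = geometry.random_unit_quats(init_u[:, 3:6])
        energies = scorer(shifts, quats)
        for t in range(1, params.init_max_tries):
            bad = np.flatnonzero(energies.total >= params.clash_threshold)
            if bad.size == 0:
                break
            o = _DRAWS_PER_INIT_TRY * t
            s_new = geometry.uniform_in_sphere(init_u[bad, o:o + 3], self.centers[bad], 1.0)
            s_new = self.centers[bad] + (s_new - self.centers[bad]) * self.radii[bad, None]
            q_new = geometry.random_unit_quats(init_u[bad, o + 3:o + 6])
            e_new = scorer(s_new, q_new)
            shifts[bad] = s_new
            quats[bad] = q_new
            for name in ("es", "vdw", "hbond", "total"):
                getattr(energies, name)[bad] = getattr(e_new, name)
        self.clash_flagged = energies.total >= params.clash_threshold

        self.shifts = shifts
        self.quats = quats
        self.energies = energies
        self.n_accepted = 0
        self.n_proposed = 0

    # -- one MC step ------------------------------------------------------

    def step(self, step_index: int) -> None:
        """Advance every replica by one proposal (odd = rotation, even = shift)."""
        p = self.params
        M = self.shifts.shape[0]
        o = (step_index - 1) * _DRAWS_PER_MOVE
        u = self.prop_u[:, o:o + _DRAWS_PER_MOVE]

        if step_index % 2 == 0:  # translation move
            delta = (2.0 * u - 1.0) * p.max_shift
            new_shifts = self.shifts + delta
            # radial clamp with per-replica radii keeps each centroid in its spot
            v = new_shifts - self.centers
            norm = np.linalg.norm(v, axis=-1)
            over = norm > self.radii
            if np.any(over):
                new_shifts[over] = (
                    self.centers[over]
                    + v[over] * (self.radii[over] / norm[over])[:, None]
                )
            new_quats = self.quats
        else:  # rotation move
            cos_t = 2.0 * u[:, 0] - 1.0
            sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
            phi = 2.0 * np.pi * u[:, 1]
            axis = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1)
            angle = (2.0 * u[:, 2] - 1.0) * p.max_rot
            dq = geometry.axis_angle_quat(axis, angle)
            new_quats = geometry.normalize_quats(geometry.quat_mul(dq, self.quats))
            new_shifts = self.shifts

        proposal = self.scorer(new_shifts, new_quats)
        d_e = proposal.total - self.energies.total
        accept = d_e <= 0.0
        if p.temperature > 0.0:
            with np.errstate(over="ignore"):
                boltz = np.exp(np.minimum(-d_e / p.temperature, 0.0))
            accept |= self.acc_u[:, step_index - 1] < boltz

        idx = np.flatnonzero(accept)
        if idx.size:
            self.shifts[idx] = new_shifts[idx]
            self.quats[idx] = new_quats[idx]
            for name in ("es", "vdw", "hbond", "total"):
                getattr(self.energies, name)[idx] = getattr(proposal, name)[idx]
        self.n_accepted += int(idx.size)
        self.n_proposed += M

    # -- results ----------------------------------------------------------

    def results(self) -> list:
        out = []
        R = self.R
        for b, spot in enumerate(self.spots):
            sl = slice(b * R, (b + 1) * R)
            totals = self.energies.total[sl].copy()
            best, _ = find_minima(totals)
            m = b * R + best
            out.append(
                SpotResult(
                    spot_id=spot.spot_id,
                    min_energy=EnergyBreakdown.make(
                        self.energies.es[m], self.energies.vdw[m], self.energies.hbond[m]
                    ),
                    best_pose=(self.shifts[m].copy(), self.quats[m].copy()),
                    best_replica=best,
                    replica_energies=totals,
                    acceptance_rate=self.n_accepted / max(self.n_proposed, 1),
                    n_clash_flagged=int(self.clash_flagged[sl].sum()),
                )
            )
        return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def make_batch(spots, params: MCParams, scorer, spot_indices=None) -> _BatchState:
    """Initialized replica batch for *spots*, ready to be advanced by
    :func:`mc_step`.  ``spot_indices`` key the random streams (default
    ``0..len(spots)-1``)."""
    spots = list(spots)
    if spot_indices is None:
        spot_indices = list(range(len(spots)))
    return _BatchState(spots, spot_indices, params, scorer)


def initialize_replicas(spot: Spot, ligand: LigandModel, params: MCParams,
                        scorer, spot_index: int = 0) -> list:
    """Random valid starting states for every replica of one spot.

    Centroids uniform in the spot sphere, orientations uniform on SO(3);
    states with energy above ``params.clash_threshold`` are re-drawn up to
    ``init_max_tries`` times and flagged if still clashing.
    """
    batch = _BatchState([spot], [spot_index], params, scorer)
    return [
        ReplicaState(
            shift=batch.shifts[r].copy(),
            quat=batch.quats[r].copy(),
            energy=batch.energies[r],
            spot_id=spot.spot_id,
            replica_index=r,
            clash_flagged=bool(batch.clash_flagged[r]),
        )
        for r in range(params.replicas_per_spot)
    ]


def mc_step(batch: _BatchState, step_index: int) -> _BatchState:
    """Advance a replica batch by one Monte Carlo proposal (mutates *batch*)."""
    batch.step(step_index)
    return batch


def find_minima(replica_energies: np.ndarray):
    """Exact arg-min of a replica energy vector; ties resolve to the lowest index."""
    e = np.asarray(replica_energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty replica energy vector")
    i = int(np.argmin(e))
    return i, float(e[i])


def run_spot_batch(spots, ligand: LigandModel, scorer, params: MCParams,
                   spot_indices=None, trace: bool = False):
    """Minimize replica batches on *spots* and reduce each to a :class:`SpotResult`.

    ``spot_indices`` are the positions of these spots in the full spot list
    (they key the random streams); by default ``0..len(spots)-1``.  With
    ``trace=True`` also returns, per spot, the ``(n_steps+1, R)`` energy
    trajectory of every replica.
    """
    spots = list(spots)
    if spot_indices is None:
        spot_indices = list(range(len(spots)))
    results, traces = [], []
    B = max(1, params.batch_spots)
    for start in range(0, len(spots), B):
        chunk = spots[start:start + B]
        chunk_idx = spot_indices[start:start + B]
        batch = _BatchState(chunk, chunk_idx, params, scorer)
        if trace:
            track = [batch.energies.total.copy()]
        for n in range(1, params.n_steps + 1):
            batch.step(n)
            if trace:
                track.append(batch.energies.total.copy())
        results.extend(batch.results())
        if trace:
            arr = np.array(track)  # (n_steps+1, len(chunk)*R)
            R = params.replicas_per_spot
            traces.extend(arr[:, b * R:(b + 1) * R] for b in range(len(chunk)))
    return (results, traces) if trace else results
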