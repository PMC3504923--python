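"""Post-processing of screen results.

Hotspot ranking (ascending by minimum energy), score-distribution
histograms, docking-convention pose RMSD (no superposition — placement
error must count), screening enrichment as ROC/AUC over actives vs decoys,
and file exports: best-pose PDBs, a PyMOL bead script colouring each spot
by rank, histogram TSV and a versioned machine-readable JSON.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .molecules import LigandModel, apply_pose
from .pipeline import ScreenResult

__all__ = [
    "HotspotReport",
    "rank_hotspots",
    "pose_rmsd",
    "roc_auc",
    "export_outputs",
]

RESULTS_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class HotspotReport:
    """Spots ranked by minimum energy (strongest interaction first)."""

    ranked_spot_ids: tuple
    ranked_energies: tuple
    histogram_counts: tuple
    histogram_edges: tuple
    bead_values: dict           # spot_id -> normalized rank in [0, 1], 0 = strongest


def rank_hotspots(results, bins=None) -> HotspotReport:
    """Ascending sort by total minimum energy; ties keep original spot order."""
    results = list(results)
    if not results:
        raise ValueError("no spot results to rank")
    totals = np.array([r.min_energy.total for r in results])
    order = np.argsort(totals, kind="stable")
    edges = np.histogram_bin_edges(totals, bins=bins if bins is not None else "fd")
    if len(edges) < 2:
        edges = np.histogram_bin_edges(totals, bins=1)
    counts, edges = np.histogram(totals, bins=edges)
    n = len(results)
    bead = {results[i].spot_id: (rank / (n - 1) if n > 1 else 0.0)
            for rank, i in enumerate(order)}
    return HotspotReport(
        ranked_spot_ids=tuple(results[i].spot_id for i in order),
        ranked_energies=tuple(float(totals[i]) for i in order),
        histogram_counts=tuple(int(c) for c in counts),
        histogram_edges=tuple(float(e) for e in edges),
        bead_values=bead,
    )


def pose_rmsd(pred_coords, ref_coords, atom_map=None) -> float:
    """Docking RMSD in the receptor frame, without optimal superposition.

    ``atom_map[i]`` gives the reference atom matched to predicted atom ``i``
    (a hook for symmetry-equivalent atom mappings); identity by default.
    """
    pred = np.asarray(pred_coords, dtype=float).reshape(-1, 3)
    ref = np.asarray(ref_coords, dtype=float).reshape(-1, 3)
    if atom_map is not None:
        ref = ref[np.asarray(atom_map, dtype=int)]
    if pred.shape != ref.shape:
        raise ValueError(f"atom count mismatch: {pred.shape[0]} vs {ref.shape[0]}")
    d = pred - ref
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def roc_auc(scores, labels):
    """ROC points and trapezoidal AUC for energy scores (lower = more active).

    Ties are handled by threshold grouping, which makes the AUC equal to the
    Mann–Whitney pair statistic ``P(active < decoy) + ½·P(tie)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValueError("both actives and decoys are required to compute a ROC curve")
    fpr, tpr, _ = _roc_curve(labels, -scores)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

_COLORMAPS = {
    # value 0 = strongest interaction
    "red_low": lambda v: (1.0 - v, 0.0, v),
    "blue_low": lambda v: (v, 0.0, 1.0 - v),
}


def _pose_pdb_lines(ligand: LigandModel, coords):
    lines = []
    for i in range(ligand.nlig):
        x, y, z = coords[i]
        el = (ligand.elements[i] or "C")[:2].upper()
        name = ligand.names[i][:4]
        lines.append(
            f"HETATM{i+1:>5} {name:<4} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2}"
        )
    lines.append("END")
    return lines


def export_outputs(result: ScreenResult, ligand: LigandModel, spots, out_dir,
                   top_k: int = 5, colormap: str = "red_low", bins=None) -> dict:
    """Write pose PDBs for the top-k spots, a PyMOL bead script, histogram TSV
    and the full results JSON.  Byte-deterministic for a given result.

    Returns the mapping of artifact kind to written path(s).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if colormap not in _COLORMAPS:
        raise ValueError(f"unknown colormap {colormap!r} (use one of {sorted(_COLORMAPS)})")
    report = rank_hotspots(result.spot_results, bins=bins)
    by_id = {r.spot_id: r for r in result.spot_results}
    spot_by_id = {s.spot_id: s for s in spots}

    pose_paths = []
    for rank, spot_id in enumerate(report.ranked_spot_ids[:top_k], 1):
        r = by_id[spot_id]
        coords = apply_pose(ligand, *r.best_pose)
        safe = "".join(c if c.isalnum() else "_" for c in spot_id)
        p = out / f"pose_rank{rank}_{safe}.pdb"
        p.write_text("\n".join(_pose_pdb_lines(ligand, coords)) + "\n")
        pose_paths.append(p)

    cmap = _COLORMAPS[colormap]
    pml = ["# surface spot beads coloured by scoring-function rank "
           f"(colormap={colormap}; value 0 = strongest interaction)"]
    for i, spot_id in enumerate(sorted(by_id)):
        v = report.bead_values[spot_id]
        rgb = cmap(v)
        c = spot_by_id[spot_id].center
        pml.append(f"pseudoatom beads, pos=[{c[0]:.3f}, {c[1]:.3f}, {c[2]:.3f}], "
                   f"name=B{i}")
        pml.append(f"set_color spotcol{i}, [{rgb[0]:.4f}, {rgb[1]:.4f}, {rgb[2]:.4f}]")
        pml.append(f"color spotcol{i}, beads and name B{i}")
    pml += ["show spheres, beads", "set sphere_scale, 1.0, beads"]
    pml_path = out / "beads.pml"
    pml_path.write_text("\n".join(pml) + "\n")

    hist_path = out / "histogram.tsv"
    rows = ["# per-spot minimum total energy histogram (kcal/mol)",
            f"# bins={'fd' if bins is None else bins}",
            "bin_left\tbin_right\tcount"]
    for i, count in enumerate(report.histogram_counts):
        rows.append(f"{report.histogram_edges[i]:.6f}\t"
                    f"{report.histogram_edges[i+1]:.6f}\t{count}")
    hist_path.write_text("\n".join(rows) + "\n")

    payload = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "ligand": result.ligand_name,
        "backend": result.backend,
        "seed": result.params.seed,
        "n_steps": result.params.n_steps,
        "replicas_per_spot": result.params.replicas_per_spot,
        "spot_radius": result.spot_radius,
        "spots": [
            {
                "spot_id": r.spot_id,
                "energy": {"es": r.min_energy.es, "vdw": r.min_energy.vdw,
                           "hbond": r.min_energy.hbond, "total": r.min_energy.total},
                "best_shift": [float(x) for x in r.best_pose[0]],
                "best_quat": [float(x) for x in r.best_pose[1]],
                "best_replica": r.best_replica,
                "acceptance_rate": r.acceptance_rate,
            }
            for r in result.spot_results
        ],
    }
    json_path = out / "results.json"
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return {"poses": pose_paths, "pml": pml_path, "histogram": hist_path,
            "json": json_path}
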