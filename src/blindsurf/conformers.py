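"""Rigid conformer ensembles.

Flexibility is handled outside the search: the user supplies an ensemble of
rigid conformations of the same molecule (a directory of MOL2/PDBQT files),
each of which is screened independently; per spot, the best energy over
conformers is reported.  A single input file is the recommended rigid mode
and degenerates to a plain screen.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .forcefield import ForceField
from .molecules import MoleculeError, read_ligand
from .pipeline import run_screen

__all__ = ["ConformerSet", "EnsembleResult", "load_conformers", "screen_ensemble"]


@dataclass(frozen=True)
class ConformerSet:
    """Rigid conformations sharing atom identity (count, types, charges)."""

    conformers: tuple           # tuple[LigandModel]
    source: str                 # "external files" | "single input"

    def __post_init__(self):
        if not self.conformers:
            raise MoleculeError("empty conformer set")
        first = self.conformers[0]
        for i, c in enumerate(self.conformers[1:], 1):
            if c.nlig != first.nlig or c.lj_types != first.lj_types:
                raise MoleculeError(
                    f"conformer mismatch: {Path(first.source).name or 'conformer 0'} vs "
                    f"{Path(c.source).name or f'conformer {i}'} "
                    f"(atom count/types differ)"
                )

    def __len__(self):
        return len(self.conformers)


def load_conformers(paths, ff: ForceField) -> ConformerSet:
    """Load one conformer per file, all re-centred to the origin."""
    paths = [Path(p) for p in paths]
    if not paths:
        raise MoleculeError("no conformer files supplied")
    models = [read_ligand(p, ff) for p in sorted(paths)]
    return ConformerSet(
        conformers=tuple(models),
        source="single input" if len(models) == 1 else "external files",
    )


@dataclass(frozen=True)
class EnsembleResult:
    """Per-conformer screens plus the element-wise best over conformers."""

    per_conformer: tuple        # tuple[ScreenResult]
    best_conformer_per_spot: tuple  # conformer index attaining each spot minimum
    best_total_per_spot: tuple      # the corresponding minima


def screen_ensemble(conformer_set: ConformerSet, receptor, ff: ForceField,
                    params, **screen_kw) -> EnsembleResult:
    """Screen every conformer and aggregate the per-spot minimum.

    Aggregation is exactly the element-wise min over conformers of each
    spot's minimum energy.
    """
    screens = []
    for i, conf in enumerate(conformer_set.conformers):
        try:
            screens.append(run_screen(receptor, conf, ff, params, **screen_kw))
        except Exception as exc:
            raise RuntimeError(f"screen failed for conformer {i} "
                               f"({Path(conf.source).name})") from exc
    n_spots = len(screens[0].spot_results)
    best_idx, best_tot = [], []
    for s in range(n_spots):
        totals = [sc.spot_results[s].min_energy.total for sc in screens]
        i = min(range(len(totals)), key=totals.__getitem__)
        best_idx.append(i)
        best_tot.append(totals[i])
    return EnsembleResult(per_conformer=tuple(screens),
                          best_conformer_per_spot=tuple(best_idx),
                          best_total_per_spot=tuple(best_tot))
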