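"""Surface spots: the spherical regions where replica batches run.

One spot per residue, centred on its alpha carbon, with a default cutoff
radius of 10 Å.  The spot list can be replaced wholesale by a plain-text
file (one ``x y z [radius]`` line per spot), so any external site-detection
method can drive the screen.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .molecules import Receptor

__all__ = ["Spot", "generate_spots", "load_spots", "thin_spots", "DEFAULT_SPOT_RADIUS"]

DEFAULT_SPOT_RADIUS = 10.0  # Å


@dataclass(frozen=True)
class Spot:
    center: np.ndarray  # (3,) Å
    radius: float       # Å
    spot_id: str

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"spot {self.spot_id}: radius must be > 0")
        c = np.asarray(self.center, dtype=float)
        c.setflags(write=False)
        object.__setattr__(self, "center", c)


def generate_spots(receptor: Receptor, radius: float = DEFAULT_SPOT_RADIUS) -> list:
    """One spot per residue with an alpha carbon, in residue order."""
    if receptor.n_residues == 0:
        raise ValueError("receptor has no alpha carbons: cannot generate spots")
    return [
        Spot(center=receptor.calpha_coords[i], radius=radius, spot_id=receptor.calpha_ids[i])
        for i in range(receptor.n_residues)
    ]


def load_spots(path, default_radius: float = DEFAULT_SPOT_RADIUS) -> list:
    """Load spot centres from a whitespace/comma-separated ``x y z [radius]`` file."""
    path = Path(path)
    spots = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#")[0].strip().replace(",", " ")
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise ValueError(f"{path.name}:{lineno}: expected 'x y z [radius]', got {raw!r}")
        try:
            values = [float(p) for p in parts]
        except ValueError:
            raise ValueError(f"{path.name}:{lineno}: non-numeric field in {raw!r}") from None
        radius = values[3] if len(values) == 4 else default_radius
        spots.append(Spot(center=np.array(values[:3]), radius=radius,
                          spot_id=f"spot{len(spots)}"))
    if not spots:
        raise ValueError(f"{path}: no spots found — refusing to run an empty screen")
    return spots


def thin_spots(spots, min_separation: float) -> list:
    """Optional greedy thinning: keep the first spot, drop later centres closer
    than *min_separation* to any kept centre.  Off by default in the pipeline."""
    kept = []
    for spot in spots:
        if all(np.linalg.norm(spot.center - k.center) >= min_separation for k in kept):
            kept.append(spot)
    return kept
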