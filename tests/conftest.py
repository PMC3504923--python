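"""Shared fixtures: toy force fields, hand-built receptors and the
session-scoped planted-pocket system (generated once, reused everywhere)."""
from __future__ import annotations

import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from blindsurf.fixtures import FixtureSpec, make_fixture_set
from blindsurf.forcefield import ForceField
from blindsurf.molecules import Atom, LigandModel, Receptor
from blindsurf.pipeline import prepare_grids
from blindsurf.spots import generate_spots


@pytest.fixture(scope="session")
def toy_ff() -> ForceField:
    """Explicit two-type force field with constant ε=1 for closed-form checks."""
    return ForceField(
        lj_params={"A": (3.0, 0.2), "B": (2.0, 0.05), "QQ": (1.0, 0.0),
                   "DH": (1.0, 0.02), "AC": (2.8, 0.2)},
        residue_table={},
        ligand_type_map={"A": ("A", "none"), "QQ": ("QQ", "none")},
        hb_params=(1.9, 5.0),
        dielectric_model="constant",
        dielectric_constant=1.0,
    )


def build_receptor(coords, charges, lj_types, hb_roles, ff) -> Receptor:
    """Receptor straight from arrays (first atom doubles as the alpha carbon)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    atoms = [
        Atom(element="X", coord=coords[i], charge=float(charges[i]),
             lj_type=lj_types[i], hb_role=hb_roles[i],
             residue_id="A:TOY1", name=f"X{i+1}")
        for i in range(coords.shape[0])
    ]
    return Receptor.from_atoms(atoms, ff, calpha_coords=[coords[0]],
                               calpha_ids=["A:TOY1"])


def build_ligand(coords, charges, lj_types, hb_roles, ff) -> LigandModel:
    return LigandModel.from_arrays(coords, charges, lj_types, hb_roles, ff)


@pytest.fixture(scope="session")
def random_system(toy_ff):
    """Deterministic random 20-atom receptor + 5-atom ligand for oracle tests."""
    rng = np.random.default_rng(42)
    n_rec, n_lig = 20, 5
    rec = build_receptor(
        rng.uniform(-6, 6, size=(n_rec, 3)),
        rng.uniform(-0.5, 0.5, size=n_rec),
        ["A"] * n_rec,
        ["acceptor" if i % 4 == 0 else "none" for i in range(n_rec)],
        toy_ff,
    )
    lig = build_ligand(
        rng.uniform(-1.5, 1.5, size=(n_lig, 3)),
        rng.uniform(-0.5, 0.5, size=n_lig),
        ["A"] * n_lig,
        ["donor-H" if i == 0 else "none" for i in range(n_lig)],
        toy_ff,
    )
    return rec, lig, toy_ff


@pytest.fixture(scope="session")
def pocket(tmp_path_factory):
    """The default planted-pocket synthetic system, built once per session."""
    d = tmp_path_factory.mktemp("pocket_fixture")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        receptor, probe, ff, reference, paths = make_fixture_set(d, FixtureSpec())
    return SimpleNamespace(receptor=receptor, probe=probe, ff=ff,
                           reference=reference, paths=paths, dir=d,
                           spec=FixtureSpec())


@pytest.fixture(scope="session")
def pocket_screen_setup(pocket):
    """Spots + prebuilt grids for the planted-pocket receptor."""
    spots = generate_spots(pocket.receptor)
    grids = prepare_grids(pocket.receptor, spots, pocket.probe, pocket.ff)
    return spots, grids
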