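"""Scoring function: DIRECT backend closed forms, GRID backend vs the
direct-summation oracle, and batching contracts."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blindsurf.geometry import normalize_quats
from blindsurf.grids import GridSpec, build_es_grid, build_vdw_grid
from blindsurf.scoring import (
    DirectScorer,
    GridScorer,
    EnergyBreakdown,
    score_direct,
    score_grid,
)

from conftest import build_ligand, build_receptor


def test_breakdown_total_is_sum():
    b = EnergyBreakdown.make(1.0, -2.5, 0.25)
    assert b.total == pytest.approx(-1.25, abs=1e-12)
    with pytest.raises(ValueError):
        EnergyBreakdown(es=1.0, vdw=1.0, hbond=0.0, total=0.0)


class TestDirectClosedForms:
    def test_coulomb_unit_charges_at_2A(self, toy_ff):
        """+1/+1 at 2 Å, constant ε = 1, LJ ε = 0: es = 332.06/2."""
        rec = build_receptor([[0, 0, 0]], [1.0], ["QQ"], ["none"], toy_ff)
        lig = build_ligand([[0, 0, 0]], [1.0], ["QQ"], ["none"], toy_ff)
        e = score_direct(rec, np.array([[2.0, 0.0, 0.0]]), lig, toy_ff)
        assert e.es == pytest.approx(166.03, abs=1e-9)
        assert e.vdw == 0.0 and e.hbond == 0.0

    def test_lj_zero_at_sigma_and_minimum_at_rmin(self, toy_ff):
        rec = build_receptor([[0, 0, 0]], [0.0], ["A"], ["none"], toy_ff)
        lig = build_ligand([[0, 0, 0]], [0.0], ["A"], ["none"], toy_ff)
        sigma, eps = 3.0, 0.2  # type A combines with itself
        at_sigma = score_direct(rec, np.array([[sigma, 0, 0]]), lig, toy_ff)
        assert at_sigma.vdw == pytest.approx(0.0, abs=1e-12)
        at_rmin = score_direct(rec, np.array([[2 ** (1 / 6) * sigma, 0, 0]]), lig, toy_ff)
        assert at_rmin.vdw == pytest.approx(-eps, abs=1e-12)

    def test_hbond_minimum_at_equilibrium_distance(self, toy_ff):
        """12-10 well: donor-H vs acceptor at r_eq scores exactly -depth."""
        r_eq, depth = toy_ff.hb_params
        rec = build_receptor([[0, 0, 0]], [0.0], ["QQ"], ["acceptor"], toy_ff)
        lig = build_ligand([[0, 0, 0]], [0.0], ["QQ"], ["donor-H"], toy_ff)
        e = score_direct(rec, np.array([[r_eq, 0.0, 0.0]]), lig, toy_ff)
        assert e.hbond == pytest.approx(-depth, abs=1e-12)
        # no donor/acceptor pairing -> no hbond term
        lig2 = build_ligand([[0, 0, 0]], [0.0], ["QQ"], ["none"], toy_ff)
        assert score_direct(rec, np.array([[r_eq, 0, 0]]), lig2, toy_ff).hbond == 0.0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_joint_translation_rotation_invariance(self, random_system, seed):
        """Moving receptor and posed ligand together changes nothing."""
        rec, lig, ff = random_system
        rng = np.random.default_rng(seed)
        coords = lig.ref_coords + rng.uniform(-8, 8, 3)
        e0 = score_direct(rec, coords, lig, ff)
        t = rng.uniform(-20, 20, 3)
        from blindsurf.geometry import quat_to_matrix

        R = quat_to_matrix(normalize_quats(rng.normal(size=4)))
        rec2 = build_receptor(rec.coords @ R.T + t, rec.charges,
                              ["A"] * rec.n_atoms,
                              ["acceptor" if a else "none" for a in rec.is_acceptor],
                              ff)
        e1 = score_direct(rec2, coords @ R.T + t, lig, ff)
        for name in ("es", "vdw", "hbond", "total"):
            # relative tolerance as well: clash poses reach ~1e7 kcal/mol,
            # where 1e-9 absolute agreement exceeds float64 resolution
            assert getattr(e1, name) == pytest.approx(getattr(e0, name),
                                                      rel=1e-9, abs=1e-9)


class TestGridBackend:
    @pytest.fixture()
    def grids(self, random_system):
        rec, lig, ff = random_system
        es = build_es_grid(rec, GridSpec.enclosing(rec.coords, 0.5, 18.0), ff)
        vdw = build_vdw_grid(rec, GridSpec.enclosing(rec.coords, 2.0, 18.0), 8.0)
        return es, vdw

    def test_neutral_ligand_zero_es(self, random_system, grids, toy_ff):
        rec, lig, ff = random_system
        neutral = build_ligand(lig.ref_coords, np.zeros(lig.nlig),
                               list(lig.lj_types), list(lig.hb_roles), ff)
        e = score_grid(*grids, rec, neutral, (0, 0, 0), (1, 0, 0, 0), ff)
        assert e.es == 0.0

    def test_far_ligand_zero_vdw_hbond(self, random_system, grids):
        """Beyond cutoff + list slack every neighbour list is empty."""
        rec, lig, ff = random_system
        far = np.array([0.0, 0.0, rec.coords[:, 2].max() + 15.0])
        e = score_grid(*grids, rec, lig, far, (1, 0, 0, 0), ff)
        assert e.vdw == 0.0 and e.hbond == 0.0

    def test_grid_vs_direct_oracle(self, random_system, grids):
        """Near-field poses: grid ES tracks direct summation within the
        documented d=0.5 Å tolerance; VDW/HBOND agree exactly because every
        true neighbour is inside the cutoff."""
        rec, lig, ff = random_system
        es, _ = grids
        # cutoff covering every pair: the neighbour lists are complete, so
        # grid VDW/HBOND must equal the no-cutoff direct sums bit-exactly
        vdw = build_vdw_grid(rec, GridSpec.enclosing(rec.coords, 2.0, 18.0), 50.0)
        gs = GridScorer(rec, lig, es, vdw, ff)
        ds = DirectScorer(rec, lig, ff)
        rng = np.random.default_rng(5)
        shifts = rec.coords.mean(axis=0) + rng.uniform(-4, 4, (100, 3))
        quats = normalize_quats(rng.normal(size=(100, 4)))
        g = gs(shifts, quats)
        d = ds(shifts, quats)
        # ES accuracy is only meaningful away from hard clashes, where the
        # node clamp (not interpolation) dominates and VDW rejects the pose
        ok = d.vdw < 50.0
        assert ok.sum() >= 30
        scale = np.maximum(np.abs(d.es[ok]), 1.0)
        assert np.max(np.abs(g.es[ok] - d.es[ok]) / scale) < 0.15
        np.testing.assert_array_equal(g.vdw, d.vdw)
        np.testing.assert_array_equal(g.hbond, d.hbond)

    def test_es_error_shrinks_with_spacing(self, random_system):
        rec, lig, ff = random_system
        ds = DirectScorer(rec, lig, ff)
        rng = np.random.default_rng(9)
        shifts = rec.coords.mean(axis=0) + rng.uniform(-4, 4, (40, 3))
        quats = normalize_quats(rng.normal(size=(40, 4)))
        d = ds(shifts, quats)
        errs = []
        vdw = build_vdw_grid(rec, GridSpec.enclosing(rec.coords, 2.0, 8.0), 8.0)
        for spacing in (1.0, 0.5, 0.25):
            es = build_es_grid(rec, GridSpec.enclosing(rec.coords, spacing, 8.0), ff)
            g = GridScorer(rec, lig, es, vdw, ff)(shifts, quats)
            errs.append(float(np.mean(np.abs(g.es - d.es))))
        assert errs[0] > errs[1] > errs[2]

    def test_batch_equals_singles_bitwise_and_permutes(self, random_system, grids):
        rec, lig, ff = random_system
        gs = GridScorer(rec, lig, *grids, ff)
        rng = np.random.default_rng(13)
        shifts = rec.coords.mean(axis=0) + rng.uniform(-5, 5, (17, 3))
        quats = normalize_quats(rng.normal(size=(17, 4)))
        batch = gs(shifts, quats)
        for i in range(17):
            single = gs(shifts[i:i + 1], quats[i:i + 1])
            assert single.total[0] == batch.total[i]  # bit-identical
        perm = rng.permutation(17)
        permuted = gs(shifts[perm], quats[perm])
        np.testing.assert_array_equal(permuted.total, batch.total[perm])

    def test_receptor_arrays_immutable_during_scoring(self, random_system, grids):
        rec, lig, ff = random_system
        before = rec.coords.copy()
        gs = GridScorer(rec, lig, *grids, ff)
        gs(np.array([rec.coords.mean(axis=0) + 12.0]), np.array([[1.0, 0, 0, 0]]))
        np.testing.assert_array_equal(rec.coords, before)
        with pytest.raises(ValueError):
            rec.coords[0, 0] = 99.0
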