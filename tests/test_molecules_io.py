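"""Structure I/O, parameter assignment and the rigid pose model."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blindsurf.forcefield import ForceField, ForceFieldError
from blindsurf.geometry import normalize_quats
from blindsurf.molecules import (
    MoleculeError,
    apply_pose,
    apply_poses,
    read_ligand,
    read_receptor,
    write_mol2,
)

from conftest import build_ligand

POLY_ALA = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.986  -0.773   1.208  1.00  0.00           C
ATOM      6  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       6.036   1.583   0.000  1.00  0.00           O
ATOM     10  CB  ALA A   2       3.575   3.653   1.232  1.00  0.00           C
ATOM     11  N   ALA A   3       6.207   3.824   0.000  1.00  0.00           N
ATOM     12  CA  ALA A   3       7.663   3.846   0.000  1.00  0.00           C
ATOM     13  C   ALA A   3       8.214   5.266   0.000  1.00  0.00           C
ATOM     14  O   ALA A   3       7.456   6.236   0.000  1.00  0.00           O
ATOM     15  CB  ALA A   3       8.191   3.073   1.208  1.00  0.00           C
END
"""


@pytest.fixture()
def opls():
    return ForceField.default()


class TestReadReceptor:
    def test_three_residue_poly_alanine(self, tmp_path, opls):
        p = tmp_path / "polyala.pdb"
        p.write_text(POLY_ALA)
        rec = read_receptor(p, opls)
        assert rec.n_residues == 3
        assert rec.calpha_coords.shape == (3, 3)
        assert rec.n_atoms == 15
        # every atom typed and charged from the table
        assert np.all(rec.sigmas > 0)
        np.testing.assert_allclose(rec.charges[:5], [-0.47, 0.07, 0.51, -0.51, 0.0])

    def test_multi_model_uses_first_model_only(self, tmp_path, opls):
        body = POLY_ALA.replace("END\n", "")
        shifted = body.replace("   0.000   0.000", "  50.000  50.000")
        p = tmp_path / "two_models.pdb"
        p.write_text(f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{shifted}ENDMDL\nEND\n")
        rec = read_receptor(p, opls)
        assert rec.n_atoms == 15
        np.testing.assert_allclose(rec.coords[1], [1.458, 0.0, 0.0])

    def test_unknown_atom_is_fatal_and_named(self, tmp_path, opls):
        p = tmp_path / "bad.pdb"
        p.write_text(POLY_ALA.replace(" CB  ALA A   1", " XX  ALA A   1"))
        with pytest.raises(ForceFieldError, match="XX.*ALA|ALA.*XX"):
            read_receptor(p, opls)
        rec = read_receptor(p, opls, skip_unknown=True)
        assert rec.n_atoms == 14
        assert rec.n_skipped == 1

    def test_hetatm_excluded_and_missing_file(self, tmp_path, opls):
        p = tmp_path / "het.pdb"
        p.write_text(POLY_ALA.replace("END\n", "")
                     + "HETATM   16  O   HOH A 101      9.000   9.000   9.000"
                       "  1.00  0.00           O\nEND\n")
        assert read_receptor(p, opls).n_atoms == 15
        with pytest.raises(FileNotFoundError):
            read_receptor(tmp_path / "missing.pdb", opls)


class TestReadLigand:
    def _mol2(self, tmp_path, rows):
        lines = ["@<TRIPOS>MOLECULE", "toy", f"{len(rows)} 0 0 0 0", "SMALL",
                 "USER_CHARGES", "@<TRIPOS>ATOM"]
        lines += [f"{i+1} A{i+1} {x} {y} {z} {t} 1 LIG {q}"
                  for i, (x, y, z, t, q) in enumerate(rows)]
        p = tmp_path / "lig.mol2"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_single_atom_centred_with_stored_centroid(self, tmp_path, opls):
        p = self._mol2(tmp_path, [(5.0, 5.0, 5.0, "C.3", -1.0)])
        lig = read_ligand(p, opls)
        np.testing.assert_allclose(lig.ref_coords, [[0.0, 0.0, 0.0]], atol=1e-12)
        np.testing.assert_allclose(lig.input_centroid, [5.0, 5.0, 5.0])
        assert lig.charges[0] == -1.0

    def test_two_atom_centroid_arithmetic(self, tmp_path, opls):
        p = self._mol2(tmp_path, [(0, 0, 0, "C.3", 0.1), (2, 0, 0, "C.3", -0.1)])
        lig = read_ligand(p, opls)
        np.testing.assert_allclose(lig.ref_coords, [[-1, 0, 0], [1, 0, 0]], atol=1e-12)

    def test_ring_centroid_invariant(self, tmp_path, opls):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        rows = [(1.4 * np.cos(a) + 3, 1.4 * np.sin(a) - 2, 0.5, "C.ar", 0.05)
                for a in ang]
        lig = read_ligand(self._mol2(tmp_path, rows), opls)
        assert np.all(np.abs(lig.ref_coords.mean(axis=0)) < 1e-9)

    def test_missing_charge_column_is_fatal(self, tmp_path, opls):
        p = tmp_path / "nocharge.mol2"
        p.write_text("@<TRIPOS>MOLECULE\ntoy\n1 0 0 0 0\nSMALL\nNO_CHARGES\n"
                     "@<TRIPOS>ATOM\n1 C1 0.0 0.0 0.0 C.3\n")
        with pytest.raises(MoleculeError, match="charge"):
            read_ligand(p, opls)

    def test_mol2_roundtrip_preserves_coords_and_charges(self, tmp_path, opls):
        rng = np.random.default_rng(3)
        coords = np.round(rng.uniform(-8, 8, (7, 3)), 4)  # format precision
        charges = rng.uniform(-1, 1, 7)
        p = tmp_path / "rt.mol2"
        write_mol2(p, coords, charges, ["C.3"] * 7)
        lig = read_ligand(p, opls)
        np.testing.assert_allclose(lig.ref_coords + lig.input_centroid, coords,
                                   atol=5e-5)
        np.testing.assert_array_equal(lig.charges, charges)  # charges exact

    def test_pdbqt_charges_and_types(self, tmp_path, opls):
        p = tmp_path / "lig.pdbqt"
        p.write_text(
            "ATOM      1  C1  LIG A   1       1.000   2.000   3.000  1.00  0.00"
            "    +0.180 C \n"
            "ATOM      2  O1  LIG A   1       2.200   2.000   3.000  1.00  0.00"
            "    -0.380 OA\n")
        lig = read_ligand(p, opls)
        assert lig.nlig == 2
        np.testing.assert_allclose(lig.charges, [0.18, -0.38])
        assert lig.hb_roles[1] == "acceptor"


class TestApplyPose:
    def test_identity_rotation_translates(self, random_system):
        _, lig, _ = random_system
        out = apply_pose(lig, (1.0, 2.0, 3.0), (1, 0, 0, 0))
        np.testing.assert_allclose(out, lig.ref_coords + [1, 2, 3], atol=1e-12)

    def test_180deg_about_z(self, toy_ff):
        lig = build_ligand([[1, 0, 0], [-1, 0, 0]], [0, 0], ["A", "A"],
                           ["none", "none"], toy_ff)
        out = apply_pose(lig, (0, 0, 0), (0, 0, 0, 1))  # 180 deg about z
        np.testing.assert_allclose(out, [[-1, 0, 0], [1, 0, 0]], atol=1e-12)

    def test_non_unit_quaternion_rejected(self, random_system):
        _, lig, _ = random_system
        with pytest.raises(ValueError, match="unit"):
            apply_pose(lig, (0, 0, 0), (1.0, 0.1, 0.0, 0.0))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_pose_roundtrip_and_rigidity(self, random_system, seed):
        """Applying a pose then its inverse recovers the original coordinates,
        and every pose preserves all pairwise distances (rigid body)."""
        _, lig, _ = random_system
        rng = np.random.default_rng(seed)
        q = normalize_quats(rng.normal(size=4))
        shift = rng.uniform(-10, 10, 3)
        posed = apply_pose(lig, shift, q)
        q_inv = q * np.array([1.0, -1.0, -1.0, -1.0])
        back = np.einsum("ij,nj->ni", _rotm(q_inv), posed - shift)
        np.testing.assert_allclose(back, lig.ref_coords, atol=1e-9)
        d0 = np.linalg.norm(lig.ref_coords[:, None] - lig.ref_coords[None], axis=-1)
        d1 = np.linalg.norm(posed[:, None] - posed[None], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_batched_poses_match_single(self, random_system):
        _, lig, _ = random_system
        rng = np.random.default_rng(11)
        quats = normalize_quats(rng.normal(size=(6, 4)))
        shifts = rng.uniform(-5, 5, (6, 3))
        batch = apply_poses(lig, shifts, quats)
        for i in range(6):
            np.testing.assert_array_equal(batch[i], apply_pose(lig, shifts[i], quats[i]))


def _rotm(q):
    from blindsurf.geometry import quat_to_matrix

    return quat_to_matrix(np.asarray(q, dtype=float))
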