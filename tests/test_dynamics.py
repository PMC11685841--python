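"""Superposition, RMSF, Rg, DCCM, region summaries, delta-RMSF."""

import numpy as np
import pytest

import thermocomb as tc
from thermocomb.dynamics import DynamicsError, _kabsch


def _random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture(scope="module")
def gaussian_ensemble():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(12, 12)) * 0.15
    cov = A @ A.T + np.eye(12) * 0.05   # CA-scale fluctuations
    e, analytic = tc.generate_correlated_ensemble(12, cov, frames=5000, seed=1)
    return e, analytic, cov


class TestSuperpose:
    def test_rigid_rotations_align_to_zero_rmsd(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 3)) * 5
        frames = np.stack([base @ _random_rotation(rng).T + rng.normal(size=3) * 10
                           for _ in range(6)])
        aligned = tc.superpose(tc.Ensemble(frames))
        mean = aligned.coords.mean(axis=0)
        rmsd = np.sqrt(((aligned.coords - mean) ** 2).sum(axis=2).mean(axis=1))
        assert np.all(rmsd < 1e-9)

    def test_identity_when_already_aligned(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(8, 3))
        frames = np.stack([base + rng.normal(size=(8, 3)) * 0.01 for _ in range(5)])
        e = tc.Ensemble(frames - frames.mean(axis=(0, 1)))
        aligned = tc.superpose(e)
        # per-frame RMSD to the mean must not increase
        def rmsd_to_mean(c):
            m = c.mean(axis=0)
            return np.sqrt(((c - m) ** 2).sum(axis=2).mean(axis=1))
        assert np.all(rmsd_to_mean(aligned.coords) <= rmsd_to_mean(e.coords) + 1e-12)

    def test_alignment_is_rmsd_optimal_against_random_perturbations(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(9, 3)) * 3
        frames = np.stack([base @ _random_rotation(rng).T + rng.normal(size=(9, 3)) * 0.1
                           for _ in range(4)])
        aligned = tc.superpose(tc.Ensemble(frames))
        mean = aligned.coords.mean(axis=0)
        best = np.sqrt(((aligned.coords[0] - mean) ** 2).sum(axis=1).mean())
        for _ in range(100):
            angle = rng.normal(0, 0.05)
            axis_rot = _small_rotation(angle, rng)
            perturbed = aligned.coords[0] @ axis_rot.T
            rmsd = np.sqrt(((perturbed - mean) ** 2).sum(axis=1).mean())
            assert rmsd >= best - 1e-12

    def test_too_few_atoms_rejected(self):
        with pytest.raises(DynamicsError):
            tc.superpose(tc.Ensemble(np.zeros((3, 2, 3))))


def _small_rotation(angle, rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestRmsf:
    def test_static_ensemble_is_zero(self):
        coords = np.tile(np.arange(15.0).reshape(5, 3), (4, 1, 1))
        prof = tc.rmsf(tc.Ensemble(coords, superposed=True))
        assert np.allclose(prof, 0.0)

    def test_two_frame_oscillation_closed_form(self):
        d = 0.8
        coords = np.zeros((2, 4, 3))
        coords[0, 2, 0] = +d
        coords[1, 2, 0] = -d
        prof = tc.rmsf(tc.Ensemble(coords, superposed=True))
        assert prof[2] == pytest.approx(d)
        assert np.allclose(np.delete(prof, 2), 0.0)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        sigma = 0.5
        rng = np.random.default_rng(5)
        coords = rng.normal(0, sigma, size=(2000, 6, 3))
        prof = tc.rmsf(tc.Ensemble(coords, superposed=True))
        assert np.allclose(prof, sigma * np.sqrt(3), rtol=0.05)

    def test_unsuperposed_input_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="superposed"):
            tc.rmsf(tc.Ensemble(rng.normal(size=(4, 5, 3))))


class TestRadiusOfGyration:
    def test_coincident_atoms_give_zero(self):
        coords = np.ones((3, 7, 3)) * 2.5
        assert np.allclose(tc.radius_of_gyration(tc.Ensemble(coords)), 0.0)

    def test_two_atoms_2A_apart_give_1A(self):
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = 2.0
        assert np.allclose(tc.radius_of_gyration(tc.Ensemble(coords)), 1.0)

    def test_matches_independent_com_oracle(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(5, 9, 3)) * 4
        got = tc.radius_of_gyration(tc.Ensemble(coords))
        for f in range(5):
            com = coords[f].sum(axis=0) / 9
            expected = np.sqrt(sum(((coords[f, i] - com) ** 2).sum()
                                   for i in range(9)) / 9)
            assert got[f] == pytest.approx(expected, abs=1e-9)

    def test_mass_weighting_changes_com(self):
        coords = np.zeros((2, 2, 3))
        coords[:, 1, 0] = 2.0
        rg_uniform = tc.radius_of_gyration(tc.Ensemble(coords))
        rg_weighted = tc.radius_of_gyration(tc.Ensemble(coords),
                                            masses=np.array([3.0, 1.0]))
        assert rg_weighted[0] < rg_uniform[0]  # COM pulled toward heavy atom


class TestDccm:
    def test_diagonal_is_one_and_symmetric(self, gaussian_ensemble):
        e, _, _ = gaussian_ensemble
        C = tc.dccm(e)
        assert np.allclose(np.diag(C.matrix), 1.0)
        assert np.allclose(C.matrix, C.matrix.T)
        assert np.nanmax(np.abs(C.matrix)) <= 1.0 + 1e-12

    def test_mirror_motion_gives_minus_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=300)
        coords = np.zeros((300, 3, 3))
        coords[:, 0, 0] = x
        coords[:, 1, 0] = -x
        coords[:, 2, 1] = rng.normal(size=300)
        C = tc.dccm(tc.Ensemble(coords, superposed=True))
        assert C.matrix[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_empirical_matches_analytic_within_005_at_5000_frames(self, gaussian_ensemble):
        e, analytic, _ = gaussian_ensemble
        C = tc.dccm(e)
        assert np.nanmax(np.abs(C.matrix - analytic)) < 0.05

    def test_invariant_under_global_rigid_motion(self, gaussian_ensemble):
        e, _, _ = gaussian_ensemble
        ref = tc.dccm(tc.superpose(e))
        rng = np.random.default_rng(9)
        R = _random_rotation(rng)
        moved = tc.Ensemble(e.coords @ R.T + np.array([10.0, -4.0, 2.0]))
        got = tc.dccm(tc.superpose(moved))
        assert np.nanmax(np.abs(got.matrix - ref.matrix)) < 1e-6

    def test_independent_atoms_converge_to_identity(self):
        rng = np.random.default_rng(10)
        F = 4000
        coords = rng.normal(size=(F, 8, 3))
        C = tc.dccm(tc.Ensemble(coords, superposed=True))
        off = C.matrix[~np.eye(8, dtype=bool)]
        assert np.max(np.abs(off)) < 3.0 / np.sqrt(F)

    def test_replicate_averaging_is_elementwise_mean(self, gaussian_ensemble):
        e, _, cov = gaussian_ensemble
        e2, _ = tc.generate_correlated_ensemble(12, cov, frames=500, seed=42)
        c1 = tc.dccm(e).matrix
        c2 = tc.dccm(e2).matrix
        avg = tc.dccm([e, e2])
        assert np.allclose(avg.matrix, (c1 + c2) / 2)
        assert avg.n_replicates == 2

    def test_zero_variance_atom_flagged(self):
        coords = np.random.default_rng(11).normal(size=(50, 4, 3))
        coords[:, 2, :] = 1.0  # frozen atom
        C = tc.dccm(tc.Ensemble(coords, superposed=True))
        assert C.flagged[2].all() and C.flagged[:, 2].all()
        assert np.isnan(C.matrix[2, 0])


class TestRegionsAndDeltaRmsf:
    def test_single_residue_self_block_is_one(self, gaussian_ensemble):
        e, _, _ = gaussian_ensemble
        C = tc.dccm(e)
        s = tc.region_correlation(C, (3, 3), (3, 3))
        assert s["mean"] == pytest.approx(1.0)

    def test_anticorrelated_pair_block(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=400)
        coords = np.zeros((400, 2, 3))
        coords[:, 0, 0] = x
        coords[:, 1, 0] = -x
        C = tc.dccm(tc.Ensemble(coords, superposed=True))
        s = tc.region_correlation(C, (1, 1), (2, 2))
        assert s["mean"] == pytest.approx(-1.0, abs=1e-9)

    def test_cross_block_mean_equals_double_loop(self, gaussian_ensemble):
        e, _, _ = gaussian_ensemble
        C = tc.dccm(e)
        s = tc.region_correlation(C, (1, 4), (6, 9))
        oracle = np.mean([C.matrix[i, j] for i in range(0, 4) for j in range(5, 9)])
        assert s["mean"] == pytest.approx(oracle, abs=1e-12)

    def test_out_of_range_region_rejected(self, gaussian_ensemble):
        e, _, _ = gaussian_ensemble
        C = tc.dccm(e)
        with pytest.raises(DynamicsError):
            tc.region_correlation(C, (0, 3), (5, 6))
        with pytest.raises(DynamicsError):
            tc.region_correlation(C, (1, 3), (5, 99))

    def test_identical_profiles_give_zero_delta(self):
        prof = np.array([0.5, 0.8, 1.2])
        assert np.allclose(tc.delta_rmsf(prof, prof), 0.0)

    def test_uniform_10pct_reduction(self):
        wt = np.array([1.0, 2.0, 0.5])
        assert np.allclose(tc.delta_rmsf(0.9 * wt, wt), -0.1)
        assert np.allclose(tc.delta_rmsf(0.9 * wt, wt, normalize=False),
                           -0.1 * wt)

    def test_planted_stabilized_region_has_negative_delta(self):
        # variant variance reduced on atoms 5..8 only
        n = 12
        base_var = np.full(n, 0.3)
        var_variant = base_var.copy()
        var_variant[5:9] *= 0.25
        e_wt, _ = tc.generate_correlated_ensemble(n, np.diag(base_var),
                                                  frames=3000, seed=13)
        e_mut, _ = tc.generate_correlated_ensemble(n, np.diag(var_variant),
                                                   frames=3000, seed=14)
        d = tc.delta_rmsf(tc.rmsf(e_mut), tc.rmsf(e_wt))
        assert np.all(d[5:9] < 0)
        assert np.all(np.abs(d[[0, 1, 2, 3, 4, 9, 10, 11]]) < 0.25)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DynamicsError):
            tc.delta_rmsf(np.ones(4), np.ones(5))


class TestReaders:
    def test_xyz_round_trip(self, tmp_path):
        rng = np.random.default_rng(15)
        e = tc.Ensemble(rng.normal(size=(4, 6, 3)) * 3)
        path = tmp_path / "traj.xyz"
        from thermocomb.dynamics import write_xyz_ensemble
        write_xyz_ensemble(path, e)
        back = tc.read_xyz_ensemble(path)
        assert back.coords.shape == (4, 6, 3)
        assert np.allclose(back.coords, e.coords, atol=1e-5)

    def test_multi_model_pdb_reader_selects_ca(self, tmp_path):
        pdb = tmp_path / "ens.pdb"
        lines = []
        coords = {1: [(1.0, 2.0, 3.0), (4.0, 5.0, 6.0)],
                  2: [(1.1, 2.1, 3.1), (4.1, 5.1, 6.1)]}
        for model, atoms in coords.items():
            lines.append(f"MODEL     {model:4d}")
            serial = 1
            for res, (x, y, z) in enumerate(atoms, start=1):
                lines.append(
                    f"ATOM  {serial:5d}  N   ALA A{res:4d}    "
                    f"{x - 0.5:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           N")
                serial += 1
                lines.append(
                    f"ATOM  {serial:5d}  CA  ALA A{res:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
                serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        pdb.write_text("\n".join(lines) + "\n")
        e = tc.read_pdb_ensemble(pdb)
        assert e.coords.shape == (2, 2, 3)
        assert np.allclose(e.coords[0, 0], [1.0, 2.0, 3.0])
        assert np.allclose(e.coords[1, 1], [4.1, 5.1, 6.1])
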