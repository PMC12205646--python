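"""Superposition, cross-correlation matrices and region-pair totals."""

import numpy as np
import pytest

from clampdyn.dccm import (
    DCCMResult,
    RegionDefinition,
    TrajectoryWindow,
    compute_dccm,
    superpose,
    total_correlation,
    windowed_dccm_series,
)
from clampdyn import synthetic as syn


def _brute_force_dccm(coords):
    """Independent double-loop DCCM implementation (oracle)."""
    n_frames, n_atoms, _ = coords.shape
    mean = coords.mean(axis=0)
    d = coords - mean
    c = np.empty((n_atoms, n_atoms))
    for i in range(n_atoms):
        for j in range(n_atoms):
            num = sum(float(d[f, i] @ d[f, j]) for f in range(n_frames)) / n_frames
            vi = sum(float(d[f, i] @ d[f, i]) for f in range(n_frames)) / n_frames
            vj = sum(float(d[f, j] @ d[f, j]) for f in range(n_frames)) / n_frames
            c[i, j] = num / np.sqrt(vi * vj)
    return c


def _kabsch_rmsd(mobile, ref):
    """Closed-form Kabsch: optimal superposition RMSD (oracle)."""
    pm = mobile - mobile.mean(axis=0)
    pr = ref - ref.mean(axis=0)
    h = pm.T @ pr
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    aligned = pm @ rot.T
    return float(np.sqrt(np.mean(np.sum((aligned - pr) ** 2, axis=1))))


def _toy_window(coords, frame_spacing_ns=10.0):
    n_atoms = coords.shape[1]
    return TrajectoryWindow(
        coords=coords,
        residues=np.arange(1, n_atoms + 1),
        atom_names=np.array(["CA"] * n_atoms, dtype=object),
        frame_spacing_ns=frame_spacing_ns,
    )


class TestSuperpose:
    def test_rigid_transformed_frames_return_to_reference(self, rng):
        from scipy.spatial.transform import Rotation

        base = rng.normal(0, 3, (8, 3))
        frames = [base]
        for _ in range(4):
            rot = Rotation.random(rng=rng)
            frames.append(rot.apply(base) + rng.normal(0, 5, 3))
        window = _toy_window(np.array(frames))
        out = superpose(window, fit_atom_names=("CA",))
        for k in range(5):
            np.testing.assert_allclose(out.coords[k], base, atol=1e-8)

    def test_identity_input_unchanged(self, rng):
        base = rng.normal(0, 3, (6, 3))
        window = _toy_window(np.stack([base, base]))
        out = superpose(window, fit_atom_names=("CA",))
        np.testing.assert_allclose(out.coords, window.coords, atol=1e-10)

    def test_rmsd_matches_independent_kabsch(self, rng):
        ref = rng.normal(0, 3, (10, 3))
        mob = ref + rng.normal(0, 0.5, (10, 3))
        window = _toy_window(np.stack([ref, mob]))
        out = superpose(window, fit_atom_names=("CA",))
        got = float(
            np.sqrt(np.mean(np.sum((out.coords[1] - out.coords[0]) ** 2, axis=1)))
        )
        assert got == pytest.approx(_kabsch_rmsd(mob, ref), abs=1e-8)

    def test_rmsd_never_increases(self, rng):
        ref = rng.normal(0, 3, (12, 3))
        frames = np.stack([ref] + [ref + rng.normal(0, 1.0, (12, 3)) for _ in range(3)])
        window = _toy_window(frames)
        out = superpose(window, fit_atom_names=("CA",))
        for k in range(1, 4):
            before = np.sqrt(np.mean(np.sum((frames[k] - ref) ** 2, axis=1)))
            after = np.sqrt(np.mean(np.sum((out.coords[k] - ref) ** 2, axis=1)))
            assert after <= before + 1e-12

    def test_underdetermined_fit_selection_rejected(self, rng):
        window = _toy_window(rng.normal(0, 1, (3, 5, 3)))
        with pytest.raises(ValueError, match="underdetermined"):
            superpose(window, fit_first_res=1, fit_last_res=2,
                      fit_atom_names=("CA",))


class TestComputeDCCM:
    def test_shared_displacement_gives_all_ones(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 3, (4, 3))
        shifts = rng.normal(0, 1, (12, 3))
        coords = base[None, :, :] + shifts[:, None, :]
        res = compute_dccm(_toy_window(coords))
        np.testing.assert_allclose(res.matrix, 1.0, atol=1e-10)

    def test_equal_and_opposite_motion_anticorrelated(self):
        t = np.linspace(0, 2 * np.pi, 16)
        x = np.sin(t)
        coords = np.zeros((16, 2, 3))
        coords[:, 0, 0] = x
        coords[:, 1, 0] = -x
        coords[:, 1, 2] = 10.0  # spatial separation only
        res = compute_dccm(_toy_window(coords))
        assert res.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        coords = rng.normal(0, 1, (30, 7, 3))
        res = compute_dccm(_toy_window(coords))
        np.testing.assert_allclose(
            res.matrix, _brute_force_dccm(coords), rtol=1e-12, atol=1e-12
        )

    def test_prescribed_pairwise_correlation_recovered(self):
        n_frames = 4000
        window, _ = syn.gen_correlated_trajectory(
            region_sizes=(1, 1), within_corr=1.0, between_corr=0.6,
            n_frames=n_frames, seed=5,
        )
        res = compute_dccm(window)
        # sampling SD of a correlation estimate from 3*n_frames samples
        sd = (1 - 0.6**2) / np.sqrt(3 * n_frames)
        assert abs(res.matrix[0, 1] - 0.6) < 3 * sd

    def test_zero_variance_atom_rejected(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 0, 0] = np.arange(5.0)
        with pytest.raises(ValueError, match="zero-variance"):
            compute_dccm(_toy_window(coords))

    def test_few_frames_warns(self, rng):
        coords = rng.normal(0, 1, (4, 3, 3))
        with pytest.warns(UserWarning, match="frames"):
            compute_dccm(_toy_window(coords))

    def test_invariant_under_global_rotation_after_superposition(self, rng):
        window, _ = syn.gen_correlated_trajectory(
            region_sizes=(3, 4), n_frames=40, seed=11, rigid_motion=False
        )
        rigid, _ = syn.gen_correlated_trajectory(
            region_sizes=(3, 4), n_frames=40, seed=11, rigid_motion=True
        )
        a = compute_dccm(superpose(window, fit_atom_names=("CA",)))
        b = compute_dccm(superpose(rigid, fit_atom_names=("CA",)))
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-8)


class TestTotalCorrelation:
    def _result(self, matrix):
        n = matrix.shape[0]
        return DCCMResult(matrix=matrix, residues=np.arange(1, n + 1))

    def test_all_ones_disjoint_regions(self):
        res = self._result(np.ones((7, 7)))
        a = RegionDefinition("a", 1, 3)
        b = RegionDefinition("b", 4, 7)
        assert total_correlation(res, a, b) == 12.0

    def test_identity_matrix_gives_zero(self):
        res = self._result(np.eye(6))
        a = RegionDefinition("a", 1, 3)
        b = RegionDefinition("b", 4, 6)
        assert total_correlation(res, a, b) == 0.0

    def test_region_with_itself_counts_each_pair_once(self):
        res = self._result(np.ones((4, 4)))
        a = RegionDefinition("a", 1, 4)
        assert total_correlation(res, a, a) == 6.0  # 4*3/2

    def test_symmetric_in_region_arguments(self, rng):
        m = rng.normal(0, 1, (9, 9))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        res = self._result(m)
        a = RegionDefinition("a", 1, 4)
        b = RegionDefinition("b", 3, 8)  # overlapping on purpose
        assert total_correlation(res, a, b) == pytest.approx(
            total_correlation(res, b, a), rel=1e-12
        )

    def test_matches_brute_force_pair_enumeration(self, rng):
        m = rng.normal(0, 1, (10, 10))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        res = self._result(m)
        a = RegionDefinition("a", 2, 6)
        b = RegionDefinition("b", 5, 9)
        pairs = set()
        for i in range(2, 6 + 1):
            for j in range(5, 9 + 1):
                if i != j:
                    pairs.add(frozenset((i, j)))
        # residues are 1-based; the matrix is 0-indexed
        expected = sum(
            m[min(q) - 1, max(q) - 1] for q in (tuple(p) for p in pairs)
        )
        assert total_correlation(res, a, b) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_disjoint_subregions(self, rng):
        m = rng.normal(0, 1, (12, 12))
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        res = self._result(m)
        a1 = RegionDefinition("a1", 1, 3)
        a2 = RegionDefinition("a2", 4, 6)
        a = RegionDefinition("a", 1, 6)
        b = RegionDefinition("b", 7, 12)
        total_union = total_correlation(res, a, b)
        total_parts = total_correlation(res, a1, b) + total_correlation(res, a2, b)
        assert total_union == pytest.approx(total_parts, rel=1e-12)

    def test_disjoint_from_matrix_residues_rejected(self):
        res = self._result(np.ones((4, 4)))
        with pytest.raises(ValueError):
            total_correlation(
                res, RegionDefinition("x", 90, 95), RegionDefinition("a", 1, 2)
            )


class TestBlockRecovery:
    def test_between_region_correlation_within_sampling_band(self):
        # the paper-like design: 80 frames at 10 ns over 800 ns
        rho = -0.5
        window, truth = syn.gen_correlated_trajectory(
            region_sizes=(14, 32), within_corr=0.8, between_corr=rho,
            n_frames=80, seed=13,
        )
        res = compute_dccm(superpose(window, fit_atom_names=("CA",)))
        n1 = truth["region_sizes"][0]
        between = res.matrix[:n1, n1:]
        sd = (1 - rho**2) / np.sqrt(3 * 80)
        assert abs(between.mean() - rho) < 3 * sd


class TestWindowedSeries:
    def test_full_window_equals_direct_dccm(self):
        window, _ = syn.gen_correlated_trajectory(
            region_sizes=(3, 3), n_frames=81, seed=3
        )
        sup = superpose(window, fit_atom_names=("CA",))
        direct = compute_dccm(sup)
        series = windowed_dccm_series(window, step_ns=10.0, window_ns=800.0)
        assert len(series) == 1
        np.testing.assert_allclose(series[0].matrix, direct.matrix, atol=1e-8)

    def test_constant_trajectory_rejected(self):
        coords = np.zeros((20, 4, 3))
        coords += np.arange(4)[None, :, None]  # distinct but constant atoms
        window = _toy_window(coords)
        with pytest.raises(ValueError, match="zero-variance|underdetermined"):
            windowed_dccm_series(window, step_ns=10.0, window_ns=100.0)

    def test_step_larger_than_window_rejected(self):
        window, _ = syn.gen_correlated_trajectory(n_frames=40, seed=0)
        with pytest.raises(ValueError, match="step"):
            windowed_dccm_series(window, step_ns=100.0, window_ns=50.0)

    def test_stationary_process_tiled_windows_agree(self):
        window, _ = syn.gen_correlated_trajectory(
            region_sizes=(6, 6), within_corr=0.8, between_corr=-0.5,
            n_frames=161, seed=9,
        )
        series = windowed_dccm_series(
            window, step_ns=10.0, window_ns=400.0, mode="tile"
        )
        # 1600 ns of trajectory tiles into four 400 ns windows (shared
        # endpoint frames)
        assert len(series) == 4
        a = RegionDefinition("a", 1, 6)
        b = RegionDefinition("b", 7, 12)
        totals = [total_correlation(r, a, b) for r in series]
        # 36 pair sums of correlations, each with sampling SD ~ (1-ρ²)/√(3·41);
        # allow a generous shared band across window placements
        sd_sum = 36 * (1 - 0.25) / np.sqrt(3 * 41)
        assert max(totals) - min(totals) < 3 * sd_sum
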