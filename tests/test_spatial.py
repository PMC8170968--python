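"""Delay windows, CSSP stacking, and the CSP generalized eigenproblem."""

import numpy as np
import pytest

from spectra_bci.spatial import (
    ProcessId,
    WindowSpec,
    apply_filters,
    csp_features,
    csp_from_covariances,
    learn_csp,
    make_cssp_windows,
    make_windows,
)


class TestMakeWindows:
    def test_offsets_and_length(self, rng):
        epoch = rng.standard_normal((4, 200))
        windows = make_windows(epoch, WindowSpec(n_windows=3, tau=10))
        assert len(windows) == 3
        for i, w in enumerate(windows):
            assert w.shape == (4, 180)
            assert np.array_equal(w, epoch[:, i * 10:i * 10 + 180])

    def test_single_window_is_whole_epoch(self, rng):
        epoch = rng.standard_normal((3, 50))
        (w,) = make_windows(epoch, WindowSpec(n_windows=1, tau=17))
        assert np.array_equal(w, epoch)

    def test_tau_zero_gives_identical_windows(self, rng):
        epoch = rng.standard_normal((3, 50))
        windows = make_windows(epoch, WindowSpec(n_windows=3, tau=0))
        for w in windows:
            assert np.array_equal(w, epoch)

    def test_excessive_delay_rejected(self):
        with pytest.raises(ValueError):
            make_windows(np.zeros((2, 20)), WindowSpec(n_windows=3, tau=10))


class TestCsspWindows:
    def test_three_windows_give_three_ordered_pairs(self, rng):
        windows = [rng.standard_normal((10, 30)) for _ in range(3)]
        out = make_cssp_windows(windows)
        pids = [pid for pid, _ in out]
        assert pids == [
            ProcessId("cssp_tsm", 0, 1),
            ProcessId("cssp_tsm", 0, 2),
            ProcessId("cssp_tsm", 1, 2),
        ]
        for (pid, stacked) in out:
            assert stacked.shape == (20, 30)
            assert np.array_equal(stacked[:10], windows[pid.window_i])
            assert np.array_equal(stacked[10:], windows[pid.window_j])

    @pytest.mark.parametrize("n,count", [(2, 1), (3, 3), (4, 6), (1, 0)])
    def test_pair_count_formula(self, rng, n, count):
        windows = [rng.standard_normal((3, 10)) for _ in range(n)]
        assert len(make_cssp_windows(windows)) == count

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            make_cssp_windows([rng.standard_normal((3, 10)),
                               rng.standard_normal((3, 11))])


def random_trials(rng, n, c, t, cov=None):
    if cov is None:
        cov = np.eye(c)
    chol = np.linalg.cholesky(cov)
    return np.einsum("cd,ndt->nct", chol, rng.standard_normal((n, c, t)))


class TestLearnCsp:
    def test_analytic_two_channel_solution(self):
        bank = csp_from_covariances(np.diag([2.0, 1.0]), np.diag([1.0, 2.0]), m=1)
        assert np.allclose(sorted(bank.eigvals), [1 / 3, 2 / 3])
        # filters are the coordinate axes (up to normalization)
        for col in bank.W.T:
            assert np.isclose(np.abs(col).min(), 0.0, atol=1e-12)

    def test_equal_classes_give_half_eigenvalues(self, rng):
        from tests_helpers import random_spd_matrix

        C = random_spd_matrix(rng, 4)
        bank = csp_from_covariances(C, C, m=2)
        assert np.allclose(bank.eigvals, 0.5)

    def test_composite_whitening_and_joint_diagonalization(self, rng):
        trials_p = random_trials(rng, 30, 5, 100, cov=np.diag([5, 1, 1, 1, 1.0]))
        trials_n = random_trials(rng, 30, 5, 100, cov=np.diag([1, 1, 1, 1, 5.0]))
        trials = np.concatenate([trials_p, trials_n])
        labels = np.array([1] * 30 + [-1] * 30)
        from spectra_bci.spatial import class_mean_covariances

        cp, cn = class_mean_covariances(trials, labels)
        bank = learn_csp(trials, labels, m=2)
        ident = bank.W.T @ (cp + cn) @ bank.W
        assert np.allclose(ident, np.eye(4), atol=1e-8)
        for C in (cp, cn):
            D = bank.W.T @ C @ bank.W
            assert np.allclose(D, np.diag(np.diag(D)), atol=1e-8)

    def test_top_filter_beats_random_directions(self, rng):
        """Brute-force oracle: no random unit direction achieves a better
        class-variance ratio than the first learned filter."""
        trials_p = random_trials(rng, 40, 4, 80, cov=np.diag([3, 1.5, 1, 0.5]))
        trials_n = random_trials(rng, 40, 4, 80, cov=np.diag([0.5, 1, 1.5, 3.0]))
        trials = np.concatenate([trials_p, trials_n])
        labels = np.array([1] * 40 + [-1] * 40)
        from spectra_bci.spatial import class_mean_covariances

        cp, cn = class_mean_covariances(trials, labels)
        bank = learn_csp(trials, labels, m=1)
        w0 = bank.W[:, 0]
        best = (w0 @ cp @ w0) / (w0 @ cn @ w0)
        dirs = rng.standard_normal((10_000, 4))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ratios = np.einsum("kc,cd,kd->k", dirs, cp, dirs) / \
            np.einsum("kc,cd,kd->k", dirs, cn, dirs)
        assert best >= ratios.max() - 1e-12

    def test_label_swap_reverses_filter_order(self, rng):
        trials = random_trials(rng, 40, 4, 60)
        trials[:20] *= np.array([2.0, 1, 1, 1])[:, None]
        labels = np.array([1] * 20 + [-1] * 20)
        bank = learn_csp(trials, labels, m=2)
        swapped = learn_csp(trials, -labels, m=2)
        # top/bottom blocks exchange and eigenvalues map to 1 - lambda
        expected = 1.0 - np.concatenate([bank.eigvals[2:], bank.eigvals[:2]])
        assert np.allclose(swapped.eigvals, expected, atol=1e-10)
        # filters reappear with the two m-blocks exchanged (signs fixed)
        assert np.allclose(np.abs(swapped.W),
                           np.abs(np.concatenate([bank.W[:, 2:], bank.W[:, :2]], axis=1)),
                           atol=1e-8)

    def test_one_class_input_rejected(self, rng):
        trials = random_trials(rng, 10, 3, 50)
        with pytest.raises(ValueError):
            learn_csp(trials, np.ones(10), m=1)

    def test_nonfinite_trial_rejected(self, rng):
        trials = random_trials(rng, 10, 3, 50)
        trials[3, 1, 4] = np.nan
        labels = np.array([1, -1] * 5)
        with pytest.raises(ValueError):
            learn_csp(trials, labels, m=1)

    def test_tau_zero_cssp_stack_is_regularized(self, rng):
        """Duplicated channels make the stacked covariance singular; the
        ridge keeps CSP solvable with the same achievable variance ratio."""
        trials = random_trials(rng, 30, 3, 60)
        trials[:15] *= np.array([2.0, 1, 1])[:, None]
        labels = np.array([1] * 15 + [-1] * 15)
        stacked = np.concatenate([trials, trials], axis=1)
        single = learn_csp(trials, labels, m=1)
        doubled = learn_csp(stacked, labels, m=1)
        assert np.allclose(doubled.eigvals, single.eigvals, atol=1e-4)


class TestApplyFilters:
    def test_matches_matrix_product(self, rng):
        from spectra_bci.spatial import SpatialFilterBank

        W = rng.standard_normal((3, 2))
        bank = SpatialFilterBank(W=W, eigvals=np.array([0.7, 0.3]), m=1)
        X = rng.standard_normal((3, 5))
        assert np.allclose(apply_filters(bank, X), W.T @ X)
        batch = rng.standard_normal((4, 3, 5))
        out = apply_filters(bank, batch)
        assert out.shape == (4, 2, 5)
        assert np.allclose(out[2], W.T @ batch[2])

    def test_shape_mismatch_rejected(self, rng):
        from spectra_bci.spatial import SpatialFilterBank

        bank = SpatialFilterBank(W=np.eye(3), eigvals=np.ones(3), m=1)
        with pytest.raises(ValueError):
            apply_filters(bank, rng.standard_normal((4, 5)))


class TestCspFeatures:
    def test_equal_variance_rows(self, rng):
        Z = rng.standard_normal((6, 1000))
        Z /= Z.std(axis=1, ddof=1, keepdims=True)
        f = csp_features(Z)
        assert np.allclose(f, np.log(1 / 6), atol=1e-12)

    def test_direct_formula(self, rng):
        Z = rng.standard_normal((6, 500))
        Z /= Z.std(axis=1, ddof=1, keepdims=True)
        Z *= np.sqrt(np.arange(1, 7))[:, None]
        f = csp_features(Z)
        v = Z.var(axis=1, ddof=1)
        assert np.allclose(f, np.log(v / v.sum()))
        assert np.allclose(np.exp(f), v / 21 / (v.sum() / 21), atol=1e-12)

    def test_scale_invariance_and_normalization(self, rng):
        Z = rng.standard_normal((4, 100))
        f = csp_features(Z)
        assert np.allclose(csp_features(-3.7 * Z), f, atol=1e-12)
        assert np.isclose(np.exp(f).sum(), 1.0)

    def test_zero_variance_row_floored_with_warning(self, rng):
        Z = rng.standard_normal((3, 50))
        Z[1] = 2.0
        with pytest.warns(RuntimeWarning):
            f = csp_features(Z)
        assert np.isfinite(f).all()
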