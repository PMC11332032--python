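"""Tests for the sparse CCA core, projection scoring, and classical CCA."""

import numpy as np
import pytest

from holdoutcca import (
    PenaltyPair,
    VariateScores,
    classical_cca,
    covariance_explained,
    scca_fit,
    scca_project,
)
from holdoutcca._utils import abs_cosine, fix_sign, standardize_columns
from holdoutcca.scca import _unit_l1_project, l1_bound


class TestPenaltyPair:
    def test_behavior_constraint(self):
        with pytest.raises(ValueError, match="0.5"):
            PenaltyPair(0.8, 0.5)

    def test_off_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            PenaltyPair(0.85, 0.7)

    def test_l1_bound_clamped_at_one(self):
        assert l1_bound(0.0, 100) == 1.0
        assert l1_bound(0.8, 100) == pytest.approx(8.0)


class TestUnitL1Project:
    def test_respects_bound_and_unit_norm(self, rng):
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 30))
            s = rng.uniform(1.0, np.sqrt(a.size))
            u = _unit_l1_project(a, s)
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-9)
            assert np.abs(u).sum() <= s + 1e-6

    def test_bound_one_gives_coordinate_vector(self):
        u = _unit_l1_project(np.array([3.0, -1.0, 0.5]), 1.0)
        assert np.count_nonzero(u) == 1
        assert u[0] == pytest.approx(1.0)


class TestSCCAFit:
    def test_perfect_association(self, rng):
        # X columns mutually uncorrelated (orthogonal to each other and to the
        # intercept), so the covariance maximizer is exactly the shared column
        Q = np.linalg.qr(np.column_stack([np.ones(30), rng.normal(size=(30, 3))]))[0]
        X = Q[:, 1:]
        Y = X[:, [0]]
        model = scca_fit(X, Y, PenaltyPair(1.0, 1.0), d=1)
        assert abs(model.train_correlations[0]) == pytest.approx(1.0, abs=1e-8)
        assert abs(model.u[0, 0]) > 0.999

    def test_tight_l1_bound_gives_one_sparse_loading(self, rng):
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 2))
        model = scca_fit(X, Y, PenaltyPair(0.0, 0.6), d=1)  # brain bound clamps to 1
        assert np.count_nonzero(model.u[:, 0]) == 1

    def test_inactive_penalties_match_leading_singular_pair(self, rng):
        X = np.linalg.qr(rng.normal(size=(50, 4)))[0]
        Y = np.linalg.qr(rng.normal(size=(50, 3)))[0]
        model = scca_fit(X, Y, PenaltyPair(1.0, 1.0), d=1)
        C = standardize_columns(X).T @ standardize_columns(Y)
        U, _, Vt = np.linalg.svd(C)
        assert abs_cosine(model.u[:, 0], U[:, 0]) > 1 - 1e-6
        assert abs_cosine(model.v[:, 0], Vt[0]) > 1 - 1e-6

    def test_sparsity_monotone_in_brain_penalty(self):
        """More generous l1 bounds never decrease the support size."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(60, 12))
            Y = rng.normal(size=(60, 5)) + 0.3 * X[:, :5]
            nnz = [
                np.count_nonzero(
                    scca_fit(X, Y, PenaltyPair(c, 0.8), d=1).u[:, 0]
                )
                for c in (0.2, 0.4, 0.6, 0.8, 1.0)
            ]
            assert nnz == sorted(nnz)

    def test_scale_invariance(self, rng):
        X = rng.normal(size=(50, 6))
        Y = rng.normal(size=(50, 4))
        a = scca_fit(X, Y, PenaltyPair(0.8, 0.7), d=2)
        b = scca_fit(3.7 * X, Y, PenaltyPair(0.8, 0.7), d=2)
        np.testing.assert_allclose(
            a.train_correlations, b.train_correlations, atol=1e-8
        )

    def test_sign_convention_idempotent(self, rng):
        X = rng.normal(size=(40, 5))
        Y = rng.normal(size=(40, 3))
        model = scca_fit(X, Y, PenaltyPair(0.8, 0.7), d=2)
        for j in range(2):
            np.testing.assert_array_equal(fix_sign(model.u[:, j]), model.u[:, j])
            np.testing.assert_array_equal(fix_sign(model.v[:, j]), model.v[:, j])

    def test_unit_norm_and_l1_invariants(self, rng):
        X = rng.normal(size=(80, 10))
        Y = rng.normal(size=(80, 8))
        pen = PenaltyPair(0.6, 0.7)
        model = scca_fit(X, Y, pen, d=3)
        for j in range(3):
            assert np.linalg.norm(model.u[:, j]) == pytest.approx(1.0, abs=1e-8)
            assert np.abs(model.u[:, j]).sum() <= l1_bound(0.6, 10) + 1e-6
            assert np.abs(model.v[:, j]).sum() <= l1_bound(0.7, 8) + 1e-6

    def test_degenerate_behavior_block_errors(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        Y = np.zeros((30, 2))
        with pytest.raises(ValueError, match="penalty"):
            scca_fit(X, Y, PenaltyPair(0.8, 0.7), d=1)


class TestProjection:
    def test_self_projection_reproduces_training_correlations(self, rng):
        X = rng.normal(size=(100, 8))
        Y = rng.normal(size=(100, 5))
        model = scca_fit(X, Y, PenaltyPair(0.8, 0.7), d=3)
        scores = scca_project(model, X, Y)
        np.testing.assert_allclose(
            scores.correlations, model.train_correlations, atol=1e-10
        )

    def test_projection_is_explicit_matrix_product(self, rng):
        X = rng.normal(size=(30, 6))
        Y = rng.normal(size=(30, 4))
        model = scca_fit(X, Y, PenaltyPair(1.0, 0.8), d=2)
        X_new = rng.normal(size=(20, 6))
        Y_new = rng.normal(size=(20, 4))
        scores = scca_project(model, X_new, Y_new)
        np.testing.assert_allclose(
            scores.brain_scores, standardize_columns(X_new) @ model.u, atol=1e-12
        )
        np.testing.assert_allclose(
            scores.behavior_scores, standardize_columns(Y_new) @ model.v, atol=1e-12
        )

    def test_shuffled_rows_break_association(self, rng):
        n = 400
        X = rng.normal(size=(n, 5))
        Y = 0.8 * X[:, :3] + 0.6 * rng.normal(size=(n, 3))
        model = scca_fit(X, Y, PenaltyPair(1.0, 0.8), d=1)
        assert model.train_correlations[0] > 0.5
        shuffled = scca_project(model, X, Y[rng.permutation(n)])
        assert abs(shuffled.correlations[0]) < 2.5 / np.sqrt(n)  # inside the null band

    def test_dimension_mismatch(self, rng):
        X = rng.normal(size=(30, 6))
        Y = rng.normal(size=(30, 4))
        model = scca_fit(X, Y, PenaltyPair(1.0, 0.8), d=1)
        with pytest.raises(ValueError, match="columns"):
            scca_project(model, rng.normal(size=(10, 5)), rng.normal(size=(10, 4)))


class TestCovarianceExplained:
    def _scores(self, covs):
        base = np.array([1.0, -1.0, 1.0, -1.0])
        brain = np.column_stack([c * base for c in covs])
        behavior = np.column_stack([base for _ in covs])
        return VariateScores(
            brain_scores=brain,
            behavior_scores=behavior,
            correlations=np.ones(len(covs)),
        )

    def test_single_component_gate_false(self):
        shares, gate = covariance_explained(self._scores([2.0]))
        np.testing.assert_allclose(shares, [1.0])
        assert not gate[0]  # 1.0 is not strictly greater than the mean share

    def test_hand_built_shares_and_gate(self):
        shares, gate = covariance_explained(self._scores([4.0, 1.0, 1.0]))
        np.testing.assert_allclose(shares, [2 / 3, 1 / 6, 1 / 6])
        assert gate.tolist() == [True, False, False]
        assert shares.sum() == pytest.approx(1.0)

    def test_zero_covariance_warns_uniform(self, rng):
        scores = VariateScores(
            brain_scores=np.zeros((10, 2)),
            behavior_scores=rng.normal(size=(10, 2)),
            correlations=np.zeros(2),
        )
        with pytest.warns(RuntimeWarning, match="zero"):
            shares, _ = covariance_explained(scores)
        np.testing.assert_allclose(shares, [0.5, 0.5])


class TestClassicalCCA:
    def test_univariate_equals_absolute_pearson(self, rng):
        x = rng.normal(size=(200, 1))
        y = 0.5 * x + rng.normal(size=(200, 1))
        _, _, rho = classical_cca(x, y, d=1)
        assert rho[0] == pytest.approx(
            abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1]), abs=1e-10
        )

    def test_invertible_mixing_gives_perfect_correlations(self, rng):
        X = rng.normal(size=(100, 3))
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        _, _, rho = classical_cca(X, X @ M, d=3)
        np.testing.assert_allclose(rho, 1.0, atol=1e-8)

    def test_matches_whitening_svd_oracle(self, rng):
        n = 400
        X = rng.normal(size=(n, 5))
        Y = 0.4 * X[:, :4] + rng.normal(size=(n, 4))
        _, _, rho = classical_cca(X, Y, d=4)
        # independent oracle: whiten each block by Cholesky, then SVD
        Xs, Ys = standardize_columns(X), standardize_columns(Y)
        Sxx = Xs.T @ Xs / (n - 1)
        Syy = Ys.T @ Ys / (n - 1)
        Sxy = Xs.T @ Ys / (n - 1)
        Lx = np.linalg.cholesky(Sxx)
        Ly = np.linalg.cholesky(Syy)
        K = np.linalg.solve(Lx, Sxy) @ np.linalg.inv(Ly).T
        sv = np.linalg.svd(K, compute_uv=False)
        np.testing.assert_allclose(rho, sv[:4], atol=1e-8)

    def test_singular_covariance_rejected(self, rng):
        X = rng.normal(size=(50, 3))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="singular"):
            classical_cca(X, rng.normal(size=(50, 2)), d=1)
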