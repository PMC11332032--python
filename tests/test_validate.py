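"""Tests for splits, penalty search, permutation inference, bootstrap, holdout."""

import numpy as np
import pytest

from holdoutcca import (
    HoldoutConfig,
    PenaltyPair,
    bootstrap_stability,
    grid_search_penalties,
    make_disjoint_folds,
    make_site_splits,
    match_components,
    permutation_test,
    run_multiple_holdout,
    scca_fit,
)
from holdoutcca.validate import bh_qvalues


class TestSiteSplits:
    def test_partition_properties(self):
        sites = [f"s{i}" for i in range(21)]
        schemes = make_site_splits(np.repeat(sites, 2), n_test_sites=3, n_reps=30, seed=4)
        assert len(schemes) == 30
        for sch in schemes:
            assert len(sch.test_sites) == 3 and len(sch.train_sites) == 18
            assert set(sch.train_sites) | set(sch.test_sites) == set(sites)
            assert not set(sch.train_sites) & set(sch.test_sites)

    def test_deterministic_under_seed(self):
        sites = np.repeat([f"s{i}" for i in range(8)], 2)
        assert make_site_splits(sites, 2, 10, seed=9) == make_site_splits(
            sites, 2, 10, seed=9
        )

    def test_matches_independently_coded_sampler(self):
        """Reference fixture: uniform choice without replacement per repetition."""
        sites = np.repeat([f"s{i:02d}" for i in range(21)], 2)
        schemes = make_site_splits(sites, n_test_sites=3, n_reps=30, seed=123)
        ref_rng = np.random.default_rng(123)
        uniq = np.unique(sites)
        for sch in schemes:
            expected = tuple(sorted(ref_rng.choice(uniq, size=3, replace=False)))
            assert sch.test_sites == expected

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            make_site_splits(np.array(["a", "a", "b", "b"]), n_test_sites=2)


class TestDisjointFolds:
    def test_partition_and_sizes(self):
        sites = np.repeat([f"s{i:02d}" for i in range(21)], 2)
        folds = make_disjoint_folds(sites, n_folds=5, seed=2)
        test_sets = [set(f.test_sites) for f in folds]
        sizes = sorted(len(t) for t in test_sets)
        assert sizes == [4, 4, 4, 4, 5]
        assert set().union(*test_sets) == set(np.unique(sites))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not test_sets[i] & test_sets[j]

    def test_deterministic(self):
        sites = np.repeat(list("abcdefghij"), 2)
        assert make_disjoint_folds(sites, 5, seed=1) == make_disjoint_folds(
            sites, 5, seed=1
        )


class TestGridSearch:
    def test_candidates_respect_behavior_constraint(self, rng):
        X = rng.normal(size=(100, 6))
        Y = 0.5 * X[:, :4] + rng.normal(size=(100, 4))
        pair = grid_search_penalties(
            X, Y, grid_brain=(0.4, 0.8), grid_behavior=(0.3, 0.6, 0.9),
            n_inner=5, seed=0,
        )
        assert pair.c_behavior > 0.5
        assert pair.c_brain in (0.4, 0.8) and pair.c_behavior in (0.6, 0.9)

    def test_strong_signal_selects_recovering_pair(self):
        rng = np.random.default_rng(5)
        n, k = 400, 12
        X = rng.normal(size=(n, k))
        u_true = np.zeros(k)
        u_true[:3] = 1 / np.sqrt(3)
        z = X @ u_true
        Y = np.column_stack([z, rng.normal(size=(n, 3))]) + 0.4 * rng.normal(size=(n, 4))
        pair = grid_search_penalties(
            X, Y, grid_brain=(0.6, 0.8, 1.0), grid_behavior=(0.6, 0.8, 1.0),
            n_inner=20, seed=1,
        )
        model = scca_fit(X, Y, pair, d=1)
        cos = abs(model.u[:, 0] @ u_true) / np.linalg.norm(u_true)
        assert cos >= 0.7


class TestPermutation:
    def _fit(self, rng, n=120, k=6, q=4, signal=0.0):
        X = rng.normal(size=(n, k))
        Y = rng.normal(size=(n, q)) + signal * X[:, :q]
        model = scca_fit(X, Y, PenaltyPair(0.8, 0.8), d=2)
        return X, Y, model

    def test_p_bounds(self, rng):
        X, Y, model = self._fit(rng, signal=1.0)
        res = permutation_test(X, Y, model, mode="project", B=200, seed=0)
        # strong signal: the add-one estimator floors at 1/(B+1)
        assert res.p_values[0] == pytest.approx(1 / 201)
        assert np.all(res.p_values <= 1.0)
        assert np.all(res.q_values[res.tested] >= res.p_values[res.tested])

    def test_total_exceedance_gives_p_one(self, rng):
        X, Y, model = self._fit(rng, signal=1.0)
        model.v = -model.v  # observed correlation strongly negative
        res = permutation_test(
            X, Y, model, mode="project", B=150, seed=0, use_abs=False
        )
        assert res.p_values[0] == pytest.approx(1.0)

    def test_refit_and_project_modes_run(self, rng):
        X, Y, model = self._fit(rng, signal=0.8)
        for mode in ("refit", "project"):
            res = permutation_test(X, Y, model, mode=mode, B=120, seed=3)
            assert res.null_draws.shape == (120, 2)
            assert res.p_values[0] < 0.05

    def test_gate_empty_gives_nan(self, rng):
        X, Y, model = self._fit(rng)
        res = permutation_test(
            X, Y, model, mode="project", B=120, seed=0,
            components=np.array([False, False]),
        )
        assert np.all(np.isnan(res.p_values))

    def test_bh_oracle(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04], atol=1e-12)

    def test_small_b_warns(self, rng):
        X, Y, model = self._fit(rng)
        with pytest.warns(RuntimeWarning, match="small"):
            permutation_test(X, Y, model, mode="project", B=50, seed=0)


class TestBootstrap:
    def test_known_permutation_is_undone_by_matching(self, rng):
        X = rng.normal(size=(80, 8))
        Y = rng.normal(size=(80, 5)) + 0.5 * X[:, :5]
        model = scca_fit(X, Y, PenaltyPair(0.8, 0.8), d=3)
        shuffle = np.array([2, 0, 1])
        signs = np.array([1.0, -1.0, 1.0])
        v_shuffled = model.v[:, shuffle] * signs
        perm, rec_signs = match_components(model.v, v_shuffled)
        np.testing.assert_array_equal(perm, np.argsort(shuffle))
        recovered = v_shuffled[:, perm] * rec_signs
        np.testing.assert_allclose(recovered, model.v, atol=1e-12)

    def test_self_match_is_identity(self, rng):
        X = rng.normal(size=(60, 6))
        Y = rng.normal(size=(60, 4))
        model = scca_fit(X, Y, PenaltyPair(0.8, 0.8), d=2)
        perm, signs = match_components(model.v, model.v)
        np.testing.assert_array_equal(perm, [0, 1])
        np.testing.assert_array_equal(signs, [1.0, 1.0])

    def test_aligned_cosines_nonnegative(self, rng):
        X = rng.normal(size=(100, 8))
        Y = rng.normal(size=(100, 5)) + 0.4 * X[:, :5]
        model = scca_fit(X, Y, PenaltyPair(0.8, 0.8), d=2)
        boot = bootstrap_stability(X, Y, model, B=25, seed=2)
        assert boot.matched_v.shape[0] + boot.n_failed == 25
        for b in range(boot.matched_v.shape[0]):
            for j in range(2):
                num = boot.matched_v[b, :, j] @ model.v[:, j]
                assert num >= -1e-12


class TestMultipleHoldout:
    def test_deterministic_end_to_end(self, small_cohort, fast_holdout_config):
        r1 = run_multiple_holdout(small_cohort, fast_holdout_config)
        r2 = run_multiple_holdout(small_cohort, fast_holdout_config)
        assert r1.to_json() == r2.to_json()

    def test_summary_shape_and_leak_free_contract(self, small_cohort, fast_holdout_config):
        res = run_multiple_holdout(small_cohort, fast_holdout_config)
        table = res.summary_table()
        assert len(table) == len(res.repetitions) * fast_holdout_config.d
        assert set(table.columns) >= {
            "train_r", "test_r", "test_p", "test_q", "c_brain", "c_behavior",
        }
        # planted signal: first component found and validated out of sample
        assert res.n_validated()[0] >= 1
        pair = res.most_selected_penalties()
        assert isinstance(pair, PenaltyPair)
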