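"""Cross-validation protocol: folds, grids, RMSE, nested CV."""

import json

import numpy as np
import pytest

from rankreg import (
    Standardizer,
    SyntheticSpec,
    cross_validate,
    fit_linear_lowrank,
    generate_linear,
    make_fold_plan,
    make_lambda_grid,
    rmse,
    tune_lambda,
)

from .oracles import rmse_loops


class TestRmse:
    def test_perfect_prediction(self, rng):
        Y = rng.standard_normal((6, 4))
        per, mean = rmse(Y, Y)
        assert np.all(per == 0) and mean == 0

    def test_constant_offset(self, rng):
        Y = rng.standard_normal((6, 4))
        per, mean = rmse(Y + 0.7, Y)
        np.testing.assert_allclose(per, 0.7)
        assert mean == pytest.approx(0.7)

    def test_matches_loop_oracle(self, rng):
        P = rng.standard_normal((5, 3))
        O = rng.standard_normal((5, 3))
        per, mean = rmse(P, O)
        np.testing.assert_allclose(per, rmse_loops(P, O), atol=1e-12)
        assert mean == pytest.approx(rmse_loops(P, O).mean(), abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            rmse(np.zeros((3, 2)), np.zeros((2, 3)))


class TestFoldPlan:
    def test_partition_properties(self):
        plan = make_fold_plan(23, n_folds=5, seed=3)
        sizes = np.bincount(plan.assignments)
        assert sizes.sum() == 23 and sizes.max() - sizes.min() <= 1
        seen = np.zeros(23, dtype=int)
        for tr, te in plan.split():
            assert np.intersect1d(tr, te).size == 0
            seen[te] += 1
        np.testing.assert_array_equal(seen, 1)

    def test_seed_reproducibility(self):
        a = make_fold_plan(40, 10, seed=9)
        b = make_fold_plan(40, 10, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        c = make_fold_plan(40, 10, seed=10)
        assert np.any(a.assignments != c.assignments)

    def test_invalid_fold_counts(self):
        with pytest.raises(ValueError):
            make_fold_plan(5, n_folds=6)
        with pytest.raises(ValueError):
            make_fold_plan(5, n_folds=1)


class TestLambdaGrid:
    def test_two_point_one_decade(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 2))
        g = make_lambda_grid(X, Y, n_points=2, span_decades=1)
        lam_max = np.linalg.svd(X.T @ Y, compute_uv=False)[0]
        np.testing.assert_allclose(g, [lam_max / 10, lam_max], rtol=1e-12)

    def test_constant_ratio(self, rng):
        X = rng.standard_normal((10, 3))
        Y = rng.standard_normal((10, 2))
        g = make_lambda_grid(X, Y, n_points=10, span_decades=4)
        ratios = g[1:] / g[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_anchor_is_zero_solution_threshold(self, rng):
        X = rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 4))
        g = make_lambda_grid(X, Y, n_points=3, span_decades=1)
        lam_max = g[-1]
        assert np.linalg.norm(fit_linear_lowrank(X, Y, lam_max).coefficients) <= 1e-10
        assert np.linalg.norm(fit_linear_lowrank(X, Y, lam_max * 1.01).coefficients) <= 1e-10
        assert np.linalg.norm(fit_linear_lowrank(X, Y, lam_max / 10).coefficients) > 1e-6

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            make_lambda_grid(np.zeros((5, 2)), np.ones((5, 3)))


class TestStandardizer:
    def test_train_contract(self, rng):
        M = rng.standard_normal((30, 5)) * 3 + 1
        out = Standardizer().fit_transform(M)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=0), 1, atol=1e-8)

    def test_constant_column_maps_to_zero(self, rng):
        M = np.column_stack([np.full(10, 2.0), rng.standard_normal(10)])
        out = Standardizer().fit_transform(M)
        np.testing.assert_allclose(out[:, 0], 0.0)


class TestCrossValidate:
    def _data(self, seed=0, n=50, noise=0.3):
        return generate_linear(
            SyntheticSpec(n_samples=n, n_regulators=8, n_targets=10, rank=2,
                          noise_sd=noise, seed=seed)
        )

    def test_noiseless_low_rank_near_interpolation(self):
        ds = generate_linear(
            SyntheticSpec(n_samples=60, n_regulators=6, n_targets=8, rank=1,
                          noise_sd=0.0, seed=4)
        )
        rep = cross_validate("linear_lowrank", ds.X, ds.Y, n_folds=5, inner_folds=5,
                             seed=1, span_decades=6)
        assert rep.test_rmse_mean_sd[0] < 0.05

    def test_seeded_determinism(self):
        ds = self._data(seed=2)
        r1 = cross_validate("linear_lowrank", ds.X, ds.Y, n_folds=5, inner_folds=4, seed=7)
        r2 = cross_validate("linear_lowrank", ds.X, ds.Y, n_folds=5, inner_folds=4, seed=7)
        assert json.dumps(r1.to_dict(), sort_keys=True) == json.dumps(r2.to_dict(), sort_keys=True)

    def test_shuffled_targets_are_unpredictable(self):
        ds = self._data(seed=5, n=100)
        rng = np.random.default_rng(11)
        Yperm = ds.Y[rng.permutation(ds.Y.shape[0])]
        rep = cross_validate("linear_lowrank", ds.X, Yperm, n_folds=5, inner_folds=5, seed=3)
        assert abs(rep.test_rmse_mean_sd[0] - 1.0) < 0.05

    def test_selected_lambda_attains_inner_minimum(self):
        ds = self._data(seed=6)
        rep = cross_validate("linear_lowrank", ds.X, ds.Y, n_folds=4, inner_folds=4, seed=2)
        for f in range(4):
            idx = np.argmin(rep.per_fold_rmse[f])
            assert rep.per_fold_rmse[f][
                np.flatnonzero(rep.lambda_grid == rep.selected_lambdas[f])[0]
            ] == pytest.approx(rep.per_fold_rmse[f][idx])

    def test_leave_one_out_runs_on_tiny_input(self):
        ds = generate_linear(
            SyntheticSpec(n_samples=12, n_regulators=4, n_targets=5, rank=1, seed=8)
        )
        rep = cross_validate("linear_lowrank", ds.X, ds.Y, n_folds=12, inner_folds=5, seed=1)
        assert rep.test_rmse.shape == (12,)
        assert np.all(rep.test_rmse >= 0)

    def test_lasso_and_kernel_kinds_run(self):
        from rankreg import KernelSpec

        ds = self._data(seed=9, n=40)
        rl = cross_validate("lasso", ds.X, ds.Y, n_folds=4, inner_folds=3, seed=2)
        assert rl.test_rmse_mean_sd[0] < 1.0
        rk = cross_validate("kernel_lowrank", ds.X, ds.Y, n_folds=3, inner_folds=3, seed=2,
                            kernel_spec=KernelSpec("linear"))
        assert rk.test_rmse_mean_sd[0] < 1.0

    def test_paper_mode_global_standardization(self):
        ds = self._data(seed=10)
        rep = cross_validate("linear_lowrank", ds.X, ds.Y, n_folds=4, inner_folds=3,
                             seed=2, paper_mode=True)
        assert np.all(rep.test_rmse >= 0)

    def test_plan_mismatch_rejected(self):
        ds = self._data(seed=1)
        bad_plan = make_fold_plan(20, 4, seed=0)
        with pytest.raises(ValueError):
            cross_validate("linear_lowrank", ds.X, ds.Y, plan=bad_plan)


class TestTuneLambda:
    def test_tie_break_prefers_larger_lambda(self, rng):
        # construct a flat region by using a grid entirely above lambda_max:
        # every fit is zero, every RMSE equal -> select the largest
        X = rng.standard_normal((30, 4))
        Y = rng.standard_normal((30, 3))
        lam_max = np.linalg.svd(X.T @ Y, compute_uv=False)[0]
        grid = np.array([2.0, 3.0, 4.0]) * lam_max
        t = tune_lambda("linear_lowrank", X, Y, n_folds=3, seed=0, grid=grid,
                        standardize=False)
        assert t.selected_lambda == grid[-1]
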