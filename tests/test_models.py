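"""PLSR, SVR (with QP oracle), grid search, and the kite metaheuristic."""

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from nirquant import (
    BKAConfig,
    SVRHyperparams,
    bka_optimize,
    cross_val_rmse,
    fit_bka_svr,
    fit_pls_fixed,
    fit_plsr,
    fit_svr,
    grid_search_svr,
)
from nirquant.errors import ConfigError

rng = np.random.default_rng(17)


class TestPLSR:
    def test_rank_one_noiseless_needs_one_lv(self):
        t = rng.normal(size=50)
        X = np.outer(t, rng.normal(size=30))  # rank 1
        y = X @ rng.normal(size=30)
        model = fit_plsr(X, y, max_lvs=20, folds=5, seed=0)
        resid = y - model.predict(X)
        assert np.sqrt(np.mean(resid**2)) < 1e-8
        assert model.n_lvs == 1

    def test_full_lv_limit_equals_ols(self):
        X = rng.normal(size=(30, 5))
        y = X @ [1.0, -2.0, 0.5, 3.0, -1.0] + rng.normal(0, 0.3, 30)
        model = fit_pls_fixed(X, y, 5)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(model.predict(X), Xc @ beta + y.mean(),
                                   atol=1e-6)

    def test_chosen_lvs_within_search_range(self):
        X = rng.normal(size=(60, 40))
        y = rng.normal(size=60)
        model = fit_plsr(X, y, max_lvs=20)
        assert 1 <= model.n_lvs <= 20
        assert model.cv_curve.size <= 20

    def test_training_error_non_increasing_in_lvs(self):
        X = rng.normal(size=(40, 15))
        y = X @ rng.normal(size=15) + rng.normal(0, 0.5, 40)
        errs = []
        for k in range(1, 9):
            m = fit_pls_fixed(X, y, k)
            errs.append(np.sqrt(np.mean((y - m.predict(X)) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_too_many_folds_rejected(self):
        with pytest.raises(Exception):
            fit_plsr(rng.normal(size=(4, 3)), rng.normal(size=4), folds=10)


def _svr_dual_objective(dual_coef, K, y, epsilon):
    """epsilon-SVR dual objective at alpha - alpha* = dual_coef (maximized)."""
    return (-0.5 * dual_coef @ K @ dual_coef
            - epsilon * np.abs(dual_coef).sum() + y @ dual_coef)


class TestSVR:
    def test_constant_target_stays_in_tube(self):
        X = rng.normal(size=(25, 4))
        y = np.full(25, 5.0)
        model = fit_svr(X, y, SVRHyperparams(c=10.0, g=0.1, epsilon=0.1))
        pred = model.predict(X)
        assert (pred >= 4.9 - 1e-6).all() and (pred <= 5.1 + 1e-6).all()

    def test_huge_gamma_memorizes_training_points(self):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15) * 3
        model = fit_svr(X, y, SVRHyperparams(c=1e4, g=1e4, epsilon=0.05))
        assert np.abs(model.predict(X) - y).max() <= 0.05 + 1e-3

    def test_objective_matches_quadratic_program_oracle(self):
        """libsvm's solution attains the dual optimum found by a generic QP solver."""
        g = np.random.default_rng(3)
        X = np.sort(g.uniform(-2, 2, 30))[:, None]
        y = np.sin(X.ravel()) + g.normal(0, 0.1, 30)
        c, gamma, eps = 10.0, 0.5, 0.1
        model = fit_svr(X, y, SVRHyperparams(c=c, g=gamma, epsilon=eps))
        sq = (X - X.T) ** 2
        K = np.exp(-gamma * sq)

        dc = np.zeros(30)
        dc[model.support_] = model.dual_coef_.ravel()
        obj_libsvm = _svr_dual_objective(dc, K, y, eps)

        # smooth QP in split variables u = (alpha, alpha*): the |.| term
        # becomes linear, so a generic constrained solver converges tightly
        n = 30
        A = np.hstack([np.eye(n), -np.eye(n)])

        def neg_dual(u):
            d = A @ u
            return 0.5 * d @ K @ d + eps * u.sum() - y @ d

        def grad(u):
            return A.T @ (K @ (A @ u)) + eps - A.T @ y

        res = minimize(
            neg_dual, np.zeros(2 * n), jac=grad, method="trust-constr",
            bounds=[(0, c)] * (2 * n),
            constraints=[LinearConstraint(
                np.concatenate([np.ones(n), -np.ones(n)]), 0, 0)],
            options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
        )
        obj_oracle = -res.fun
        assert obj_libsvm == pytest.approx(obj_oracle, abs=1e-4 * (1 + abs(obj_oracle)))


class TestGridSearch:
    def test_degenerate_grid_returns_its_point(self):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        hp, _ = grid_search_svr(X, y, c_grid=[2.0], g_grid=[0.25])
        assert (hp.c, hp.g) == (2.0, 0.25)

    def test_minimum_verified_by_exhaustive_reevaluation(self):
        g = np.random.default_rng(8)
        X = g.normal(size=(30, 4))
        y = X @ [1, -1, 2, 0.5] + g.normal(0, 0.2, 30)
        c_grid, g_grid = [0.5, 4.0, 32.0], [0.01, 0.1, 1.0]
        hp, score = grid_search_svr(X, y, c_grid, g_grid, seed=4)
        from nirquant.evaluate import kfold_indices
        folds = kfold_indices(30, 5, 4)
        scores = {
            (c, gg): cross_val_rmse(
                lambda a, b, c=c, gg=gg: fit_svr(a, b, SVRHyperparams(c, gg)),
                X, y, fold_ids=folds)
            for c in c_grid for gg in g_grid
        }
        assert score == pytest.approx(min(scores.values()), abs=1e-12)
        assert scores[(hp.c, hp.g)] == score

    def test_reported_optima_lie_on_default_grid(self):
        from nirquant.models import default_c_grid
        grid = default_c_grid()
        for c in (2.8284, 22.6274, 64.0):
            assert np.min(np.abs(grid - c)) < 5e-4


class TestBKA:
    def test_sphere_function_convergence(self):
        res = bka_optimize(lambda x: float(x @ x),
                           bounds=[(-5, 5), (-5, 5)],
                           pop_size=20, n_iter=100, seed=0)
        assert res.best_f < 1e-2
        assert abs(res.best_x).max() <= 5

    def test_best_so_far_trace_non_increasing(self):
        res = bka_optimize(lambda x: float(np.cos(x).sum() + x @ x / 10),
                           bounds=[(-4, 4), (-4, 4)],
                           pop_size=8, n_iter=40, seed=1)
        trace = np.array(res.trace)
        assert (np.diff(trace) <= 1e-12).all()

    def test_zero_iterations_degrade_to_best_of_init(self):
        res = bka_optimize(lambda x: float(x @ x), bounds=[(-1, 2)] * 2,
                           pop_size=5, n_iter=0, seed=2)
        assert np.isfinite(res.best_f) and res.n_evals == 5

    def test_candidates_respect_bounds_and_nan_rejected(self):
        seen = []

        def objective(x):
            seen.append(x.copy())
            if x[0] > 0.9:
                return float("nan")
            return float(x @ x)

        res = bka_optimize(objective, bounds=[(-1, 1), (-1, 1)],
                           pop_size=6, n_iter=25, seed=3)
        pts = np.array(seen)
        assert (pts >= -1 - 1e-12).all() and (pts <= 1 + 1e-12).all()
        assert res.best_x[0] <= 0.9  # NaN region never wins

    def test_beats_discretized_grid_on_toy_svr_objective(self):
        g = np.random.default_rng(6)
        X = g.normal(size=(25, 3))
        y = X @ [1.0, -0.5, 2.0] + g.normal(0, 0.3, 25)
        from nirquant.evaluate import kfold_indices
        folds = kfold_indices(25, 5, 0)

        def objective(z):
            hp = SVRHyperparams(float(2.0 ** z[0]), float(2.0 ** z[1]))
            return cross_val_rmse(lambda a, b: fit_svr(a, b, hp), X, y,
                                  fold_ids=folds)

        bounds = np.array([[-2.0, 8.0], [-8.0, 0.0]])
        grid_best = min(
            objective(np.array([zc, zg]))
            for zc in np.linspace(-2, 8, 20) for zg in np.linspace(-8, 0, 20)
        )
        res = bka_optimize(objective, bounds, pop_size=15, n_iter=40, seed=0)
        assert res.best_f <= grid_best + 1e-12


class TestBKASVR:
    def test_params_within_bounds_and_deterministic(self):
        g = np.random.default_rng(10)
        X = g.normal(size=(30, 4))
        y = X @ [2.0, -1.0, 0.5, 1.0] + g.normal(0, 0.2, 30)
        cfg = BKAConfig(pop_size=6, n_iter=10, seed=5)
        a = fit_bka_svr(X, y, cfg)
        b = fit_bka_svr(X, y, cfg)
        assert (a.params.c, a.params.g) == (b.params.c, b.params.g)
        assert cfg.c_bounds[0] <= a.params.c <= cfg.c_bounds[1]
        assert cfg.g_bounds[0] <= a.params.g <= cfg.g_bounds[1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            BKAConfig(pop_size=2)
        with pytest.raises(ConfigError):
            BKAConfig(c_bounds=(5.0, 1.0))
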