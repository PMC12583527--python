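import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from mvewas.multivar import (
    compute_bic,
    cross_validate,
    fit_penalized,
    make_grid,
    PenalizedFit,
    PenalizedProblem,
    select_probes,
    tune_by_bic,
)
from mvewas.reference import ref_fit, ref_objective

from conftest import standardize


def random_problem(rng, n=50, m=5, q=3, signal=0.5, n_signals=2):
    """A small instance with planted sparse signal and correlated noise."""
    W = np.column_stack(
        [np.ones(n), rng.integers(0, 3, n), rng.integers(0, 3, n)]
    ).astype(float)
    X = standardize(rng.standard_normal((n, m)))
    G3 = np.zeros((q, m))
    G3[rng.integers(0, q, n_signals), rng.choice(m, n_signals, replace=False)] = signal
    cov = np.eye(q) * 0.2 + 0.1
    Y = (
        W @ rng.normal(0, 0.3, (W.shape[1], q))
        + X @ G3.T
        + rng.multivariate_normal(np.zeros(q), cov, size=n)
    )
    return Y, W, X


class TestSolverCore:
    def test_matches_independent_oracle(self):
        """Objective and support agree with the FISTA+ADMM reference solver."""
        rng = np.random.default_rng(0)
        for _ in range(8):
            Y, W, X = random_problem(rng, n=rng.integers(40, 61), m=rng.integers(3, 7))
            lam = float(rng.uniform(0.02, 0.3))
            rho = float(rng.uniform(0.01, 0.2))
            fit = fit_penalized(
                PenalizedProblem(Y, W, X, lam, rho), tol=1e-10, max_outer=500
            )
            _, g3_ref, _, obj_ref = ref_fit(Y, W, X, lam, rho)
            assert abs(fit.objective - obj_ref) < 1e-4
            assert np.array_equal(np.abs(fit.Gamma3) > 1e-6, np.abs(g3_ref) > 1e-6)

    def test_objective_value_consistent_with_reference_formula(self):
        rng = np.random.default_rng(3)
        Y, W, X = random_problem(rng)
        fit = fit_penalized(PenalizedProblem(Y, W, X, 0.1, 0.05), tol=1e-8)
        obj = ref_objective(Y, W, X, fit.Gamma_w, fit.Gamma3, fit.Theta, 0.1, 0.05)
        assert fit.objective == pytest.approx(obj, abs=1e-10)

    def test_unpenalized_limit_is_ols_plus_inverse_mle_covariance(self):
        rng = np.random.default_rng(1)
        Y, W, X = random_problem(rng, n=60, m=4)
        fit = fit_penalized(PenalizedProblem(Y, W, X, 0.0, 0.0), tol=1e-12, max_outer=500)
        Z = np.hstack([W, X])
        B = np.linalg.lstsq(Z, Y, rcond=None)[0]
        R = Y - Z @ B
        Theta = np.linalg.inv(R.T @ R / len(Y))
        np.testing.assert_allclose(
            np.vstack([fit.Gamma_w, fit.Gamma3.T]), B, atol=1e-6
        )
        np.testing.assert_allclose(fit.Theta, Theta, atol=1e-6)

    def test_single_response_reduction_matches_lasso(self):
        """With q=1 and rho=0 the fixed point is a lasso with penalty
        lambda/(2 theta_hat); verified against the sklearn solver."""
        rng = np.random.default_rng(2)
        n, m = 80, 6
        X = standardize(rng.standard_normal((n, m)))
        y = X[:, 0] * 0.5 - X[:, 2] * 0.3 + rng.standard_normal(n) * 0.8 + 2.0
        W = np.ones((n, 1))
        lam = 0.08
        fit = fit_penalized(
            PenalizedProblem(y[:, None], W, X, lam, 0.0), tol=1e-12, max_outer=1000
        )
        alpha = lam / (2.0 * fit.Theta[0, 0])
        ref = Lasso(alpha=alpha, fit_intercept=True, tol=1e-12, max_iter=200_000).fit(X, y)
        np.testing.assert_allclose(fit.Gamma3.ravel(), ref.coef_, atol=1e-6)
        assert fit.Gamma_w[0, 0] == pytest.approx(ref.intercept_, abs=1e-6)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        Y, W, X = random_problem(rng, n=45, m=6)
        fit = fit_penalized(PenalizedProblem(Y, W, X, 0.05, 0.02), tol=1e-12, max_outer=200)
        diffs = np.diff(fit.objective_history)
        assert np.all(diffs <= 1e-8)

    def test_theta_positive_definite(self):
        rng = np.random.default_rng(5)
        for lam, rho in [(0.02, 0.01), (0.2, 0.1), (0.5, 0.3)]:
            Y, W, X = random_problem(rng)
            fit = fit_penalized(PenalizedProblem(Y, W, X, lam, rho))
            assert np.linalg.eigvalsh(fit.Theta).min() > 0

    def test_invalid_problems_rejected(self, rng):
        Y = rng.standard_normal((10, 3))
        W = np.ones((10, 1))
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            PenalizedProblem(Y, W, X, lam=-0.1)
        with pytest.raises(ValueError):
            PenalizedProblem(Y[:3], W[:3], X[:3])  # n <= q
        with pytest.raises(ValueError):
            PenalizedProblem(Y, W[:5], X)


class TestGrid:
    def test_lambda_max_gives_empty_support(self):
        rng = np.random.default_rng(6)
        Y, W, X = random_problem(rng, n=60, m=5)
        lam_grid, _ = make_grid(Y, W, X)
        fit = fit_penalized(PenalizedProblem(Y, W, X, float(lam_grid[0]), 0.0), tol=1e-10)
        assert np.all(fit.Gamma3 == 0.0)

    def test_path_support_grows_as_lambda_shrinks(self):
        rng = np.random.default_rng(7)
        Y, W, X = random_problem(rng, n=60, m=5)
        lam_grid, _ = make_grid(Y, W, X, n_lambda=8)
        warm = None
        counts = []
        for lam in lam_grid:  # decreasing
            fit = fit_penalized(
                PenalizedProblem(Y, W, X, float(lam), 0.0), tol=1e-8, warm_B=warm
            )
            warm = np.vstack([fit.Gamma_w, fit.Gamma3.T])
            counts.append(fit.n_nonzero)
        assert counts[0] == 0
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_grid_shapes_and_range(self):
        rng = np.random.default_rng(8)
        Y, W, X = random_problem(rng)
        lam_grid, rho_grid = make_grid(Y, W, X)
        assert len(lam_grid) == 20 and len(rho_grid) == 10
        assert lam_grid[0] == pytest.approx(100 * lam_grid[-1])

    def test_all_zero_X_rejected(self, rng):
        Y = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            make_grid(Y, np.ones((20, 1)), np.zeros((20, 4)))


class TestBic:
    def _toy_fit(self, gamma3, theta, resid):
        return PenalizedFit(
            Gamma_w=np.zeros((1, theta.shape[0])), Gamma3=gamma3, Theta=theta,
            lam=0.1, rho=0.1, objective=0.0, n_iter=1, converged=True, residuals=resid,
        )

    def test_hand_computed_example(self):
        n, q = 10, 2
        resid = np.tile(np.array([[1.0, -1.0]]), (n, 1))
        theta = np.array([[2.0, 0.5], [0.5, 1.0]])
        gamma3 = np.array([[0.3, 0.0], [0.0, -0.2]])
        fit = self._toy_fit(gamma3, theta, resid)
        S = resid.T @ resid / n
        expected = n * (np.trace(S @ theta) - np.log(np.linalg.det(theta)))
        expected += np.log(n) * (2 + 1)  # 2 nonzero coefficients + 1 off-diagonal
        assert compute_bic(fit, n) == pytest.approx(expected, abs=1e-12)

    def test_stored_zeros_do_not_change_bic(self):
        n = 10
        resid = np.random.default_rng(0).standard_normal((n, 2))
        theta = np.eye(2)
        f1 = self._toy_fit(np.array([[0.3, 0.0]]).reshape(2, 1), theta, resid)
        f2 = self._toy_fit(np.array([[0.3], [0.0]]), theta, resid)
        assert compute_bic(f1, n) == compute_bic(f2, n)

    def test_extra_df_costs_log_n(self):
        n = 50
        resid = np.random.default_rng(1).standard_normal((n, 2))
        theta = np.eye(2)
        sparse = self._toy_fit(np.array([[0.3], [0.0]]), theta, resid)
        denser = self._toy_fit(np.array([[0.3], [0.1]]), theta, resid)
        assert compute_bic(denser, n) - compute_bic(sparse, n) == pytest.approx(np.log(n))


class TestCrossValidation:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        Y, W, X = random_problem(rng, n=60)
        lam_grid, rho_grid = make_grid(Y, W, X, n_lambda=4, n_rho=2)
        r1 = cross_validate(Y, W, X, lam_grid, rho_grid, k=3, seed=5)
        r2 = cross_validate(Y, W, X, lam_grid, rho_grid, k=3, seed=5)
        assert r1[0] == r2[0]
        pd.testing.assert_frame_equal(r1[1], r2[1])

    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(10)
        Y, W, X = random_problem(rng, n=40)
        (lam, rho), surface = cross_validate(
            Y, W, X, np.array([0.1]), np.array([0.05]), k=3, seed=1
        )
        assert (lam, rho) == (0.1, 0.05)
        assert len(surface) == 1

    def test_error_surface_finite_on_pure_noise(self):
        rng = np.random.default_rng(11)
        n = 100
        Y = rng.standard_normal((n, 3))
        W = np.ones((n, 1))
        X = standardize(rng.standard_normal((n, 5)))
        lam_grid, rho_grid = make_grid(Y, W, X, n_lambda=5, n_rho=3)
        _, surface = cross_validate(Y, W, X, lam_grid, rho_grid, k=5, seed=2)
        assert np.all(np.isfinite(surface["cv_error"]))

    def test_too_few_samples_rejected(self, rng):
        Y, W, X = random_problem(np.random.default_rng(12), n=8)
        with pytest.raises(ValueError):
            cross_validate(Y, W, X, np.array([0.1]), np.array([0.1]), k=5)


class TestSelection:
    def _fit_with(self, gamma3):
        gamma3 = np.asarray(gamma3, dtype=float)
        q, m = gamma3.shape
        return PenalizedFit(
            Gamma_w=np.zeros((1, q)), Gamma3=gamma3,
            Theta=np.eye(q), lam=0.1, rho=0.1, objective=0.0, n_iter=1,
            converged=True, residuals=np.zeros((2, q)),
        )

    def test_all_zero_fits_give_empty_table(self):
        fits = [("g1", ["p1", "p2"], self._fit_with(np.zeros((3, 2))))]
        assert len(select_probes(fits)) == 0

    def test_duplicate_probe_keeps_largest_magnitude(self):
        f1 = self._fit_with([[0.0, 0.0], [0.02, 0.0], [0.0, 0.0]])
        f2 = self._fit_with([[0.0], [0.03], [0.0]])
        table = select_probes([("g1", ["pA", "pB"], f1), ("g2", ["pA"], f2)])
        assert table.loc["pA", "effect_M"] == 0.03
        assert table.loc["pA", "clusters"] == "g1;g2"

    def test_ordering_by_max_absolute_effect(self):
        f = self._fit_with(
            [[0.0, 0.0, 0.0], [0.0705, -0.0746, 0.0], [0.0, 0.0, 0.011]]
        )
        table = select_probes([("g", ["cg16027546", "cg14294953", "cg26476169"], f)])
        assert list(table.index) == ["cg14294953", "cg16027546", "cg26476169"]

    def test_tie_broken_by_probe_id(self):
        f = self._fit_with([[0.05, 0.05], [0.0, 0.0], [0.0, 0.0]])
        table = select_probes([("g", ["zzz", "aaa"], f)])
        assert list(table.index) == ["aaa", "zzz"]


def test_bic_tuning_recovers_planted_support_better_than_chance():
    rng = np.random.default_rng(13)
    n, m = 200, 8
    X = standardize(rng.standard_normal((n, m)))
    W = np.ones((n, 1))
    G3 = np.zeros((3, m))
    G3[0, 1] = G3[1, 4] = 0.6
    Y = X @ G3.T + rng.multivariate_normal(np.zeros(3), np.eye(3) * 0.3, size=n)
    lam_grid, rho_grid = make_grid(Y, W, X, n_lambda=10, n_rho=4)
    best, surface = tune_by_bic(Y, W, X, lam_grid, rho_grid)
    sel = np.abs(best.Gamma3) > 1e-8
    assert sel[0, 1] and sel[1, 4]
    assert sel.sum() <= 6  # not wildly overselecting
    assert len(surface) == 40
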