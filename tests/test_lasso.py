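import numpy as np
import pandas as pd
import pytest

from soundlasso.lasso import (PenaltySpec, fit_path, fit_penalized,
                              kkt_max_violation, lambda_grid, lambda_max,
                              make_penalty, penalized_objective)
from soundlasso.lmm import fit_mixed
from soundlasso.preprocess import INTERCEPT, PreparedDesign

from soundlasso.preprocess import prepare_design


def toy_design(x: np.ndarray, y: np.ndarray, names=None) -> PreparedDesign:
    """Unstandardized design with singleton clusters (tau00-free toys)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    names = names or [f"x{j}" for j in range(x.shape[1])]
    X = pd.DataFrame(x, columns=names)
    X.insert(0, INTERCEPT, 1.0)
    return PreparedDesign(
        y=np.asarray(y, dtype=float), X=X,
        groups={n: [n] for n in names},
        cluster_ids=np.arange(len(y)),
        standardization={n: (0.0, 1.0) for n in names},
    )


class TestObjective:
    def test_lambda_zero_is_rss(self):
        d = toy_design([1.0, 2, 3], [1.0, 1, 2])
        pen = make_penalty(d, 0.0)
        beta = np.array([0.5, 0.25])
        rss = np.sum((d.y - d.X.to_numpy() @ beta) ** 2)
        assert penalized_objective(beta, d.y, d.X, pen) == pytest.approx(rss)

    def test_zero_beta_centered_y_is_tss(self):
        y = np.array([1.0, -1, 2, -2])
        d = toy_design([1.0, 2, 3, 4], y)
        pen = make_penalty(d, 3.0)
        assert penalized_objective(np.zeros(2), d.y, d.X, pen) \
            == pytest.approx(np.sum(y**2))

    def test_three_point_toy(self):
        """x=[-1,0,1], y=[-1,0,1], beta=1, lambda=2 -> RSS 0 + penalty 2."""
        d = toy_design([-1.0, 0, 1], [-1.0, 0, 1])
        pen = make_penalty(d, 2.0)
        assert penalized_objective(np.array([0.0, 1.0]), d.y, d.X, pen) \
            == pytest.approx(2.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            PenaltySpec(-1.0, {"x": ["x"]})


class TestLambdaGrid:
    def test_two_points(self):
        np.testing.assert_allclose(lambda_grid(5.0, 2), [0.0, 5.0])

    def test_formula_values(self):
        """Direct evaluation of grid_i = lmax (e^{s i/(n-1)}-1)/(e^s-1)."""
        g = lambda_grid(100.0, 5, curvature=4.0)
        np.testing.assert_allclose(g, [0.0, 3.2059, 11.9203, 35.6086, 100.0],
                                   atol=5e-4)

    def test_denser_near_zero(self):
        g = lambda_grid(17.0, 40)
        d = np.diff(g)
        assert d[0] < d[-1]
        assert np.all(d > 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            lambda_grid(0.0, 10)
        with pytest.raises(ValueError):
            lambda_grid(1.0, 1)


def dense_grid_minimum(d: PreparedDesign, lam: float, span=2.0):
    """Coarse-to-fine grid search over the two penalized coefficients
    (intercept profiled out exactly), resolution 1e-3."""
    Xc = d.X.to_numpy()[:, 1:]
    yc = d.y - d.y.mean()
    Xc = Xc - Xc.mean(axis=0)
    A = Xc.T @ Xc
    b = Xc.T @ yc
    q = yc @ yc

    def best_on(b0s, b1s):
        B0, B1 = np.meshgrid(b0s, b1s, indexing="ij")
        obj = (A[0, 0] * B0**2 + A[1, 1] * B1**2 + 2 * A[0, 1] * B0 * B1
               - 2 * b[0] * B0 - 2 * b[1] * B1 + q
               + lam * (np.abs(B0) + np.abs(B1)))
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        return b0s[i], b1s[j]

    c0, c1 = best_on(np.arange(-span, span, 1e-2), np.arange(-span, span, 1e-2))
    return best_on(np.arange(c0 - 2e-2, c0 + 2e-2, 1e-3),
                   np.arange(c1 - 2e-2, c1 + 2e-2, 1e-3))


class TestFitPenalized:
    def test_matches_dense_grid_search(self):
        """12-observation 2-predictor toy with tau00 forced to 0: the
        solver agrees with a brute-force grid minimizer and satisfies the
        subgradient conditions."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 2))
        y = 0.8 * x[:, 0] - 0.3 * x[:, 1] + rng.normal(0, 0.5, 12)
        d = toy_design(x, y)
        pen = make_penalty(d, 3.0, group_norm="l1")
        fit = fit_penalized(d, pen, update_vc=False, cd_tol=1e-14)
        g0, g1 = dense_grid_minimum(d, 3.0)
        assert fit.beta["x0"] == pytest.approx(g0, abs=1.5e-3)
        assert fit.beta["x1"] == pytest.approx(g1, abs=1.5e-3)
        assert kkt_max_violation(d, fit.beta.to_numpy(), pen) < 1e-6

    def test_lambda_zero_equals_mixed_fit(self, factor_design):
        pen = make_penalty(factor_design, 0.0)
        fit = fit_penalized(factor_design, pen)
        ml = fit_mixed(factor_design, method="ML")
        np.testing.assert_allclose(fit.beta.to_numpy(), ml.beta.to_numpy(),
                                   atol=1e-6)

    def test_all_zero_at_lambda_max(self, factor_design):
        pen = make_penalty(factor_design, 0.0)
        lmax = lambda_max(factor_design, pen)
        fit = fit_penalized(factor_design, pen.with_lambda(lmax * 1.0001))
        assert all(fit.beta[c] == 0.0 for c in factor_design.penalized_columns)

    def test_group_l2_zeroes_factor_jointly(self, factor_design):
        """With the groupwise-L2 norm all dummies of a factor leave the
        model at the same lambda; with L1 a split pattern exists."""
        pen = make_penalty(factor_design, 0.0, group_norm="l2")
        lmax = lambda_max(factor_design, pen)
        grid = lambda_grid(lmax, 60)
        path = fit_path(factor_design, grid, pen)
        f_cols = factor_design.groups["f"]
        nz = path.coefficients[f_cols].to_numpy() != 0
        assert np.all(nz.all(axis=1) == nz.any(axis=1))

        pen1 = make_penalty(factor_design, 0.0, group_norm="l1")
        path1 = fit_path(factor_design, lambda_grid(
            lambda_max(factor_design, pen1), 60), pen1)
        nz1 = path1.coefficients[f_cols].to_numpy() != 0
        assert np.any(nz1.any(axis=1) & ~nz1.all(axis=1))

    def test_warm_start_objective_not_worse(self, factor_design):
        pen = make_penalty(factor_design, 0.0)
        lmax = lambda_max(factor_design, pen)
        grid = lambda_grid(lmax, 30)
        path = fit_path(factor_design, grid, pen)
        for k in [3, 11, 23]:
            cold = fit_penalized(factor_design, pen.with_lambda(grid[k]))
            assert path.objective[k] <= cold.objective \
                + 1e-8 * (abs(cold.objective) + 1)

    def test_kkt_along_path(self, factor_design):
        """Subgradient conditions hold at every grid point (variance
        ratio frozen at each point's estimate)."""
        pen = make_penalty(factor_design, 0.0)
        grid = lambda_grid(lambda_max(factor_design, pen), 25)
        path = fit_path(factor_design, grid, pen)
        scale = float(np.sum(factor_design.y**2))
        for k in range(len(grid)):
            theta = path.tau00[k] / path.sigma2[k]
            viol = kkt_max_violation(factor_design,
                                     path.coefficients.iloc[k].to_numpy(),
                                     pen.with_lambda(grid[k]), theta=theta)
            assert viol < 1e-6 * scale


class TestLambdaMax:
    def test_single_predictor_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        x = (x - x.mean()) / np.linalg.norm(x - x.mean())
        y = rng.normal(size=30)
        d = toy_design(x, y)
        pen = make_penalty(d, 0.0)
        lmax = lambda_max(d, pen, update_vc=False)
        assert lmax == pytest.approx(abs(2 * x @ (y - y.mean())), rel=1e-10)

    def test_constant_y(self):
        d = toy_design([1.0, 2, 3, 4], [2.0, 2, 2, 2])
        assert lambda_max(d, make_penalty(d, 0.0), update_vc=False) == 0.0

    def test_homogeneous_in_y(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        d1 = toy_design(x, y)
        d2 = toy_design(x, y.mean() + 2 * (y - y.mean()))
        pen = make_penalty(d1, 0.0)
        assert lambda_max(d2, pen, update_vc=False) \
            == pytest.approx(2 * lambda_max(d1, pen, update_vc=False), rel=1e-9)

    def test_bisection_agrees_with_kkt_under_vc(self, factor_design):
        """With variance components updating, the bisection threshold
        still nulls every penalized coefficient, and a fit just below it
        does not."""
        pen = make_penalty(factor_design, 0.0)
        lmax = lambda_max(factor_design, pen, update_vc=True)
        hi = fit_penalized(factor_design, pen.with_lambda(lmax * 1.0001))
        lo = fit_penalized(factor_design, pen.with_lambda(lmax * 0.98))
        pcols = factor_design.penalized_columns
        assert all(hi.beta[c] == 0 for c in pcols)
        assert any(lo.beta[c] != 0 for c in pcols)


class TestPathExport:
    def test_csv_round_trip(self, tmp_path, small_design):
        pen = make_penalty(small_design, 0.0)
        grid = lambda_grid(lambda_max(small_design, pen), 10)
        path = fit_path(small_design, grid, pen)
        out = path.to_csv(tmp_path / "path.csv")
        back = pd.read_csv(out)
        assert len(back) == 10
        np.testing.assert_allclose(back["lambda"], grid)
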