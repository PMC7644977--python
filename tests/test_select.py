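import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soundlasso.lasso import lambda_grid, lambda_max, make_penalty
from soundlasso.lmm import fit_mixed
from soundlasso.preprocess import INTERCEPT, prepare_design
from soundlasso.select import (CvCurve, assign_folds, cv_curve, one_se_lambda,
                               percentile_lambda, percentile_lasso,
                               refit_selected)

from conftest import continuous_roster, make_survey


class TestFolds:
    def test_even_split(self):
        f = assign_folds(np.arange(10), K=5, seed=0)
        counts = pd.Series(f.mapping).value_counts()
        assert (counts == 2).all()

    def test_near_even_split(self):
        f = assign_folds(np.arange(11), K=5, seed=0)
        counts = sorted(pd.Series(f.mapping).value_counts())
        assert counts == [2, 2, 2, 2, 3]

    def test_deterministic_and_seed_sensitive(self):
        ids = np.arange(40)
        assert assign_folds(ids, seed=3).mapping == assign_folds(ids, seed=3).mapping
        assert assign_folds(ids, seed=3).mapping != assign_folds(ids, seed=4).mapping

    def test_rows_of_cluster_share_fold(self):
        ds = make_survey(seed=1, n_clusters=50)
        f = assign_folds(ds.data["cluster_id"], K=5, seed=0)
        per_cluster = pd.Series(
            f.fold_of_rows(ds.data["cluster_id"].to_numpy())
        ).groupby(ds.data["cluster_id"].to_numpy()).nunique()
        assert (per_cluster == 1).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            assign_folds(np.arange(10), K=1)
        with pytest.raises(ValueError):
            assign_folds(np.arange(3), K=5)


class TestOneSeRule:
    def test_zero_se_returns_argmin_with_larger_tie(self):
        curve = CvCurve(grid=np.array([1.0, 2, 3, 4]),
                        cv=np.array([2.0, 1.0, 1.0, 1.5]),
                        se=np.zeros(4))
        assert one_se_lambda(curve) == 3.0

    def test_hand_example(self):
        """{10: 1.00 +/- 0.10, 20: 1.05, 30: 1.12} -> 20."""
        curve = CvCurve(grid=np.array([10.0, 20, 30]),
                        cv=np.array([1.00, 1.05, 1.12]),
                        se=np.array([0.10, 0.08, 0.08]))
        assert one_se_lambda(curve) == 20.0

    def test_monotone_decreasing_curve(self):
        curve = CvCurve(grid=np.array([1.0, 2, 3, 4]),
                        cv=np.array([4.0, 3.0, 2.0, 1.0]),
                        se=np.array([0.5, 0.5, 0.5, 0.5]))
        assert one_se_lambda(curve) == 4.0


class TestPercentileRule:
    def test_textbook_percentile(self):
        assert percentile_lambda(np.arange(1, 101), 95) == pytest.approx(95.05)

    def test_constant_cycles(self):
        for q in (5, 50, 95, 100):
            assert percentile_lambda([7.0] * 12, q) == 7.0

    @given(st.lists(st.floats(0, 1e3), min_size=2, max_size=30),
           st.floats(1, 99), st.floats(1, 99))
    @settings(deadline=None, max_examples=60)
    def test_monotone_in_q(self, lams, q1, q2):
        lo, hi = sorted([q1, q2])
        assert percentile_lambda(lams, lo) <= percentile_lambda(lams, hi)


class TestCvCurve:
    def test_perfect_linear_data_zero_cv(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "cluster_id": np.repeat(np.arange(30), 2),
            "x1": rng.normal(size=60),
        })
        df["y"] = 1.0 + 2.0 * df["x1"]
        d = prepare_design(df, "y", ["x1"])
        pen = make_penalty(d, 0.0)
        curve = cv_curve(d, np.array([0.0]), assign_folds(df["cluster_id"], 5, 0),
                         pen)
        assert curve.cv[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_loco_oracle(self):
        """Leave-one-cluster-out CV on a 6-cluster toy reproduced by an
        independently coded loop (OLS at lambda=0, fixed effects only)."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "cluster_id": np.repeat(np.arange(6), [1, 2, 3, 2, 1, 3]),
            "x1": rng.normal(size=12),
        })
        df["y"] = 0.5 + 0.8 * df["x1"] + rng.normal(0, 0.4, 12)
        d = prepare_design(df, "y", ["x1"])
        folds = assign_folds(df["cluster_id"], K=6, seed=2)
        curve = cv_curve(d, np.array([0.0]), folds, make_penalty(d, 0.0),
                         update_vc=False)

        X = d.X.to_numpy()
        fold_of = folds.fold_of_rows(d.cluster_ids)
        mses = []
        for k in range(6):
            val = fold_of == k
            beta, *_ = np.linalg.lstsq(X[~val], d.y[~val], rcond=None)
            mses.append(np.mean((d.y[val] - X[val] @ beta) ** 2))
        assert curve.cv[0] == pytest.approx(np.mean(mses), rel=1e-9)
        assert curve.se[0] == pytest.approx(np.std(mses, ddof=1) / np.sqrt(6),
                                            rel=1e-9)

    def test_pure_noise_prefers_large_lambda(self):
        """With no signal, CV error at the sparse end of the grid is on
        average no worse than at the dense end (Monte Carlo over seeds)."""
        wins = 0
        reps = 20
        for seed in range(reps):
            ds = make_survey(seed=seed, n_clusters=60, beta={},
                             roster=continuous_roster(6))
            d = prepare_design(ds.data, "annoyance",
                               [f"x{i}" for i in range(1, 7)])
            pen = make_penalty(d, 0.0)
            grid = lambda_grid(lambda_max(d, pen), 12)
            folds = assign_folds(d.cluster_ids, 5, seed)
            curve = cv_curve(d, grid, folds, pen)
            if curve.cv[-1] <= curve.cv[0]:
                wins += 1
        assert wins >= 0.7 * reps


@pytest.fixture(scope="module")
def scenario():
    roster = continuous_roster(6)
    ds = make_survey(seed=21, n_clusters=150,
                     beta={"x1": 0.6, "x2": -0.5}, roster=roster)
    return prepare_design(ds.data, "annoyance",
                          [f"x{i}" for i in range(1, 7)])


class TestPercentileLasso:
    def test_single_cycle_equals_one_se(self, scenario):
        pen = make_penalty(scenario, 0.0)
        sel = percentile_lasso(scenario, pen, R=1, K=5, q=95, seed=3,
                               n_grid=40, keep_curves=True)
        assert sel.lambda_final == one_se_lambda(sel.curves[0])

    def test_reproducible_end_to_end(self, scenario):
        pen = make_penalty(scenario, 0.0)
        a = percentile_lasso(scenario, pen, R=4, K=5, q=95, seed=9, n_grid=30)
        b = percentile_lasso(scenario, pen, R=4, K=5, q=95, seed=9, n_grid=30)
        np.testing.assert_array_equal(a.lambda_opt_per_cycle,
                                      b.lambda_opt_per_cycle)
        assert a.lambda_final == b.lambda_final
        assert a.selected_terms == b.selected_terms
        pd.testing.assert_series_equal(a.refit.fit.beta, b.refit.fit.beta)

    def test_strong_effects_survive(self, scenario):
        pen = make_penalty(scenario, 0.0)
        sel = percentile_lasso(scenario, pen, R=5, K=5, q=95, seed=2, n_grid=50)
        assert {"x1", "x2"} <= set(sel.selected_terms)


class TestRefit:
    def test_full_selection_equals_full_fit(self, factor_design):
        refit = refit_selected(factor_design, list(factor_design.groups))
        full = fit_mixed(factor_design)
        pd.testing.assert_series_equal(refit.fit.beta, full.beta)

    def test_empty_selection_intercept_only(self, factor_design):
        refit = refit_selected(factor_design, [])
        assert list(refit.fit.beta.index) == [INTERCEPT]
        assert refit.r2m == 0.0

    def test_refit_ci_coverage(self):
        """Given the true predictors, the refit's 95% CIs cover the true
        standardized effects in most replicates."""
        hits, total = 0, 0
        for seed in range(30):
            ds = make_survey(seed=100 + seed, n_clusters=300,
                             beta={"x1": 0.4, "x2": -0.4},
                             roster=continuous_roster(5))
            d = prepare_design(ds.data, "annoyance",
                               [f"x{i}" for i in range(1, 6)])
            refit = refit_selected(d, ["x1", "x2"])
            for name, truth in [("x1", 0.4), ("x2", -0.4)]:
                t = refit.tests.loc[name]
                sd = d.standardization[name][1]
                hits += t.ci_low <= truth * sd <= t.ci_high
                total += 1
        assert hits / total >= 0.90

    def test_report_mentions_variance_components(self, factor_design):
        text = refit_selected(factor_design, ["x1"]).report()
        for token in ("sigma2", "tau00", "ICC_adj", "N_ID", "N_obs",
                      "Marginal R2"):
            assert token in text
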