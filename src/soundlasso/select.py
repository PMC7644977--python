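"""Percentile-Lasso variable selection with cluster-aware cross-validation.

The tuning parameter lambda is chosen by K-fold cross-validation in
which folds partition participants, never observations: all listening
situations of one participant land in the same fold, so validation
clusters are genuinely unseen. Held-out predictions use the fixed
effects only (the random intercept of an unseen participant has
expectation zero). The 1-SE rule picks the most parsimonious model
within one standard error of the minimum CV error; repeating the whole
CV over many random fold assignments and taking an upper percentile of
the per-cycle optima (the percentile Lasso) stabilizes the choice
against the fold-assignment lottery. A final unpenalized mixed-model
refit on the surviving variables provides estimates, Satterthwaite
tests, R-squared and ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lasso import (PenaltySpec, fit_path, fit_penalized, lambda_grid,
                    lambda_max)
from .lmm import MixedFit, fit_mixed, fixed_effect_tests, icc_adj, r2_nakagawa
from .preprocess import PreparedDesign

__all__ = [
    "FoldAssignment",
    "CvCurve",
    "RefitResult",
    "SelectionResult",
    "assign_folds",
    "cv_curve",
    "one_se_lambda",
    "percentile_lambda",
    "percentile_lasso",
    "refit_selected",
]


@dataclass
class FoldAssignment:
    """Cluster -> fold map; every cluster's observations share one fold."""

    mapping: dict
    K: int
    seed: int

    def fold_of_rows(self, cluster_ids: np.ndarray) -> np.ndarray:
        return np.array([self.mapping[c] for c in cluster_ids])


@dataclass
class CvCurve:
    """Cross-validation error (mean fold MSE) and its SE per lambda."""

    grid: np.ndarray
    cv: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.cv)) and np.all(self.se >= 0)):
            raise ValueError("CV curve must be finite with nonnegative SEs")


def assign_folds(cluster_ids, K: int = 5, seed: int = 0) -> FoldAssignment:
    """Deal a random permutation of clusters round-robin into K folds.

    Fold cluster-counts differ by at most one; deterministic given seed.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    clusters = np.unique(np.asarray(cluster_ids))
    if len(clusters) < K:
        raise ValueError(f"need at least K={K} clusters, have {len(clusters)}")
    perm = np.random.default_rng(seed).permutation(len(clusters))
    mapping = {clusters[j]: int(i % K) for i, j in enumerate(perm)}
    return FoldAssignment(mapping=mapping, K=K, seed=seed)


def _subset_rows(design: PreparedDesign, mask: np.ndarray) -> PreparedDesign:
    return PreparedDesign(
        y=design.y[mask],
        X=design.X.iloc[mask].reset_index(drop=True),
        groups=design.groups,
        cluster_ids=design.cluster_ids[mask],
        standardization=design.standardization,
        n_dropped=design.n_dropped,
        outcome=design.outcome,
    )


def cv_curve(design: PreparedDesign, grid: np.ndarray, folds: FoldAssignment,
             penalty: PenaltySpec, update_vc: bool = True) -> CvCurve:
    """Cluster-level K-fold CV error along a lambda grid.

    Each fold's model is trained on the other K-1 folds (full path, warm
    starts) and validated on the held-out participants via the fixed
    effects alone; CV is the mean of the K fold MSEs, SE their standard
    deviation over sqrt(K).
    """
    grid = np.asarray(grid, dtype=float)
    fold_of_row = folds.fold_of_rows(design.cluster_ids)
    mse = np.empty((folds.K, len(grid)))
    X = design.X.to_numpy(dtype=float)
    for k in range(folds.K):
        val = fold_of_row == k
        if not val.any() or val.all():
            raise ValueError(f"fold {k} has an empty training or validation set")
        path = fit_path(_subset_rows(design, ~val), grid, penalty,
                        update_vc=update_vc)
        pred = X[val] @ path.coefficients.to_numpy().T  # (n_val, n_lambda)
        mse[k] = np.mean((design.y[val, None] - pred) ** 2, axis=0)
    cv = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(folds.K)
    return CvCurve(grid=grid, cv=cv, se=se)


def one_se_lambda(curve: CvCurve) -> float:
    """Largest lambda whose CV error is within one SE (taken at the
    argmin) of the minimum CV error; ties at the minimum break toward
    the larger lambda."""
    cv = np.asarray(curve.cv)
    if cv.size == 0:
        raise ValueError("empty CV curve")
    i_min = int(np.flatnonzero(cv == cv.min())[-1])
    threshold = cv[i_min] + curve.se[i_min]
    eligible = np.flatnonzero(cv <= threshold)
    return float(curve.grid[eligible[-1]])


@dataclass
class RefitResult:
    """Unpenalized mixed-model refit on the selected variables."""

    fit: MixedFit
    tests: pd.DataFrame
    r2m: float
    r2c: float
    icc: float

    def report(self) -> str:
        """Human-readable model table: estimates, CI, p, df per term and
        the variance-component block."""
        lines = [f"{'term':<28}{'estimate':>10}{'ci_low':>9}{'ci_high':>9}"
                 f"{'p':>10}{'df':>9}"]
        for term, row in self.tests.iterrows():
            lines.append(f"{term:<28}{row.estimate:>10.3f}{row.ci_low:>9.3f}"
                         f"{row.ci_high:>9.3f}{row.p_value:>10.3g}{row.df:>9.1f}")
        f = self.fit
        lines += [
            f"sigma2        {f.sigma2:.3f}",
            f"tau00         {f.tau00:.3f}",
            f"ICC_adj       {self.icc:.3f}",
            f"N_ID          {f.n_clusters}",
            f"N_obs         {f.n_obs}",
            f"Marginal R2   {self.r2m:.3f}",
            f"Conditional R2 {self.r2c:.3f}",
        ]
        return "\n".join(lines)


@dataclass
class SelectionResult:
    """Outcome of the percentile-Lasso procedure."""

    lambda_opt_per_cycle: np.ndarray
    lambda_final: float
    lambda_max: float
    grid: np.ndarray
    percentile: float
    selected_terms: list[str]
    final_fit: object
    refit: RefitResult
    curves: list[CvCurve] = field(default_factory=list)


def refit_selected(design: PreparedDesign, selected_terms: list[str]) -> RefitResult:
    """REML refit on the selected variables with Satterthwaite tests,
    marginal/conditional R-squared and the adjusted ICC (the shape of a
    final comprehensive-model report)."""
    sub = design.subset_terms(list(selected_terms))
    fit = fit_mixed(sub, method="REML")
    tests = fixed_effect_tests(fit)
    r2m, r2c = r2_nakagawa(fit)
    return RefitResult(fit=fit, tests=tests, r2m=r2m, r2c=r2c,
                       icc=icc_adj(fit.tau00, fit.sigma2))


def percentile_lambda(lams, q: float) -> float:
    """q-th percentile of the per-cycle optimal lambdas, using linear
    interpolation between order statistics."""
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    return float(np.percentile(np.asarray(lams, dtype=float), q))


def _cycle_seed(master_seed: int, cycle: int) -> int:
    return int(np.random.SeedSequence([master_seed, cycle]).generate_state(1)[0]
               % (2**31 - 1))


def percentile_lasso(design: PreparedDesign, penalty: PenaltySpec,
                     R: int = 100, K: int = 5, q: float = 95.0,
                     seed: int = 0, n_grid: int = 100, curvature: float = 4.0,
                     update_vc: bool = True, keep_curves: bool = False,
                     grid: np.ndarray | None = None) -> SelectionResult:
    """Run R independent CV cycles and select the q-th percentile lambda.

    The lambda grid is built once from the full data's lambda_max (the
    all-zero threshold found in advance). Each cycle draws a fresh
    cluster-level fold assignment (child seed derived from the master
    seed), computes the CV curve, and applies the 1-SE rule; the final
    lambda is the q-th percentile (linear interpolation between order
    statistics) of the R per-cycle optima. The model is then refit at
    lambda_final; surviving variables are refit unpenalized.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    if grid is None:
        lam_max = lambda_max(design, penalty, update_vc=update_vc)
        grid = lambda_grid(lam_max, n_points=n_grid, curvature=curvature)
    else:
        grid = np.asarray(grid, dtype=float)
        lam_max = float(grid[-1])

    lams = np.empty(R)
    curves: list[CvCurve] = []
    for r in range(R):
        folds = assign_folds(design.cluster_ids, K=K, seed=_cycle_seed(seed, r))
        try:
            curve = cv_curve(design, grid, folds, penalty, update_vc=update_vc)
        except Exception as err:  # propagate with cycle index
            raise RuntimeError(f"cross-validation cycle {r} failed") from err
        lams[r] = one_se_lambda(curve)
        if keep_curves:
            curves.append(curve)

    lambda_final = percentile_lambda(lams, q)
    final = fit_penalized(design, penalty.with_lambda(lambda_final),
                          update_vc=update_vc)
    selected = final.selected_terms(penalty)
    refit = refit_selected(design, selected)
    return SelectionResult(
        lambda_opt_per_cycle=lams,
        lambda_final=lambda_final,
        lambda_max=lam_max,
        grid=grid,
        percentile=q,
        selected_terms=selected,
        final_fit=final,
        refit=refit,
        curves=curves,
    )
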