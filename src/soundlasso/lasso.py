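"""Lasso and group-Lasso paths for random-intercept models.

The penalized criterion generalizes the least-squares Lasso loss

    sum_i (y_i - x_i' beta)^2 + lambda * P(beta)

to clustered data by replacing the residual sum of squares with its
generalized form (y - X beta)' V0^{-1} (y - X beta), where
V0 = I + theta Z Z' whitens the random-intercept correlation
(theta = tau00/sigma2). The penalty P is either the plain L1 sum of
absolute coefficients or, by default, the groupwise-L2 norm that shrinks
and zeroes all dummy columns of one factor together. The intercept (and
any other listed column) is never penalized, and the random-intercept
variance itself is never penalized.

Fitting alternates (i) maximum-likelihood estimation of (tau00, sigma2)
given the current coefficients with (ii) exact blockwise coordinate
descent on the penalized weighted least squares problem given the
current variance components, to a joint fixed point. With tau00 fixed at
0 the solution is the standard (group) Lasso. Zeros are exact
(soft-thresholding), never epsilon-truncation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .lmm import ClusterStats
from .preprocess import INTERCEPT, PreparedDesign

__all__ = [
    "PenaltySpec",
    "PenalizedFit",
    "LassoPath",
    "make_penalty",
    "penalized_objective",
    "fit_penalized",
    "lambda_max",
    "lambda_grid",
    "fit_path",
    "kkt_max_violation",
]


@dataclass
class PenaltySpec:
    """Penalty weight, group structure, and norm.

    groups maps a model term to the design columns it owns; the groups
    must partition the penalized columns. group_norm "l2" applies the
    groupwise Euclidean norm (one shrinkage amount per factor), "l1" the
    plain absolute-value sum. With scale_by_size, each group's weight is
    multiplied by sqrt(group size).
    """

    lam: float
    groups: dict[str, list[str]]
    group_norm: str = "l2"
    scale_by_size: bool = False
    unpenalized: tuple[str, ...] = (INTERCEPT,)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.group_norm not in {"l1", "l2"}:
            raise ValueError("group_norm must be 'l1' or 'l2'")
        cols = [c for g in self.groups.values() for c in g]
        if len(cols) != len(set(cols)):
            raise ValueError("groups must not overlap")
        overlap = set(cols) & set(self.unpenalized)
        if overlap:
            raise ValueError(f"columns cannot be both grouped and unpenalized: {overlap}")

    def with_lambda(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(lam, self.groups, self.group_norm,
                           self.scale_by_size, self.unpenalized)

    def blocks(self, columns: list[str]):
        """Resolve groups to column positions: list of
        (term, positions, weight, penalized)."""
        pos = {c: j for j, c in enumerate(columns)}
        out = []
        for c in self.unpenalized:
            if c in pos:
                out.append((c, np.array([pos[c]]), 0.0, False))
        for term, cols in self.groups.items():
            idx = np.array([pos[c] for c in cols])
            if self.group_norm == "l1":
                for c in cols:
                    out.append((c, np.array([pos[c]]), 1.0, True))
            else:
                w = np.sqrt(len(cols)) if self.scale_by_size else 1.0
                out.append((term, idx, w, True))
        covered = {j for _, idx, _, _ in out for j in idx}
        missing = [c for c in columns if pos[c] not in covered]
        if missing:
            raise ValueError(f"columns not covered by penalty spec: {missing}")
        return out


def make_penalty(design: PreparedDesign, lam: float, group_norm: str = "l2",
                 scale_by_size: bool = False) -> PenaltySpec:
    """Penalty over all of a prepared design's terms (intercept free)."""
    return PenaltySpec(lam, {t: list(c) for t, c in design.groups.items()},
                       group_norm=group_norm, scale_by_size=scale_by_size)


@dataclass
class PenalizedFit:
    beta: pd.Series
    tau00: float
    sigma2: float
    objective: float
    n_iter: int
    converged: bool

    def selected_terms(self, penalty: PenaltySpec) -> list[str]:
        """Terms with any nonzero coefficient."""
        return [t for t, cols in penalty.groups.items()
                if any(self.beta.get(c, 0.0) != 0.0 for c in cols)]


@dataclass
class LassoPath:
    """Coefficient trajectories over an ascending lambda grid."""

    grid: np.ndarray
    coefficients: pd.DataFrame  # one row per lambda, columns = design columns
    tau00: np.ndarray
    sigma2: np.ndarray
    objective: np.ndarray

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.coefficients.copy()
        out.insert(0, "lambda", self.grid)
        out["tau00"] = self.tau00
        out["sigma2"] = self.sigma2
        out.to_csv(path, index=False)
        return path


def _penalty_value(beta: np.ndarray, blocks, lam: float) -> float:
    return lam * sum(w * np.linalg.norm(beta[idx])
                     for _, idx, w, pen in blocks if pen)


def penalized_objective(beta, y, X, penalty: PenaltySpec,
                        cluster_ids=None, theta: float = 0.0) -> float:
    """Whitened residual sum of squares plus penalty.

    With theta = 0 (no random intercept) this is exactly the Lasso loss:
    the plain residual sum of squares plus lambda times the penalty norm.
    """
    X = pd.DataFrame(X)
    b = np.asarray(beta, dtype=float)
    r = np.asarray(y, dtype=float) - X.to_numpy(dtype=float) @ b
    if theta > 0:
        if cluster_ids is None:
            raise ValueError("cluster_ids required when theta > 0")
        _, inv = np.unique(cluster_ids, return_inverse=True)
        sizes = np.bincount(inv).astype(float)
        s = np.bincount(inv, weights=r)
        w = theta / (1.0 + theta * sizes)
        rss = float(r @ r) - float(w @ s**2)
    else:
        rss = float(r @ r)
    blocks = penalty.blocks(list(X.columns))
    return rss + _penalty_value(b, blocks, penalty.lam)


def _vc_ml(st: ClusterStats, r: np.ndarray, theta_init: float = 0.0):
    """ML variance components of r = Z u + e given the cluster structure.

    Profiles sigma2 out and maximizes over theta = tau00/sigma2 by root-
    finding on the profiled score; returns (theta, sigma2)."""
    rr = float(r @ r)
    s = st.cluster_sums(r)
    s2 = s**2
    theta = _kernels.vc_solve(rr, s2, st.sizes, st.n, theta_init)
    q = rr - float((theta / (1.0 + theta * st.sizes)) @ s2)
    return theta, q / st.n


def _encode_blocks(blocks):
    """Flatten a block structure for the compiled solver."""
    idxs = np.concatenate([idx for _, idx, _, _ in blocks]).astype(np.int64)
    ptr = np.cumsum([0] + [len(idx) for _, idx, _, _ in blocks]).astype(np.int64)
    wgt = np.array([w if pen else 0.0 for _, _, w, pen in blocks])
    pen8 = np.array([1 if pen else 0 for _, _, _, pen in blocks], dtype=np.int8)
    return idxs, ptr, wgt, pen8


def fit_penalized(design: PreparedDesign, penalty: PenaltySpec,
                  update_vc: bool = True, theta0: float = 0.0,
                  beta0: np.ndarray | None = None,
                  tol: float = 1e-8, max_iter: int = 100,
                  cd_tol: float = 1e-11,
                  _stats: ClusterStats | None = None) -> PenalizedFit:
    """Fit the penalized random-intercept model at one lambda.

    Alternates exact blockwise coordinate descent (given the variance
    components) with ML variance-component estimation (given the
    coefficients) to a joint fixed point: relative objective change
    below `tol`. update_vc=False freezes theta at `theta0` (theta0=0
    gives the standard group Lasso on the raw residual sum of squares).
    """
    st = _stats if _stats is not None else ClusterStats(
        design.y, design.X.to_numpy(dtype=float), design.cluster_ids)
    cols = list(design.X.columns)
    blocks = penalty.blocks(cols)
    idxs, ptr, wgt, pen8 = _encode_blocks(blocks)
    beta = np.zeros(st.p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    theta, sigma2, obj, n_iter, converged = _kernels.penalized_fit(
        st.XtX, st.Xty, st.yty, st.Sx, st.Sy, st.sizes, st.n,
        idxs, ptr, wgt, pen8, float(penalty.lam), float(theta0), beta,
        update_vc, tol, max_iter, cd_tol, 5000)
    if not converged:
        raise RuntimeError(
            f"penalized fit did not converge in {max_iter} iterations "
            f"(lambda={penalty.lam:g}, last objective {obj:g})")
    return PenalizedFit(beta=pd.Series(beta, index=cols), tau00=theta * sigma2,
                        sigma2=sigma2, objective=obj, n_iter=n_iter,
                        converged=converged)


def kkt_max_violation(design: PreparedDesign, beta, penalty: PenaltySpec,
                      theta: float = 0.0) -> float:
    """Largest violation of the subgradient optimality conditions.

    For active blocks the stationarity equation must hold; for inactive
    blocks the dual-norm bound ||2 X_g' V0^{-1} r|| <= lambda_g must hold.
    Returns the maximum excess over all blocks (0 at an exact solution).
    """
    st = ClusterStats(design.y, design.X.to_numpy(dtype=float), design.cluster_ids)
    A, b, _, _ = st.whitened_forms(theta)
    beta = np.asarray(beta, dtype=float)
    grad = 2.0 * (A @ beta - b)
    worst = 0.0
    for _, idx, w, pen in penalty.blocks(list(design.X.columns)):
        g = grad[idx]
        if not pen or penalty.lam == 0:
            worst = max(worst, float(np.max(np.abs(g))))
        elif np.any(beta[idx] != 0):
            direction = beta[idx] / np.linalg.norm(beta[idx])
            worst = max(worst, float(np.linalg.norm(g + penalty.lam * w * direction)))
        else:
            worst = max(worst, max(0.0, float(np.linalg.norm(g)) - penalty.lam * w))
    return worst


def lambda_max(design: PreparedDesign, penalty: PenaltySpec,
               update_vc: bool = True, rel_tol: float = 1e-6) -> float:
    """Smallest lambda at which every penalized coefficient is zero.

    With the variance ratio fixed at 0 this is the closed-form KKT bound
    max_g ||2 X_g'(y - y_hat_unpenalized)|| / w_g. With variance-component
    updating, the KKT bound at the all-zero fixed point seeds a bisection
    on the fitted path, refined to relative tolerance `rel_tol`.
    """
    st = ClusterStats(design.y, design.X.to_numpy(dtype=float), design.cluster_ids)
    cols = list(design.X.columns)
    blocks = penalty.blocks(cols)
    free = [blk for blk in blocks if not blk[3]]

    def kkt_bound(theta: float) -> tuple[float, np.ndarray]:
        A, b, _, _ = st.whitened_forms(theta)
        beta = np.zeros(st.p)
        for _, idx, _, _ in free:
            beta[idx] = np.linalg.solve(A[np.ix_(idx, idx)], b[idx])
        grad = 2.0 * (b - A @ beta)
        bound = 0.0
        for _, idx, w, pen in blocks:
            if pen:
                bound = max(bound, float(np.linalg.norm(grad[idx])) / w)
        return bound, beta

    theta = 0.0
    if update_vc:
        for _ in range(100):
            _, beta = kkt_bound(theta)
            theta_new, _ = _vc_ml(st, design.y - st.X @ beta)
            if abs(theta_new - theta) <= 1e-10 * (theta + 1.0):
                theta = theta_new
                break
            theta = theta_new
    lam0, _ = kkt_bound(theta)
    if lam0 <= 0:
        return 0.0
    if not update_vc:
        return lam0

    def all_zero(lam: float) -> bool:
        fit = fit_penalized(design, penalty.with_lambda(lam), update_vc=True)
        b = fit.beta.to_numpy()
        return all(np.all(b[idx] == 0) for _, idx, _, pen in blocks if pen)

    lo, hi = 0.5 * lam0, lam0 * (1.0 + 1e-9)
    while not all_zero(hi):
        lo, hi = hi, hi * 1.5
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if all_zero(mid):
            hi = mid
        else:
            lo = mid
    return hi


def lambda_grid(lam_max: float, n_points: int = 100,
                curvature: float = 4.0) -> np.ndarray:
    """Ascending exponential lambda grid from 0 to lam_max.

    grid_i = lam_max * (exp(s i/(n-1)) - 1) / (exp(s) - 1): spacing is
    finest near zero, where the cross-validation curve needs resolution.
    """
    if lam_max <= 0:
        raise ValueError("lambda_max must be > 0")
    if n_points < 2:
        raise ValueError("need at least 2 grid points")
    i = np.arange(n_points)
    return lam_max * np.expm1(curvature * i / (n_points - 1)) / np.expm1(curvature)


def fit_path(design: PreparedDesign, grid: np.ndarray, penalty: PenaltySpec,
             update_vc: bool = True) -> LassoPath:
    """Fit the penalized model along an ascending grid (computed from the
    largest lambda down, warm-starting each fit at its neighbor)."""
    grid = np.asarray(grid, dtype=float)
    st = ClusterStats(design.y, design.X.to_numpy(dtype=float), design.cluster_ids)
    p = design.X.shape[1]
    coefs = np.zeros((len(grid), p))
    tau = np.zeros(len(grid))
    sig = np.zeros(len(grid))
    obj = np.zeros(len(grid))
    beta0 = np.zeros(p)
    theta0 = 0.0
    for k in range(len(grid) - 1, -1, -1):
        fit = fit_penalized(design, penalty.with_lambda(grid[k]),
                            update_vc=update_vc, theta0=theta0, beta0=beta0,
                            _stats=st)
        beta0 = fit.beta.to_numpy().copy()
        theta0 = fit.tau00 / fit.sigma2 if fit.sigma2 > 0 else 0.0
        coefs[k] = beta0
        tau[k], sig[k], obj[k] = fit.tau00, fit.sigma2, fit.objective
    return LassoPath(grid=grid,
                     coefficients=pd.DataFrame(coefs, columns=design.X.columns),
                     tau00=tau, sigma2=sig, objective=obj)
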