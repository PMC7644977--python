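"""Random-intercept linear mixed models.

Model: y_ij = x_ij' beta + u_i + e_ij with u_i ~ N(0, tau00) and
e_ij ~ N(0, sigma2), i indexing clusters (participants). Estimation
profiles the criterion over the variance ratio theta = tau00/sigma2:
for fixed theta, beta and sigma2 have closed forms, so the (restricted)
likelihood reduces to a smooth scalar function of theta maximized with a
bounded optimizer. The boundary tau00 = 0 is allowed and reduces the fit
to ordinary least squares.

Derived quantities: Satterthwaite degrees of freedom for fixed-effect
t-tests (via the observed information of the REML criterion in
(tau00, sigma2)), marginal/conditional R-squared, and the adjusted
intraclass correlation tau00/(tau00 + sigma2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocess import PreparedDesign

__all__ = [
    "MixedFit",
    "TestResult",
    "fit_mixed",
    "satterthwaite_test",
    "fixed_effect_tests",
    "r2_nakagawa",
    "icc_adj",
]

_LOG_THETA_LO, _LOG_THETA_HI = -14.0, 12.0


class ClusterStats:
    """Sufficient statistics of (y, X, clusters) for random-intercept GLS.

    For V0 = I + theta * Z Z' (Z the cluster indicator matrix),
    V0^{-1} is block diagonal with blocks I - w_i J, w_i = theta/(1 + theta n_i),
    so X'V0^{-1}X, X'V0^{-1}y and y'V0^{-1}y need only the per-cluster
    sums of X and y. Everything here is O(n) once, then O(n_clusters p^2)
    per theta evaluation.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, cluster_ids: np.ndarray):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        _, inv = np.unique(cluster_ids, return_inverse=True)
        self.n, self.p = X.shape
        self.n_clusters = int(inv.max()) + 1
        self.inv = inv
        self.sizes = np.bincount(inv).astype(float)
        self.X, self.y = X, y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Sx = np.zeros((self.n_clusters, self.p))
        np.add.at(self.Sx, inv, X)
        self.Sy = np.bincount(inv, weights=y)

    def whitened_forms(self, theta: float):
        """Return (A, b, q, logdetV0) with A = X'V0^{-1}X, b = X'V0^{-1}y,
        q = y'V0^{-1}y."""
        w = theta / (1.0 + theta * self.sizes)
        A = self.XtX - self.Sx.T @ (w[:, None] * self.Sx)
        b = self.Xty - self.Sx.T @ (w * self.Sy)
        q = self.yty - float(w @ (self.Sy**2))
        logdet = float(np.sum(np.log1p(theta * self.sizes)))
        return A, b, q, logdet

    def cluster_sums(self, r: np.ndarray) -> np.ndarray:
        return np.bincount(self.inv, weights=r, minlength=self.n_clusters)


@dataclass
class TestResult:
    """t-test of one fixed effect with Satterthwaite degrees of freedom."""

    term: str
    estimate: float
    se: float
    df: float
    t: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass
class MixedFit:
    """Fitted random-intercept model."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    tau00: float
    sigma2: float
    loglik: float
    method: str
    n_obs: int
    n_clusters: int
    converged: bool
    boundary: bool
    fitted_fixed: np.ndarray
    warnings: list[str] = field(default_factory=list)
    _stats: ClusterStats | None = None

    @property
    def theta(self) -> float:
        return self.tau00 / self.sigma2

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def se_beta(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta.to_numpy())),
                         index=self.beta.index)

    @property
    def icc(self) -> float:
        return icc_adj(self.tau00, self.sigma2)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        from scipy.linalg import qr

        _, _, piv = qr(arr, mode="economic", pivoting=True)
        bad = [X.columns[j] for j in piv[rank:]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


@np.errstate(all="ignore")  # near-singular evaluations during the search
def _criterion(stats_: ClusterStats, theta: float, method: str):
    """Negative profiled (restricted) log-likelihood and profiled estimates."""
    A, b, q, logdet = stats_.whitened_forms(theta)
    beta = np.linalg.solve(A, b)
    rss = max(q - float(b @ beta), 1e-300)
    n, p = stats_.n, stats_.p
    if method == "REML":
        sigma2 = rss / (n - p)
        sign, logdetA = np.linalg.slogdet(A)
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet + logdetA)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return -ll, beta, sigma2, A


def fit_mixed(design: PreparedDesign, method: str = "REML") -> MixedFit:
    """Fit the random-intercept model to a prepared design.

    Profiles the (restricted) likelihood over theta = tau00/sigma2 on a
    log scale with a bounded scalar optimizer; the boundary estimate
    tau00 = 0 is returned whenever it attains the higher likelihood.
    """
    if method not in {"ML", "REML"}:
        raise ValueError("method must be 'ML' or 'REML'")
    _check_rank(design.X)
    st = ClusterStats(design.y, design.X.to_numpy(dtype=float), design.cluster_ids)
    if st.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    warnings: list[str] = []

    if st.sizes.max() <= 1:
        # every cluster observed once: tau00 not identified, fall back to OLS
        theta_hat, boundary = 0.0, True
        warnings.append("all clusters have a single observation; tau00 not "
                        "identified, returning the OLS solution with tau00 = 0")
        converged = True
    else:
        res = optimize.minimize_scalar(
            lambda t: _criterion(st, np.exp(t), method)[0],
            bounds=(_LOG_THETA_LO, _LOG_THETA_HI),
            method="bounded",
            options={"xatol": 1e-10},
        )
        converged = bool(res.success)
        if not converged:
            raise RuntimeError(f"variance-ratio optimization failed: {res}")
        nll0 = _criterion(st, 0.0, method)[0]
        if nll0 <= res.fun or res.x <= _LOG_THETA_LO + 1e-6:
            theta_hat, boundary = 0.0, True
            warnings.append("tau00 estimated at the boundary 0")
        else:
            theta_hat, boundary = float(np.exp(res.x)), False

    nll, beta, sigma2, A = _criterion(st, theta_hat, method)
    cov = sigma2 * np.linalg.inv(A)
    cols = list(design.X.columns)
    return MixedFit(
        beta=pd.Series(beta, index=cols),
        cov_beta=pd.DataFrame(cov, index=cols, columns=cols),
        tau00=theta_hat * sigma2,
        sigma2=sigma2,
        loglik=-nll,
        method=method,
        n_obs=st.n,
        n_clusters=st.n_clusters,
        converged=converged,
        boundary=boundary,
        fitted_fixed=design.X.to_numpy(dtype=float) @ beta,
        warnings=warnings,
        _stats=st,
    )


@np.errstate(all="ignore")  # finite-difference probes may graze the boundary
def _reml_loglik_vc(st: ClusterStats, tau00: float, sigma2: float) -> float:
    """Unprofiled REML log-likelihood as a function of the variance
    components (beta profiled out)."""
    theta = tau00 / sigma2
    A, b, q, logdet = st.whitened_forms(theta)
    beta = np.linalg.solve(A, b)
    rss = q - float(b @ beta)
    n, p = st.n, st.p
    _, logdetA = np.linalg.slogdet(A)
    # log|X'V^-1 X| = log|A| - p log sigma2; log|V| = n log sigma2 + log|V0|
    return -0.5 * ((n - p) * np.log(2 * np.pi) + (n - p) * np.log(sigma2)
                   + logdet + logdetA + rss / sigma2)


def _var_cbeta(st: ClusterStats, c: np.ndarray, tau00: float, sigma2: float) -> float:
    A, *_ = st.whitened_forms(tau00 / sigma2)
    return sigma2 * float(c @ np.linalg.solve(A, c))


def satterthwaite_test(fit: MixedFit, coefficient: str,
                       level: float = 0.95) -> TestResult:
    """t-test of one coefficient with Satterthwaite degrees of freedom.

    df = 2 [Var(c'beta)]^2 / Var[Var(c'beta)], where the variance of the
    variance combines the gradient of Var(c'beta) in (tau00, sigma2) with
    the inverse observed information of the REML criterion (central
    finite differences). At the tau00 = 0 boundary the test falls back to
    the OLS residual degrees of freedom n - p.
    """
    if fit.method != "REML":
        raise ValueError("Satterthwaite tests require a REML fit")
    st = fit._stats
    if st is None:
        raise ValueError("fit does not carry its sufficient statistics")
    idx = list(fit.beta.index).index(coefficient)
    est = float(fit.beta.iloc[idx])
    var = float(fit.cov_beta.iloc[idx, idx])
    se = np.sqrt(var)
    n, p = fit.n_obs, fit.p

    if fit.boundary:
        df = float(n - p)
    else:
        c = np.zeros(p)
        c[idx] = 1.0
        vc = np.array([fit.tau00, fit.sigma2])
        h = np.maximum(1e-5 * np.maximum(np.abs(vc), fit.sigma2), 1e-10)

        def f(v):
            return _var_cbeta(st, c, v[0], v[1])

        def ll(v):
            return _reml_loglik_vc(st, v[0], v[1])

        grad = np.zeros(2)
        hess = np.zeros((2, 2))
        for i in range(2):
            ei = np.zeros(2)
            ei[i] = h[i]
            grad[i] = (f(vc + ei) - f(vc - ei)) / (2 * h[i])
            hess[i, i] = (ll(vc + ei) - 2 * ll(vc) + ll(vc - ei)) / h[i] ** 2
        e0 = np.array([h[0], 0.0])
        e1 = np.array([0.0, h[1]])
        hess[0, 1] = hess[1, 0] = (
            ll(vc + e0 + e1) - ll(vc + e0 - e1) - ll(vc - e0 + e1) + ll(vc - e0 - e1)
        ) / (4 * h[0] * h[1])
        info = -hess
        try:
            var_of_var = float(grad @ np.linalg.solve(info, grad))
        except np.linalg.LinAlgError:
            var_of_var = np.inf
        if not np.isfinite(var_of_var) or var_of_var <= 0:
            df = float(n - p)
        else:
            df = 2.0 * var**2 / var_of_var
            df = float(np.clip(df, 1.0, n - p))

    t = est / se
    p_value = 2.0 * stats.t.sf(abs(t), df)
    tq = stats.t.ppf(0.5 + level / 2.0, df)
    return TestResult(coefficient, est, se, df, t, p_value,
                      est - tq * se, est + tq * se)


def fixed_effect_tests(fit: MixedFit, level: float = 0.95) -> pd.DataFrame:
    """Satterthwaite t-tests for every fixed effect, as a table."""
    rows = [satterthwaite_test(fit, c, level) for c in fit.beta.index]
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("term")


def r2_nakagawa(fit: MixedFit) -> tuple[float, float]:
    """Marginal and conditional R-squared for a random-intercept fit.

    R2m = varF / (varF + tau00 + sigma2) is the share explained by the
    fixed effects; R2c = (varF + tau00) / (varF + tau00 + sigma2) adds
    the random intercept. varF is the sample variance of the fixed-effect
    linear predictor.
    """
    fitted = fit.fitted_fixed
    if fit.n_obs <= 1 or np.ptp(fitted) == 0.0:  # constant predictor
        var_f = 0.0
    else:
        var_f = float(np.var(fitted, ddof=1))
    total = var_f + fit.tau00 + fit.sigma2
    return var_f / total, (var_f + fit.tau00) / total


def icc_adj(tau00: float, sigma2: float) -> float:
    """Adjusted intraclass correlation tau00 / (tau00 + sigma2)."""
    if tau00 < 0 or sigma2 <= 0:
        raise ValueError("need tau00 >= 0 and sigma2 > 0")
    return tau00 / (tau00 + sigma2)
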