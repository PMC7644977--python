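"""Compiled inner loops of the penalized mixed-model solver.

The solver operates entirely on sufficient statistics: the Gram forms
X'X, X'y, y'y and the per-cluster sums of X and y. Whitening for the
random-intercept covariance V0 = I + theta ZZ' then costs
O(n_clusters p^2), one coordinate-descent sweep O(p^2), and the
variance-component score O(n_clusters) — all independent of n. These
loops dominate the cross-validation workload, hence numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["whiten", "cd", "vc_solve", "penalized_fit"]


@njit(cache=True)
def whiten(XtX, Xty, yty, Sx, Sy, sizes, theta):
    """A = X'V0^{-1}X, b = X'V0^{-1}y, q = y'V0^{-1}y for the given
    variance ratio theta."""
    nc, p = Sx.shape
    A = XtX.copy()
    b = Xty.copy()
    q = yty
    for i in range(nc):
        w = theta / (1.0 + theta * sizes[i])
        sy = Sy[i]
        q -= w * sy * sy
        for r in range(p):
            wr = w * Sx[i, r]
            b[r] -= wr * sy
            for c in range(p):
                A[r, c] -= wr * Sx[i, c]
    return A, b, q


@njit(cache=True)
def cd(A, b, beta, idxs, ptr, lamw, pen, tol, max_iter):
    """Blockwise coordinate descent on beta'A beta - 2 b'beta + penalty.

    Blocks are encoded by `idxs[ptr[g]:ptr[g+1]]`; lamw[g] is the
    block's penalty weight (lambda times group weight; 0 = unpenalized),
    pen[g] flags penalized blocks. Singleton updates soft-threshold;
    multi-column group updates solve the exact groupwise problem via the
    block's eigendecomposition and a monotone Newton iteration. Exact
    zeros only ever arise from thresholding.
    """
    p = A.shape[0]
    nb = ptr.shape[0] - 1
    m_max = 1
    for g in range(nb):
        m = ptr[g + 1] - ptr[g]
        if m > m_max:
            m_max = m
    ev = np.zeros((nb, m_max))
    evec = np.zeros((nb, m_max, m_max))
    for g in range(nb):
        s, e = ptr[g], ptr[g + 1]
        m = e - s
        if m > 1:
            Agg = np.empty((m, m))
            for r in range(m):
                for c in range(m):
                    Agg[r, c] = A[idxs[s + r], idxs[s + c]]
            w_, v_ = np.linalg.eigh(Agg)
            ev[g, :m] = w_
            evec[g, :m, :m] = v_

    Abeta = A @ beta
    for _ in range(max_iter):
        delta = 0.0
        for g in range(nb):
            s, e = ptr[g], ptr[g + 1]
            m = e - s
            lw = lamw[g]
            if m == 1:
                j = idxs[s]
                a = A[j, j]
                old = beta[j]
                z = b[j] - Abeta[j] + a * old
                if pen[g] == 1 and lw > 0.0:
                    az = abs(z) - 0.5 * lw
                    if az > 0.0:
                        new = az / a if z > 0.0 else -az / a
                    else:
                        new = 0.0
                else:
                    new = z / a
                if new != old:
                    diff = new - old
                    beta[j] = new
                    for r in range(p):
                        Abeta[r] += A[r, j] * diff
                    if abs(diff) > delta:
                        delta = abs(diff)
            else:
                z2 = np.empty(m)  # 2 * partial-residual correlation
                for r in range(m):
                    j = idxs[s + r]
                    zz = b[j] - Abeta[j]
                    for c in range(m):
                        zz += A[j, idxs[s + c]] * beta[idxs[s + c]]
                    z2[r] = 2.0 * zz
                nz2 = 0.0
                for r in range(m):
                    nz2 += z2[r] * z2[r]
                nz = np.sqrt(nz2)
                newv = np.zeros(m)
                zt = np.zeros(m)
                for r in range(m):
                    for c in range(m):
                        zt[r] += evec[g, c, r] * z2[c]
                if pen[g] == 1 and lw > 0.0:
                    if nz > lw:
                        # phi(t) = sum zt^2/(2 d t + lw)^2 is decreasing
                        # convex; Newton from the left bracket is monotone
                        t = (nz - lw) / (2.0 * ev[g, m - 1])
                        for _it in range(100):
                            phi = 0.0
                            dphi = 0.0
                            for r in range(m):
                                den = 2.0 * ev[g, r] * t + lw
                                u = zt[r] * zt[r] / (den * den)
                                phi += u
                                dphi -= 4.0 * ev[g, r] * u / den
                            if abs(phi - 1.0) < 1e-14:
                                break
                            step = (phi - 1.0) / dphi
                            t -= step
                            if abs(step) < 1e-16 * (1.0 + t):
                                break
                        for r in range(m):
                            u = zt[r] / (2.0 * ev[g, r] + lw / t)
                            for c in range(m):
                                newv[c] += evec[g, c, r] * u
                else:
                    for r in range(m):
                        u = 0.5 * zt[r] / ev[g, r]
                        for c in range(m):
                            newv[c] += evec[g, c, r] * u
                for r in range(m):
                    j = idxs[s + r]
                    diff = newv[r] - beta[j]
                    if diff != 0.0:
                        beta[j] = newv[r]
                        for rr in range(p):
                            Abeta[rr] += A[rr, j] * diff
                        if abs(diff) > delta:
                            delta = abs(diff)
        bmax = 0.0
        for j in range(p):
            if abs(beta[j]) > bmax:
                bmax = abs(beta[j])
        if delta <= tol * (1.0 + bmax):
            break
    return beta


@njit(cache=True)
def _vc_score(theta, rr, s2, sizes, n):
    t1 = 0.0
    t2 = 0.0
    q = rr
    for i in range(s2.shape[0]):
        den = 1.0 + theta * sizes[i]
        t1 += sizes[i] / den
        t2 += s2[i] / (den * den)
        q -= theta / den * s2[i]
    return t1 - n * t2 / q


@njit(cache=True)
def vc_solve(rr, s2, sizes, n, theta_init):
    """Profiled ML score root for theta = tau00/sigma2 (0 at boundary)."""
    if rr <= 1e-300:  # exact fit: no residual variance to decompose
        return 0.0
    if _vc_score(0.0, rr, s2, sizes, n) >= 0.0:
        return 0.0
    hi = 1.0 if theta_init <= 0.5 else 2.0 * theta_init
    while _vc_score(hi, rr, s2, sizes, n) < 0.0:
        hi *= 4.0
        if hi > 1e8:
            return hi
    lo = 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _vc_score(mid, rr, s2, sizes, n) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-13 * (1.0 + hi):
            break
    return 0.5 * (lo + hi)


@njit(cache=True)
def penalized_fit(XtX, Xty, yty, Sx, Sy, sizes, n, idxs, ptr, wgt, pen,
                  lam, theta0, beta, update_vc, tol, max_iter,
                  cd_tol, cd_max_iter):
    """Alternate coordinate descent and ML variance-component updates to
    a joint fixed point; returns (theta, sigma2, objective, n_iter,
    converged). `beta` is updated in place (warm starts)."""
    nb = ptr.shape[0] - 1
    lamw = np.empty(nb)
    for g in range(nb):
        lamw[g] = lam * wgt[g]
    theta = theta0
    prev_obj = 1.0e300
    obj = prev_obj
    sigma2 = 0.0
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        A, b, q = whiten(XtX, Xty, yty, Sx, Sy, sizes, theta)
        cd(A, b, beta, idxs, ptr, lamw, pen, cd_tol, cd_max_iter)
        if update_vc:
            rr = yty - 2.0 * np.dot(Xty, beta) + np.dot(beta, XtX @ beta)
            s_r = Sy - Sx @ beta
            s2 = s_r * s_r
            theta = vc_solve(rr, s2, sizes, n, theta)
            qr = rr
            for i in range(s2.shape[0]):
                qr -= theta / (1.0 + theta * sizes[i]) * s2[i]
            sigma2 = qr / n
            A, b, q = whiten(XtX, Xty, yty, Sx, Sy, sizes, theta)
        pen_val = 0.0
        for g in range(nb):
            if pen[g] == 1:
                s, e = ptr[g], ptr[g + 1]
                nn = 0.0
                for r in range(s, e):
                    nn += beta[idxs[r]] * beta[idxs[r]]
                pen_val += wgt[g] * np.sqrt(nn)
        obj = q - 2.0 * np.dot(b, beta) + np.dot(beta, A @ beta) + lam * pen_val
        if abs(prev_obj - obj) <= tol * (abs(obj) + 1.0):
            converged = True
            break
        prev_obj = obj
        if not update_vc:
            converged = True
            break
    if not update_vc:
        A, b, q = whiten(XtX, Xty, yty, Sx, Sy, sizes, theta)
        wrss = q - 2.0 * np.dot(b, beta) + np.dot(beta, A @ beta)
        sigma2 = wrss / n if wrss > 0.0 else 0.0
    return theta, sigma2, obj, n_iter, converged
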