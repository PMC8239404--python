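"""Numerical kernels for the penalized linear mixed model.

The model is ``y = b0 + X beta + Z u + e`` with a single grouped random
intercept ``u ~ N(0, s2_site I)`` and ``e ~ N(0, s2_res I)``.  For fixed
variance components the fit minimizes the Henderson-type joint objective

    J = (1/2n) ||y - b0 - X beta - Z u||^2 + (kappa/2n) ||u||^2
        + lam1 ||beta||_1 + (lam2/2) ||beta||^2

with ``kappa = s2_res / s2_site`` (the mixed-model ridge weight on the
random intercepts), ``lam1 = lam * alpha`` and ``lam2 = lam * (1-alpha)``.
Each iteration exactly minimizes over u (per-group shrunken means) and b0,
then runs one cyclic coordinate-descent sweep with soft-thresholding over
beta — every step decreases J, so the recorded objective trace is
non-increasing by construction.  Variance components are re-estimated by
EM-type moment updates interleaved with the coordinate sweeps (phase A);
once they stabilize, kappa is frozen and the fit polishes to the beta
tolerance while recording the trace (phase B).

Kernels are numba-compiled; everything takes plain float64/int64 arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KAPPA_MAX = 1e12
S2_SITE_FLOOR = 1e-12


@njit(cache=True)
def _soft_threshold(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def _cd_sweep(X, r, beta, d, lam1, lam2):
    """One cyclic coordinate-descent sweep; r is updated in place.

    r holds ``y - b0 - X beta - Z u``.  Returns max absolute beta change.
    """
    n, p = X.shape
    max_delta = 0.0
    for j in range(p):
        bj = beta[j]
        s = 0.0
        for i in range(n):
            s += X[i, j] * r[i]
        z = s / n + d[j] * bj
        bnew = _soft_threshold(z, lam1) / (d[j] + lam2)
        if bnew != bj:
            diff = bnew - bj
            for i in range(n):
                r[i] -= diff * X[i, j]
            beta[j] = bnew
            ad = abs(diff)
            if ad > max_delta:
                max_delta = ad
    return max_delta


@njit(cache=True)
def _apply_u_delta(r, u_old, u, gidx):
    n = r.shape[0]
    for i in range(n):
        r[i] -= u[gidx[i]] - u_old[gidx[i]]


@njit(cache=True)
def _objective(r, u, beta, kappa, lam1, lam2, has_ranef):
    n = r.shape[0]
    rss = 0.0
    for i in range(n):
        rss += r[i] * r[i]
    obj = 0.5 * rss / n
    if has_ranef:
        uu = 0.0
        for j in range(u.shape[0]):
            uu += u[j] * u[j]
        if uu > 0.0:
            obj += 0.5 * kappa * uu / n
    l1 = 0.0
    l2 = 0.0
    for j in range(beta.shape[0]):
        l1 += abs(beta[j])
        l2 += beta[j] * beta[j]
    return obj + lam1 * l1 + 0.5 * lam2 * l2


@njit(cache=True)
def _em_variance_update(rf, gidx, gsize, s2_site, s2_res):
    """One EM update of (s2_site, s2_res) given fixed-effect residuals rf."""
    n = rf.shape[0]
    q = gsize.shape[0]
    gsum = np.zeros(q)
    for i in range(n):
        gsum[gidx[i]] += rf[i]
    s2_site_new = 0.0
    trace_term = 0.0
    ublup = np.zeros(q)
    for j in range(q):
        denom = s2_res + gsize[j] * s2_site
        ublup[j] = s2_site * gsum[j] / denom
        vj = s2_res * s2_site / denom
        s2_site_new += ublup[j] * ublup[j] + vj
        trace_term += gsize[j] * vj
    s2_site_new /= q
    rss = 0.0
    for i in range(n):
        d = rf[i] - ublup[gidx[i]]
        rss += d * d
    s2_res_new = (rss + trace_term) / n
    return s2_site_new, s2_res_new


@njit(cache=True)
def fit_kernel(
    X,
    y,
    gidx,
    gsize,
    lam1,
    lam2,
    tol,
    max_iter,
    s2_site0,
    s2_res0,
    update_var,
    var_tol,
    has_ranef,
    beta0,
    b0_init,
    warm,
):
    """Full penalized LMM fit.  Returns (beta, b0, u, s2_site, s2_res,
    trace, n_trace, n_iter, converged)."""
    n, p = X.shape
    q = gsize.shape[0]
    d = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        d[j] = s / n

    beta = np.zeros(p)
    if warm:
        for j in range(p):
            beta[j] = beta0[j]
        b0 = b0_init
    else:
        b0 = 0.0
        s = 0.0
        for i in range(n):
            s += y[i]
        b0 = s / n
    u = np.zeros(q)
    s2_site = s2_site0
    s2_res = s2_res0

    # residual r = y - b0 - X beta - Z u   (u starts at 0)
    r = np.empty(n)
    for i in range(n):
        s = y[i]
        for j in range(p):
            if beta[j] != 0.0:
                s -= X[i, j] * beta[j]
        r[i] = s - b0

    n_iter = 0
    converged = False

    # ---- phase A: interleave coordinate sweeps with EM variance updates
    if update_var and has_ranef:
        for _ in range(max_iter):
            n_iter += 1
            kappa = s2_res / max(s2_site, S2_SITE_FLOOR)
            if kappa > KAPPA_MAX:
                kappa = KAPPA_MAX
            u_old = u.copy()
            gsum = np.zeros(q)
            for i in range(n):
                gsum[gidx[i]] += r[i]
            for j in range(q):
                u[j] = (gsum[j] + gsize[j] * u[j]) / (gsize[j] + kappa)
            _apply_u_delta(r, u_old, u, gidx)
            s = 0.0
            for i in range(n):
                s += r[i]
            db0 = s / n
            b0 += db0
            for i in range(n):
                r[i] -= db0
            max_db = _cd_sweep(X, r, beta, d, lam1, lam2)
            # EM variance update from fixed-effect residuals rf = r + Z u
            rf = np.empty(n)
            for i in range(n):
                rf[i] = r[i] + u[gidx[i]]
            s2_site_new, s2_res_new = _em_variance_update(
                rf, gidx, gsize, s2_site, s2_res
            )
            rel = abs(s2_site_new - s2_site) + abs(s2_res_new - s2_res)
            denom = s2_site + s2_res
            s2_site = s2_site_new
            s2_res = s2_res_new
            if s2_site < S2_SITE_FLOOR:
                s2_site = 0.0
            if rel <= var_tol * denom and max_db < tol:
                break

    # ---- phase B: fixed variance weights, monotone objective trace
    if has_ranef:
        kappa = s2_res / max(s2_site, S2_SITE_FLOOR)
        if kappa > KAPPA_MAX:
            kappa = KAPPA_MAX
    else:
        kappa = KAPPA_MAX
    trace = np.empty(max_iter)
    n_trace = 0
    for _ in range(max_iter):
        n_iter += 1
        max_du = 0.0
        if has_ranef:
            u_old = u.copy()
            gsum = np.zeros(q)
            for i in range(n):
                gsum[gidx[i]] += r[i]
            for j in range(q):
                unew = (gsum[j] + gsize[j] * u[j]) / (gsize[j] + kappa)
                du = abs(unew - u[j])
                if du > max_du:
                    max_du = du
                u[j] = unew
            _apply_u_delta(r, u_old, u, gidx)
        s = 0.0
        for i in range(n):
            s += r[i]
        db0 = s / n
        b0 += db0
        for i in range(n):
            r[i] -= db0
        max_db = _cd_sweep(X, r, beta, d, lam1, lam2)
        trace[n_trace] = _objective(r, u, beta, kappa, lam1, lam2, has_ranef)
        n_trace += 1
        if max_db < tol and max_du < tol and abs(db0) < tol:
            converged = True
            break

    if not has_ranef:
        s2_site = 0.0
        rss = 0.0
        for i in range(n):
            rss += r[i] * r[i]
        if update_var:
            s2_res = rss / n

    return beta, b0, u, s2_site, s2_res, trace[:n_trace], n_trace, n_iter, converged


@njit(cache=True)
def fit_path_kernel(
    X,
    y,
    gidx,
    gsize,
    lam1s,
    lam2s,
    tol,
    max_iter,
    s2_site0,
    s2_res0,
    update_var,
    var_tol,
    has_ranef,
):
    """Warm-started fits along a decreasing penalty path.

    Returns (B, b0s, U, s2_sites, s2_ress, conv) with one row per penalty.
    """
    n, p = X.shape
    q = gsize.shape[0]
    L = lam1s.shape[0]
    B = np.zeros((L, p))
    b0s = np.zeros(L)
    U = np.zeros((L, q))
    s2_sites = np.zeros(L)
    s2_ress = np.zeros(L)
    conv = np.zeros(L, dtype=np.bool_)

    beta = np.zeros(p)
    b0 = 0.0
    s2_site = s2_site0
    s2_res = s2_res0
    warm = False
    for k in range(L):
        beta, b0, u, s2_site, s2_res, _, _, _, ok = fit_kernel(
            X, y, gidx, gsize, lam1s[k], lam2s[k], tol, max_iter,
            s2_site, s2_res, update_var, var_tol, has_ranef,
            beta, b0, warm,
        )
        warm = True
        B[k] = beta
        b0s[k] = b0
        U[k] = u
        s2_sites[k] = s2_site
        s2_ress[k] = s2_res
        conv[k] = ok
        if s2_site < S2_SITE_FLOOR:
            s2_site = 1e-8  # keep EM restartable for the next penalty
    return B, b0s, U, s2_sites, s2_ress, conv
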