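"""Numba kernels for L1-penalized Cox partial-likelihood fitting.

All kernels expect rows sorted by ascending time, with ``first_idx``
giving the first sorted position tied with each row (see
``_survdata.risk_set_starts``), and use the Breslow convention for tied
event times. The penalized objective is

    l(beta) - lam * sum_j |beta_j|

with ``l`` the (unnormalized) Breslow log partial likelihood. It is
maximized by proximal Newton: an outer loop forms the exact quadratic
model of ``l`` (gradient and observed-information Hessian), an inner
cyclic coordinate descent solves the L1-penalized quadratic, and
step-halving keeps the true penalized objective non-decreasing across
outer iterations. A fixed point satisfies the exact KKT conditions of
the penalized partial likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Coefficients hitting this magnitude are flagged as divergent
#: (monotone likelihood); mirrors the unpenalized Newton cap.
BETA_CAP = 15.0


@njit(cache=True)
def breslow_loglik(eta, events, first_idx):
    """Breslow log partial likelihood at linear predictor ``eta``."""
    n = eta.shape[0]
    # shift for overflow safety; Breslow loglik is invariant to it only
    # through the event terms, so track the correction explicitly
    m = eta[0]
    for i in range(1, n):
        if eta[i] > m:
            m = eta[i]
    r = np.empty(n)
    for i in range(n):
        r[i] = np.exp(eta[i] - m)
    # reverse cumulative risk sums
    S = np.empty(n)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc += r[i]
        S[i] = acc
    ll = 0.0
    for i in range(n):
        if events[i] == 1.0:
            ll += (eta[i] - m) - np.log(S[first_idx[i]])
    return ll


@njit(cache=True)
def breslow_grad_weights(eta, events, first_idx):
    """Exact gradient and diagonal curvature of the Breslow log partial
    likelihood with respect to ``eta``.

    Returns ``(g, w)`` with ``g_i = d l / d eta_i`` and
    ``w_i = -d^2 l / d eta_i^2`` (diagonal term only).
    """
    n = eta.shape[0]
    m = eta[0]
    for i in range(1, n):
        if eta[i] > m:
            m = eta[i]
    r = np.empty(n)
    for i in range(n):
        r[i] = np.exp(eta[i] - m)
    S = np.empty(n)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc += r[i]
        S[i] = acc
    # cumulative hazard increments: for each event, 1/S and 1/S^2 applied
    # to all rows in its risk set (rows >= first_idx of the event)
    a1 = np.zeros(n)
    a2 = np.zeros(n)
    for i in range(n):
        if events[i] == 1.0:
            j = first_idx[i]
            a1[j] += 1.0 / S[j]
            a2[j] += 1.0 / (S[j] * S[j])
    c1 = 0.0
    c2 = 0.0
    g = np.empty(n)
    w = np.empty(n)
    for i in range(n):
        c1 += a1[i]
        c2 += a2[i]
        g[i] = events[i] - r[i] * c1
        w[i] = r[i] * c1 - r[i] * r[i] * c2
    return g, w


@njit(cache=True)
def score_at_zero(X, events, first_idx):
    """Score vector d l / d beta at beta = 0."""
    n, p = X.shape
    eta = np.zeros(n)
    g, _ = breslow_grad_weights(eta, events, first_idx)
    s = np.zeros(p)
    for i in range(n):
        for j in range(p):
            s[j] += g[i] * X[i, j]
    return s


@njit(cache=True)
def _penalized_objective(X, events, first_idx, beta, lam):
    n, p = X.shape
    eta = np.zeros(n)
    for i in range(n):
        for j in range(p):
            eta[i] += X[i, j] * beta[j]
    pen = 0.0
    for j in range(p):
        pen += abs(beta[j])
    return breslow_loglik(eta, events, first_idx) - lam * pen


@njit(cache=True)
def breslow_grad_hess(eta, X, events, first_idx):
    """Log-likelihood, gradient, and observed information (negative
    Hessian) of the Breslow partial likelihood with respect to beta."""
    n, p = X.shape
    m = eta[0]
    for i in range(1, n):
        if eta[i] > m:
            m = eta[i]
    r = np.empty(n)
    for i in range(n):
        r[i] = np.exp(eta[i] - m)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S = 0.0
    Sx = np.zeros(p)
    Sxx = np.zeros((p, p))
    # iterate sorted rows from latest to earliest, accumulating risk sums;
    # contributions are added at the first index of each tie group
    i = n - 1
    while i >= 0:
        j = first_idx[i]
        d = 0
        for k in range(j, i + 1):
            S += r[k]
            for a in range(p):
                Sx[a] += r[k] * X[k, a]
                for b in range(a, p):
                    Sxx[a, b] += r[k] * X[k, a] * X[k, b]
            if events[k] == 1.0:
                d += 1
                ll += eta[k] - m
                for a in range(p):
                    grad[a] += X[k, a]
        if d > 0:
            ll -= d * np.log(S)
            for a in range(p):
                grad[a] -= d * Sx[a] / S
                for b in range(a, p):
                    hess[a, b] += d * (Sxx[a, b] / S
                                       - Sx[a] * Sx[b] / (S * S))
        i = j - 1
    for a in range(p):
        for b in range(a + 1, p):
            hess[b, a] = hess[a, b]
    return ll, grad, hess


@njit(cache=True)
def lasso_fit(X, events, first_idx, lam, beta0, tol, max_sweeps):
    """Maximize the L1-penalized Breslow partial likelihood at one ``lam``.

    Proximal Newton: the inner coordinate descent solves the penalized
    exact quadratic model. Returns ``(beta, converged, sweeps_used)``;
    ``beta0`` is the warm start. Convergence: maximum absolute
    coefficient change below ``tol`` across a full outer iteration.
    """
    n, p = X.shape
    beta = beta0.copy()
    eta = np.zeros(n)
    for i in range(n):
        for j in range(p):
            eta[i] += X[i, j] * beta[j]
    pen = 0.0
    for j in range(p):
        pen += abs(beta[j])
    sweeps = 0
    converged = False
    obj = -np.inf
    for _outer in range(100):
        ll, grad, hess = breslow_grad_hess(eta, X, events, first_idx)
        if obj == -np.inf:
            obj = ll - lam * pen
        beta_old = beta.copy()
        # v = gradient of the negated quadratic model: H (beta - beta_old) - g
        v = -grad.copy()
        # cyclic coordinate descent on the penalized quadratic
        for _sweep in range(100):
            sweeps += 1
            maxstep = 0.0
            for j in range(p):
                bj = beta[j]
                hjj = hess[j, j]
                if hjj < 1e-12:
                    continue
                rho = hjj * bj - v[j]
                if rho > lam:
                    newb = (rho - lam) / hjj
                elif rho < -lam:
                    newb = (rho + lam) / hjj
                else:
                    newb = 0.0
                if newb > BETA_CAP:
                    newb = BETA_CAP
                elif newb < -BETA_CAP:
                    newb = -BETA_CAP
                step = newb - bj
                if step != 0.0:
                    for a in range(p):
                        v[a] += hess[a, j] * step
                    beta[j] = newb
                if abs(step) > maxstep:
                    maxstep = abs(step)
            if maxstep < 0.1 * tol or sweeps >= max_sweeps:
                break
        # step-halving against the true penalized objective
        scale = 1.0
        for _half in range(25):
            for i in range(n):
                acc = 0.0
                for j in range(p):
                    acc += X[i, j] * (beta_old[j]
                                      + scale * (beta[j] - beta_old[j]))
                eta[i] = acc
            pen = 0.0
            for j in range(p):
                pen += abs(beta_old[j] + scale * (beta[j] - beta_old[j]))
            new_obj = breslow_loglik(eta, events, first_idx) - lam * pen
            if new_obj >= obj - 1e-12:
                break
            scale *= 0.5
        if scale != 1.0:
            for j in range(p):
                beta[j] = beta_old[j] + scale * (beta[j] - beta_old[j])
        obj = new_obj
        delta = 0.0
        for j in range(p):
            d = abs(beta[j] - beta_old[j])
            if d > delta:
                delta = d
        if delta < tol:
            converged = True
            break
        if sweeps >= max_sweeps:
            break
    return beta, converged, sweeps


@njit(cache=True)
def lasso_path(X, events, first_idx, lams, tol, max_sweeps):
    """Warm-started coefficient path over a descending ``lams`` grid.

    Returns ``(betas, converged)`` with one row per grid point.
    """
    p = X.shape[1]
    k = lams.shape[0]
    betas = np.zeros((k, p))
    conv = np.zeros(k, dtype=np.bool_)
    beta = np.zeros(p)
    for idx in range(k):
        beta, ok, _ = lasso_fit(X, events, first_idx, lams[idx], beta, tol,
                                max_sweeps)
        betas[idx] = beta
        conv[idx] = ok
    return betas, conv
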