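"""Unpenalized Cox partial-likelihood: value, derivatives, Newton fitting.

Supports the Breslow and Efron conventions for tied event times; rows
must be pre-sorted by ascending time (see ``_survdata.sort_survival``).
"""

from __future__ import annotations

import numpy as np

BETA_CAP = 15.0


def loglik_derivs(beta, X, t, e, first_idx, ties="efron", order: int = 2):
    """Log partial likelihood and (optionally) gradient / information.

    ``order`` 0 returns only the log-likelihood, 1 adds the gradient,
    2 adds the observed information (negative Hessian).
    """
    n, p = X.shape
    eta = X @ beta
    shift = eta.max() if n else 0.0
    r = np.exp(eta - shift)
    want_grad = order >= 1
    want_info = order >= 2

    ll = 0.0
    grad = np.zeros(p) if want_grad else None
    info = np.zeros((p, p)) if want_info else None

    # group boundaries: rows first_idx[i]..next-1 share one event time
    starts = np.unique(first_idx)
    bounds = np.append(starts, n)

    S = 0.0
    Sx = np.zeros(p)
    Sxx = np.zeros((p, p)) if want_info else None
    for gi in range(len(starts) - 1, -1, -1):
        lo, hi = bounds[gi], bounds[gi + 1]
        rg = r[lo:hi]
        Xg = X[lo:hi]
        S += rg.sum()
        Sx += rg @ Xg
        if want_info:
            Sxx += (rg[:, None] * Xg).T @ Xg
        ev = e[lo:hi] == 1.0
        d = int(ev.sum())
        if d == 0:
            continue
        ll += float(eta[lo:hi][ev].sum() - d * shift)
        if want_grad:
            grad += Xg[ev].sum(axis=0)
        if ties == "breslow" or d == 1:
            denoms = np.full(d, S)
            sB = np.zeros(p)
            sC = np.zeros((p, p)) if want_info else None
            fracs = np.zeros(d)
        elif ties == "efron":
            re_ = rg[ev]
            Xe = Xg[ev]
            s_r = re_.sum()
            s_rx = re_ @ Xe
            fracs = np.arange(d) / d
            denoms = S - fracs * s_r
            sB = s_rx
            sC = (re_[:, None] * Xe).T @ Xe if want_info else None
        else:
            raise ValueError(f"unknown ties convention {ties!r}")
        for l in range(d):
            A = denoms[l]
            ll -= float(np.log(A))
            if want_grad:
                B = Sx - fracs[l] * sB
                grad -= B / A
            if want_info:
                C = Sxx - fracs[l] * sC
                BA = B / A
                info += C / A - np.outer(BA, BA)
    if order == 0:
        return ll
    if order == 1:
        return ll, grad
    return ll, grad, info


def newton_fit(X, t, e, first_idx, ties="efron", tol=1e-9, max_iter=50):
    """Newton-Raphson maximization with step-halving line search.

    Returns ``(beta, se, loglik, converged, diverged, info)`` where
    ``diverged`` flags coefficients pinned at the +-15 cap (monotone
    likelihood) and ``info`` is the observed information at the optimum.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, info = loglik_derivs(beta, X, t, e, first_idx, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix") from exc
        scale = 1.0
        for _half in range(40):
            cand = np.clip(beta + scale * step, -BETA_CAP, BETA_CAP)
            ll_new = loglik_derivs(cand, X, t, e, first_idx, ties, order=0)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        beta = cand
        improved = ll_new - ll
        ll, grad, info = loglik_derivs(beta, X, t, e, first_idx, ties)
        if abs(improved) < tol:
            converged = True
            break
    diverged = np.abs(beta) >= BETA_CAP - 1e-10
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        if not diverged.any():
            raise ValueError("singular information matrix at optimum")
        se = np.full(p, np.nan)
    return beta, se, ll, converged, diverged, info
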