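"""Breslow partial-likelihood primitives shared across the package.

All survival code in this package works on right-censored data given as a
pair of aligned arrays ``time`` (strictly positive event/censoring times) and
``event`` (1 = event observed, 0 = censored).  Ties in event times are handled
with the Breslow approximation throughout: every subject with ``t_j >= t_i``
is in the risk set of an event at ``t_i``, and tied events share one
log-denominator.
"""

from __future__ import annotations

import numpy as np


def _check_surv(risk, time, event):
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if risk.shape != time.shape or time.shape != event.shape:
        raise ValueError("risk, time and event must be aligned 1-d arrays")
    if event.sum() < 1:
        raise ValueError("partial likelihood undefined with zero events")
    if not np.all(np.isfinite(risk)):
        raise ValueError("non-finite risk scores")
    return risk, time, event


def _suffix_logcumsum(w: np.ndarray) -> np.ndarray:
    """suffix cumulative sum: out[k] = sum(w[k:])."""
    return np.cumsum(w[::-1])[::-1]


def breslow_nll_grad(risk, time, event, strata=None, with_grad=True):
    """Negative Breslow log partial likelihood and its gradient w.r.t. risk.

    Returns ``nll`` or ``(nll, grad)``; both are sums over events (not means),
    so the loss is invariant to adding a constant to every risk score.
    """
    risk, time, event = _check_surv(risk, time, event)
    n = risk.size
    if strata is None:
        groups = [np.arange(n)]
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]

    nll = 0.0
    grad = np.zeros(n) if with_grad else None
    for idx in groups:
        r, t, e = risk[idx], time[idx], event[idx]
        if e.sum() == 0:
            continue  # stratum contributes no event terms
        order = np.argsort(t, kind="stable")
        r, t, e = r[order], t[order], e[order]
        c = r.max()
        w = np.exp(r - c)
        s_suffix = _suffix_logcumsum(w)  # s_suffix[k] = sum_{j>=k} exp(r_j - c)
        # first index of each tied-time block
        first = np.zeros(t.size, dtype=int)
        same = np.flatnonzero(t[1:] == t[:-1]) + 1
        for k in same:  # small loop over tie runs only
            first[k] = first[k - 1]
        other = np.setdiff1d(np.arange(t.size), same, assume_unique=True)
        first[other] = other
        ev = np.flatnonzero(e == 1)
        f_ev = first[ev]
        nll += -(np.sum(r[ev]) - np.sum(np.log(s_suffix[f_ev]) + c))
        if with_grad:
            # A[k] = sum over events i with first-tie-index <= k of 1/S_i
            inv = np.zeros(t.size)
            np.add.at(inv, f_ev, 1.0 / s_suffix[f_ev])
            a = np.cumsum(inv)
            g = -e + w * a
            gfull = np.empty(t.size)
            gfull[order] = g
            grad[idx] = gfull
    return (nll, grad) if with_grad else nll


def cox_objective(beta, X, time, event, strata=None, offset=None,
                  with_hessian=False):
    """Breslow negative log partial likelihood of a linear model.

    Parameters are the coefficients ``beta``; risk = X @ beta (+ offset).
    Returns (nll, grad) or (nll, grad, hessian).
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    risk = X @ beta
    if offset is not None:
        risk = risk + offset
    nll, grad_r = breslow_nll_grad(risk, time, event, strata=strata)
    grad = X.T @ grad_r
    if not with_hessian:
        return nll, grad

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if strata is None:
        groups = [np.arange(n)]
    else:
        sarr = np.asarray(strata)
        groups = [np.flatnonzero(sarr == s) for s in np.unique(sarr)]
    H = np.zeros((p, p))
    for idx in groups:
        r, t, e, x = risk[idx], time[idx], event[idx], X[idx]
        if e.sum() == 0:
            continue
        order = np.argsort(t, kind="stable")
        r, t, e, x = r[order], t[order], e[order], x[order]
        c = r.max()
        w = np.exp(r - c)
        s0 = _suffix_logcumsum(w)
        s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]        # (n, p)
        xx = np.einsum("ij,ik->ijk", x, x)                          # (n, p, p)
        s2 = np.cumsum((w[:, None, None] * xx)[::-1], axis=0)[::-1]  # (n, p, p)
        first = np.zeros(t.size, dtype=int)
        same = np.flatnonzero(t[1:] == t[:-1]) + 1
        for k in same:
            first[k] = first[k - 1]
        other = np.setdiff1d(np.arange(t.size), same, assume_unique=True)
        first[other] = other
        f_ev = first[np.flatnonzero(e == 1)]
        pos, counts = np.unique(f_ev, return_counts=True)
        mu = s1[pos] / s0[pos, None]                                 # (m, p)
        e2 = s2[pos] / s0[pos, None, None]                           # (m, p, p)
        cov = e2 - np.einsum("ij,ik->ijk", mu, mu)
        H += np.einsum("m,mjk->jk", counts.astype(float), cov)
    return nll, grad, H


def newton_cox(X, time, event, strata=None, offset=None, tol=1e-9,
               max_iter=100, ridge=0.0):
    """Newton–Raphson maximizer of the Breslow partial likelihood.

    ``ridge`` adds a tiny quadratic penalty only as a numerical safeguard for
    near-separated designs; it defaults to 0 (plain maximum partial
    likelihood).  Returns (beta, covariance, nll, n_iter, converged).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    nll_prev = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        nll, grad, H = cox_objective(beta, X, time, event, strata=strata,
                                     offset=offset, with_hessian=True)
        if ridge:
            nll += 0.5 * ridge * beta @ beta
            grad = grad + ridge * beta
            H = H + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # halve the step until the objective does not increase
        shrink = 1.0
        for _ in range(30):
            cand = beta - shrink * step
            nll_new = cox_objective(cand, X, time, event, strata=strata,
                                    offset=offset)[0]
            if ridge:
                nll_new += 0.5 * ridge * cand @ cand
            if nll_new <= nll + 1e-12:
                break
            shrink *= 0.5
        beta = beta - shrink * step
        if np.max(np.abs(shrink * step)) < tol or abs(nll_prev - nll) < tol:
            converged = True
            break
        nll_prev = nll
    nll, grad, H = cox_objective(beta, X, time, event, strata=strata,
                                 offset=offset, with_hessian=True)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return beta, cov, nll, it, converged
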