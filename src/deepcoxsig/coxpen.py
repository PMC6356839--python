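"""Penalized Cox regression comparators: ridge, adaptive lasso, elastic net.

Fits maximize the Breslow partial log-likelihood minus a penalty

* ridge:          lambda * sum beta_j^2
* adaptive lasso: lambda * sum w_j |beta_j|,  w_j = 1 / |beta_j0| from ridge
* elastic net:    lambda * sum (alpha |beta_j| + (1 - alpha) beta_j^2 / 2)

by proximal gradient descent with backtracking line search: the l1 part is
handled exactly by soft-thresholding, the smooth part (partial likelihood +
quadratic penalty terms) by its analytic gradient.  The penalty level is
chosen by k-fold cross-validated partial-likelihood deviance in the
Verweij–van Houwelingen full-minus-training form, taking the
deviance-minimizing lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coxcore import cox_objective
from .genefilter import stratified_partition

__all__ = [
    "PenaltySpec",
    "CoxPenFit",
    "LambdaPath",
    "fit_penalized_cox",
    "adaptive_weights",
    "default_lambda_grid",
    "cv_lambda_path",
    "rank_by_coefficient",
    "kkt_violation",
]

KINDS = ("ridge", "adaptive_lasso", "elastic_net")


@dataclass(frozen=True)
class PenaltySpec:
    kind: str
    alpha: float = 0.5  # elastic-net mixing
    weights: np.ndarray | None = None  # adaptive-lasso weights, default 1

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w <= 0):
                raise ValueError("adaptive-lasso weights must be positive")
            object.__setattr__(self, "weights", w)

    def l1_scale(self, p: int) -> np.ndarray:
        """Per-feature multiplier of lambda inside the l1 term."""
        if self.kind == "ridge":
            return np.zeros(p)
        if self.kind == "adaptive_lasso":
            w = np.ones(p) if self.weights is None else self.weights
            if w.size != p:
                raise ValueError("weights length must match n_features")
            return w
        return np.full(p, self.alpha)  # elastic net

    def l2_scale(self) -> float:
        """Multiplier of lambda in the quadratic term lam*c2*beta^2."""
        if self.kind == "ridge":
            return 1.0
        if self.kind == "elastic_net":
            return (1.0 - self.alpha) / 2.0
        return 0.0


@dataclass
class CoxPenFit:
    beta: pd.Series
    lam: float
    penalty: PenaltySpec
    converged: bool
    n_iter: int
    objective: float = np.nan


@dataclass
class LambdaPath:
    lambda_grid: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    n_folds_used: int = 0
    fits: dict = field(default_factory=dict)


def _penalized_parts(penalty: PenaltySpec, lam: float, p: int):
    c1 = lam * penalty.l1_scale(p)  # soft-threshold levels
    c2 = lam * penalty.l2_scale()  # quadratic coefficient: c2 * sum beta^2...
    return c1, c2


def penalized_objective(beta, X, time, event, penalty: PenaltySpec, lam: float):
    """Full objective value: NLL + lam * penalty (used by fits and oracles)."""
    beta = np.asarray(beta, dtype=float)
    nll = cox_objective(beta, X, time, event)[0]
    c1, c2 = _penalized_parts(penalty, lam, beta.size)
    return nll + float(c1 @ np.abs(beta)) + c2 * float(beta @ beta)


def fit_penalized_cox(X, surv: pd.DataFrame, penalty: PenaltySpec, lam: float,
                      beta0=None, tol: float = 1e-6, max_iter: int = 10000
                      ) -> CoxPenFit:
    """Proximal-gradient fit of a penalized Cox model at one lambda."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(X, pd.DataFrame):
        features = list(X.columns)
        Xa = X.loc[surv.index].to_numpy(float)
    else:
        Xa = np.asarray(X, dtype=float)
        features = [f"x{j}" for j in range(Xa.shape[1])]
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    if event.sum() < 1:
        raise ValueError("undefined likelihood: zero events")
    n, p = Xa.shape
    c1, c2 = _penalized_parts(penalty, lam, p)

    def smooth(beta):
        nll, grad = cox_objective(beta, Xa, time, event)
        return nll + c2 * beta @ beta, grad + 2.0 * c2 * beta

    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    f, g = smooth(beta)
    t = 1.0 / max(n, 1)
    converged = False
    for it in range(1, max_iter + 1):
        t *= 1.5  # optimistic step growth, then backtrack
        while True:
            cand = np.sign(beta - t * g) * np.maximum(
                np.abs(beta - t * g) - t * c1, 0.0)
            step = cand - beta
            f_cand = smooth(cand)[0]
            if f_cand <= f + g @ step + (step @ step) / (2 * t) + 1e-12:
                break
            t *= 0.5
            if t < 1e-16:
                break
        delta = np.max(np.abs(cand - beta))
        beta = cand
        f, g = smooth(beta)
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"fit error risk: proximal gradient hit max_iter="
                      f"{max_iter} (last step {delta:.2e})")
    obj = f + float(c1 @ np.abs(beta))
    return CoxPenFit(beta=pd.Series(beta, index=features, name="beta"),
                     lam=float(lam), penalty=penalty, converged=converged,
                     n_iter=it, objective=float(obj))


def adaptive_weights(ridge_fit: CoxPenFit, cap: float = 1e8) -> np.ndarray:
    """Adaptive-lasso weights w_j = 1/|beta_j0| from an initial ridge fit."""
    if not ridge_fit.converged:
        raise ValueError("ridge fit did not converge")
    b = np.abs(ridge_fit.beta.to_numpy())
    with np.errstate(divide="ignore"):
        w = np.where(b < 1e-8, cap, 1.0 / np.maximum(b, 1e-300))
    return np.minimum(w, cap)


def default_lambda_grid(X, surv: pd.DataFrame, penalty: PenaltySpec,
                        n_points: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced descending grid from the all-zero-solution lambda down."""
    Xa = X.loc[surv.index].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    _, grad0 = cox_objective(np.zeros(Xa.shape[1]), Xa, time, event)
    c1 = penalty.l1_scale(Xa.shape[1])
    if np.all(c1 == 0):  # ridge: no finite all-zero threshold; use |grad| scale
        lam_max = np.max(np.abs(grad0))
    else:
        nz = c1 > 0
        lam_max = np.max(np.abs(grad0[nz]) / c1[nz])
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n_points)


def cv_lambda_path(X, surv: pd.DataFrame, penalty: PenaltySpec,
                   n_folds: int = 9, lambda_grid=None, seed: int = 0
                   ) -> LambdaPath:
    """Cross-validated partial-likelihood deviance over a lambda grid.

    Folds preserve the survival-time distribution (rank-block dealing).  The
    deviance of a fold is the Verweij–van Houwelingen cross-validated form
    -2 * (loglik_all(beta_fold) - loglik_train(beta_fold)).  Returns the
    deviance-minimizing lambda.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, surv, penalty)
    lambda_grid = np.asarray(sorted(np.atleast_1d(lambda_grid),
                                    reverse=True), dtype=float)
    folds = stratified_partition(surv, k=n_folds, seed=seed)
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
        np.asarray(X, float), index=surv.index)
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    Xall = Xdf.loc[surv.index].to_numpy(float)

    devs = np.full((len(lambda_grid), n_folds), np.nan)
    used = 0
    for f in range(n_folds):
        train_ids = folds.index[folds != f]
        surv_tr = surv.loc[train_ids]
        if surv_tr["event"].sum() < 1 or surv.loc[folds.index[folds == f],
                                                  "event"].sum() < 1:
            warnings.warn(f"fold {f} skipped: no events")
            continue
        used += 1
        Xtr = Xdf.loc[train_ids]
        ttr = surv_tr["time"].to_numpy(float)
        etr = surv_tr["event"].to_numpy(int)
        beta_prev = None
        for li, lam in enumerate(lambda_grid):  # warm start down the path
            fit = fit_penalized_cox(Xtr, surv_tr, penalty, lam, beta0=beta_prev)
            beta_prev = fit.beta.to_numpy()
            ll_all = -cox_objective(beta_prev, Xall, time, event)[0]
            ll_tr = -cox_objective(beta_prev, Xtr.to_numpy(float), ttr, etr)[0]
            devs[li, f] = -2.0 * (ll_all - ll_tr)
    if used == 0:
        raise ValueError("all folds skipped: no usable events")
    cv_mean = np.nanmean(devs, axis=1)
    cv_se = np.nanstd(devs, axis=1, ddof=1) / np.sqrt(used)
    lam_min = float(lambda_grid[int(np.nanargmin(cv_mean))])
    return LambdaPath(lambda_grid=lambda_grid, cv_mean=cv_mean, cv_se=cv_se,
                      lambda_min=lam_min, n_folds_used=used)


def rank_by_coefficient(fit: CoxPenFit) -> list[str]:
    """Features by decreasing |beta|, ties broken lexicographically."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    b = fit.beta.abs()
    if np.all(b.to_numpy() == 0):
        warnings.warn("degenerate ranking: all coefficients are zero")
    return sorted(b.index, key=lambda name: (-b[name], name))


def kkt_violation(fit: CoxPenFit, X, surv: pd.DataFrame) -> float:
    """Maximum first-order (subgradient) optimality violation of a fit."""
    Xa = X.loc[surv.index].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    beta = fit.beta.to_numpy()
    c1, c2 = _penalized_parts(fit.penalty, fit.lam, beta.size)
    _, grad = cox_objective(beta, Xa, time, event)
    grad = grad + 2.0 * c2 * beta
    viol = np.where(
        beta == 0.0,
        np.maximum(np.abs(grad) - c1, 0.0),
        np.abs(grad + c1 * np.sign(beta)),
    )
    return float(viol.max())
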