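"""Gene filtering and survival-time-stratified partitioning.

The pre-modelling reduction applied to the expression matrix before any
survival model sees it:

* per-gene Welch two-sample t-test of tumor vs normal log2 expression,
* a beta-uniform mixture (BUM) model of the resulting p-value histogram,
  giving an estimated false-discovery rate at the selection threshold,
* selection at p < 0.01 with at least a 2-fold change (|log2 FC| >= 1),
* greedy correlation pruning so no two retained genes have |r| > 0.8,
* k-way sample partitioning that preserves the survival-time distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "DiffExprResult",
    "BumFit",
    "diff_expression",
    "fit_bum",
    "bum_fdr",
    "select_de_genes",
    "correlation_prune",
    "stratified_partition",
]


@dataclass
class BumFit:
    """Beta-uniform mixture fit: f(p) = lambda + (1-lambda) * a * p^(a-1)."""

    lambda_mix: float
    a_shape: float
    loglik: float

    def density(self, p):
        p = np.asarray(p, dtype=float)
        return self.lambda_mix + (1 - self.lambda_mix) * self.a_shape * p ** (self.a_shape - 1)


DiffExprResult = pd.DataFrame  # columns: log2_fold_change, t_statistic, p_value


def diff_expression(tumor: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs normal log2 expression.

    Returns a DataFrame indexed by gene id with ``log2_fold_change``
    (mean tumor minus mean normal), ``t_statistic`` and two-sided
    ``p_value``.  Genes with identical group means and zero variance are
    reported as t = 0, p = 1.
    """
    if not tumor.index.equals(normal.index):
        raise ValueError("alignment error: tumor and normal gene ids differ")
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("insufficient data: need >= 2 samples per group")
    a, b = tumor.to_numpy(float), normal.to_numpy(float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf), t)
    p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    return pd.DataFrame(
        {"log2_fold_change": lfc, "t_statistic": t, "p_value": p},
        index=tumor.index,
    )


def _bum_negloglik(theta, p):
    lam, a = theta
    f = lam + (1 - lam) * a * np.power(p, a - 1)
    return -np.sum(np.log(np.maximum(f, 1e-300)))


def fit_bum(p_values, min_n: int = 100) -> BumFit:
    """Maximum-likelihood beta-uniform mixture fit to a p-value sample.

    Maximizes sum log(lambda + (1-lambda)*a*p^(a-1)) over lambda in [0,1],
    a in (0,1) by bounded L-BFGS-B from a small deterministic multistart.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < min_n:
        raise ValueError(f"insufficient data: need >= {min_n} p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("domain error: p-values must lie in (0, 1]")
    bounds = [(1e-6, 1.0), (1e-6, 1.0 - 1e-6)]
    best = None
    for lam0 in (0.3, 0.6, 0.9):
        for a0 in (0.2, 0.5, 0.8):
            res = minimize(_bum_negloglik, x0=[lam0, a0], args=(p,),
                           method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("fit error: BUM optimizer did not converge")
    lam, a = best.x
    return BumFit(lambda_mix=float(lam), a_shape=float(a), loglik=float(-best.fun))


def bum_fdr(fit: BumFit, tau: float) -> float:
    """Upper-bound FDR estimate among p <= tau under the fitted mixture.

    Uses the conservative null fraction pi_ub = lambda + (1-lambda)*a and the
    mixture CDF F(tau) = lambda*tau + (1-lambda)*tau^a; the ratio
    pi_ub*tau / F(tau) is capped into [0, 1].
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("domain error: tau must be in (0, 1)")
    pi_ub = fit.lambda_mix + (1 - fit.lambda_mix) * fit.a_shape
    f_tau = fit.lambda_mix * tau + (1 - fit.lambda_mix) * tau ** fit.a_shape
    return float(np.clip(pi_ub * tau / f_tau, 0.0, 1.0))


def select_de_genes(de: pd.DataFrame, p_max: float = 0.01,
                    min_abs_log2fc: float = 1.0) -> list[str]:
    """Genes passing both arms: p < p_max and |log2 FC| >= min_abs_log2fc."""
    if p_max <= 0 or min_abs_log2fc < 0:
        raise ValueError("thresholds must be positive")
    keep = (de["p_value"] < p_max) & (de["log2_fold_change"].abs() >= min_abs_log2fc)
    return list(de.index[keep])


def correlation_prune(expr: pd.DataFrame, r_max: float = 0.8) -> list[str]:
    """Collapse groups of inter-correlated genes to one representative each.

    Genes with pairwise |Pearson r| > ``r_max`` are grouped by single
    linkage (connected components of the thresholded correlation graph);
    each group is represented by its highest-variance member, ties broken by
    lexicographically smallest gene id.  A constant gene correlates with
    nothing (r treated as 0) and is always retained.
    """
    if expr.shape[1] < 2:
        raise ValueError("insufficient data: need >= 2 samples")
    x = expr.to_numpy(float)
    var = x.var(axis=1, ddof=1)
    sd = np.sqrt(var)
    ok = sd > 0
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.where(ok, sd, 1.0)
    xs = xc / denom[:, None]
    r = (xs @ xs.T) / (x.shape[1] - 1)
    r[~ok, :] = 0.0
    r[:, ~ok] = 0.0
    np.fill_diagonal(r, 1.0)
    adj = csr_matrix(np.abs(r) > r_max)
    n_comp, labels = connected_components(adj, directed=False)
    genes = np.asarray(expr.index)
    keep = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        best_var = var[members].max()
        cands = members[var[members] == best_var]
        keep.append(min(genes[cands]))
    # report in input gene order
    keep_set = set(keep)
    return [g for g in genes if g in keep_set]


def stratified_partition(surv: pd.DataFrame, k: int = 10,
                         seed: int = 0) -> pd.Series:
    """Deal samples into k partitions preserving the survival-time spread.

    Samples are ranked by survival time; each consecutive block of k ranks
    contributes one sample to every partition, with the within-block
    assignment order randomized.  Partition sizes differ by at most 1.
    Returns a Series of partition indices in [0, k) indexed by sample id.
    """
    n = len(surv)
    if k > n:
        raise ValueError("configuration error: k exceeds number of samples")
    rng = np.random.default_rng(seed)
    order = surv.sort_values(["time"], kind="stable").index.to_numpy()
    assign = np.empty(n, dtype=int)
    pos = 0
    while pos < n:
        block = order[pos:pos + k]
        parts = rng.permutation(k)[: len(block)]
        assign[pos:pos + len(block)] = parts
        pos += k
    return pd.Series(assign, index=pd.Index(order, name="sample_id"),
                     name="partition").loc[surv.index]
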