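"""Classical survival statistics: Cox PH fitting, PH diagnostics,
concordance, prognostic index, Kaplan–Meier curves and the log-rank test.

The Cox fitter is a Newton–Raphson maximizer of the Breslow partial
likelihood (with optional stratification), so tie handling is identical to
the network loss and the penalized comparators elsewhere in the package.
Kaplan–Meier estimation and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._coxcore import breslow_nll_grad, cox_objective, newton_cox

__all__ = [
    "CoxModelResult",
    "LogRankResult",
    "fit_cox_ph",
    "ph_assumption_test",
    "concordance_index",
    "prognostic_index",
    "median_split",
    "km_curve",
    "logrank_test",
    "augment_baseline_model",
]


@dataclass
class CoxModelResult:
    summary: pd.DataFrame  # beta, hazard_ratio, ci95_low, ci95_high, se, wald_p
    concordance: float
    overall_lr_p: float
    loglik: float
    covariance: np.ndarray
    strata: pd.Series | None = None
    n: int = 0
    n_events: int = 0
    n_iter: int = 0
    converged: bool = True
    condition_number: float = field(default=np.nan)

    @property
    def beta(self) -> pd.Series:
        return self.summary["beta"]

    @property
    def terms(self) -> list[str]:
        return list(self.summary.index)


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def _as_surv_arrays(surv: pd.DataFrame):
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")
    return time, event


def fit_cox_ph(covariates: pd.DataFrame, surv: pd.DataFrame,
               strata: pd.Series | None = None) -> CoxModelResult:
    """Cox proportional-hazards fit (Breslow ties, optional stratification).

    ``covariates`` is a numeric sample x term DataFrame aligned with
    ``surv`` (columns ``time``, ``event``).  Wald p-values come from the
    inverse observed information; the overall model p is the likelihood-ratio
    test against the null model; concordance is Harrell's C of the fitted
    linear predictor.
    """
    if not covariates.index.equals(surv.index):
        covariates = covariates.loc[surv.index]
    X = covariates.to_numpy(float)
    time, event = _as_surv_arrays(surv)
    const = covariates.columns[X.std(axis=0) == 0]
    if len(const):
        raise ValueError(f"degeneracy error: constant covariate {const[0]!r}")
    strata_arr = None
    if strata is not None:
        strata_arr = np.asarray(strata.loc[surv.index])
        for s in np.unique(strata_arr):
            if event[strata_arr == s].sum() < 1:
                raise ValueError(f"stratum {s!r} has no events")
    elif event.sum() < 1:
        raise ValueError("undefined likelihood: zero events")

    beta, cov, nll, n_iter, converged = newton_cox(X, time, event,
                                                   strata=strata_arr)
    if not converged or not np.all(np.isfinite(beta)):
        raise RuntimeError(f"fit error: Cox fit did not converge in {n_iter} "
                           "iterations (possible separation)")
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald_p = 2 * stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "beta": beta,
            "hazard_ratio": np.exp(beta),
            "ci95_low": np.exp(beta - 1.959963984540054 * se),
            "ci95_high": np.exp(beta + 1.959963984540054 * se),
            "se": se,
            "wald_p": wald_p,
        },
        index=covariates.columns,
    )
    risk = X @ beta
    nll0 = breslow_nll_grad(np.zeros_like(risk), time, event,
                            strata=strata_arr, with_grad=False)
    lr_stat = 2.0 * (nll0 - nll)
    overall_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=X.shape[1]))
    xs = (X - X.mean(axis=0)) / X.std(axis=0)
    cond = float(np.linalg.cond(xs.T @ xs / len(X)))
    return CoxModelResult(
        summary=summary,
        concordance=concordance_index(risk, surv),
        overall_lr_p=overall_p,
        loglik=-nll,
        covariance=cov,
        strata=None if strata is None else pd.Series(strata_arr, index=surv.index),
        n=len(surv),
        n_events=int(event.sum()),
        n_iter=n_iter,
        converged=converged,
        condition_number=cond,
    )


def ph_assumption_test(fit: CoxModelResult, covariates: pd.DataFrame,
                       surv: pd.DataFrame) -> pd.Series:
    """Grambsch–Therneau proportional-hazards test, per covariate.

    Correlates scaled Schoenfeld residuals with the rank of the event time;
    returns a Series of chi-square(1) p-values indexed by term.  Requires at
    least 3 events.
    """
    if not covariates.index.equals(surv.index):
        covariates = covariates.loc[surv.index]
    X = covariates.to_numpy(float)
    time, event = _as_surv_arrays(surv)
    d = int(event.sum())
    if d < 3:
        raise ValueError("insufficient data: need >= 3 events for PH test")
    beta = fit.beta.to_numpy()
    strata_arr = None if fit.strata is None else fit.strata.to_numpy()
    _, _, info = cox_objective(beta, X, time, event, strata=strata_arr,
                               with_hessian=True)
    info_inv = np.linalg.inv(info)

    # Schoenfeld residuals at each event: x_i - weighted mean over risk set
    risk = X @ beta
    resid = []
    g = []  # event-time ranks (Breslow: ties share a rank)
    groups = ([np.arange(len(surv))] if strata_arr is None else
              [np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)])
    for idx in groups:
        t, e, r, x = time[idx], event[idx], risk[idx], X[idx]
        order = np.argsort(t, kind="stable")
        t, e, r, x = t[order], e[order], r[order], x[order]
        w = np.exp(r - r.max())
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
        first = np.zeros(t.size, dtype=int)
        for k in range(1, t.size):
            first[k] = first[k - 1] if t[k] == t[k - 1] else k
        for k in np.flatnonzero(e == 1):
            f = first[k]
            resid.append(x[k] - s1[f] / s0[f])
            g.append(t[k])
    resid = np.asarray(resid)
    g = stats.rankdata(np.asarray(g))
    gc = g - g.mean()
    scaled = d * resid @ info_inv.T  # scaled Schoenfeld residuals
    num = gc @ scaled
    denom = d * np.diag(info_inv) * np.sum(gc ** 2)
    chi2 = num ** 2 / denom
    return pd.Series(stats.chi2.sf(chi2, df=1), index=fit.terms, name="ph_p")


def concordance_index(risk, surv: pd.DataFrame) -> float:
    """Harrell's concordance index of a risk score against survival.

    A pair is usable when the shorter observed time belongs to a subject with
    an event; the pair is concordant when that subject also has the higher
    risk; ties in risk count 1/2.  Pairs with exactly tied observed times are
    not compared.
    """
    r = np.asarray(risk, dtype=float)
    time, event = _as_surv_arrays(surv)
    # usable[i, j]: t_i < t_j and event_i
    usable = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("undefined concordance: no comparable pairs")
    higher = (r[:, None] > r[None, :]) & usable
    tied = (r[:, None] == r[None, :]) & usable
    return float((higher.sum() + 0.5 * tied.sum()) / n_usable)


def prognostic_index(fit: CoxModelResult, covariates: pd.DataFrame) -> pd.Series:
    """Linear predictor x'beta of a fitted Cox model (no baseline term)."""
    missing = [t for t in fit.terms if t not in covariates.columns]
    if missing:
        raise ValueError(f"alignment error: missing terms {missing}")
    X = covariates[fit.terms].to_numpy(float)
    return pd.Series(X @ fit.beta.to_numpy(), index=covariates.index,
                     name="prognostic_index")


def median_split(pi: pd.Series) -> pd.Series:
    """Label samples low_risk / high_risk at the median prognostic index.

    Values strictly above the median are high risk; values at the median go
    to the low-risk group (fixed convention).
    """
    if len(pi) < 2:
        raise ValueError("need >= 2 samples to split")
    med = float(np.median(pi))
    if np.all(pi == pi.iloc[0]):
        raise ValueError("degenerate split: all prognostic indices identical")
    return pd.Series(np.where(pi > med, "high_risk", "low_risk"),
                     index=pi.index, name="risk_group")


def km_curve(surv: pd.DataFrame) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve.

    Returns a DataFrame with one row per distinct event time: ``time``,
    ``survival`` (fraction surviving just after that time) and ``n_at_risk``
    (subjects at risk just before it).  Censored times shrink later risk sets
    without producing a drop.
    """
    time, event = _as_surv_arrays(surv)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table.iloc[1:] if 0.0 not in time else kmf.event_table
    table = table[table["observed"] > 0]
    surv_vals = [float(kmf.predict(t)) for t in table.index]
    return pd.DataFrame({
        "time": np.asarray(table.index, dtype=float),
        "survival": surv_vals,
        "n_at_risk": table["at_risk"].to_numpy(int),
    }).reset_index(drop=True)


def logrank_test(surv: pd.DataFrame, groups: pd.Series) -> LogRankResult:
    """Log-rank test of survival differences between >= 2 groups."""
    g = groups.loc[surv.index]
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("configuration error: need >= 2 groups")
    time, event = _as_surv_arrays(surv)
    if event.sum() < 1:
        raise ValueError("log-rank test undefined with zero events")
    res = multivariate_logrank_test(time, g.to_numpy(), event)
    return LogRankResult(chi_square=float(res.test_statistic),
                         df=len(labels) - 1,
                         p_value=float(res.p_value))


def _clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix from the clinical covariate table.

    Categorical therapy/subtype become treatment dummies against the
    reference levels 'none' and 'other'; everything else passes through.
    """
    out = {}
    for col in clinical.columns:
        if col in ("therapy", "subtype"):
            ref = "none" if col == "therapy" else "other"
            for level in sorted(clinical[col].unique()):
                if level == ref:
                    continue
                out[f"{col}_{level}"] = (clinical[col] == level).astype(float)
        else:
            out[col] = clinical[col].astype(float)
    return pd.DataFrame(out, index=clinical.index)


def augment_baseline_model(clinical: pd.DataFrame, node_outputs: pd.DataFrame,
                           surv: pd.DataFrame,
                           dichotomize: dict[str, float] | None = None,
                           stratify_on: str | None = None):
    """Fit the clinical-only Cox model and the node-augmented model.

    ``node_outputs`` holds last-hidden-layer activations (samples x nodes).
    ``dichotomize`` maps a node column to a threshold: the column is replaced
    by the indicator value >= threshold; ``stratify_on`` names one such node
    column to use as a stratification variable instead of a covariate (the
    device used when a node violates proportional hazards).  Returns
    ``(baseline_fit, augmented_fit)``; a high condition number of the
    augmented design triggers a collinearity warning.
    """
    design = _clinical_design(clinical).loc[surv.index]
    const = design.columns[design.std(axis=0) == 0]
    if len(const):
        warnings.warn(f"dropping constant clinical terms: {list(const)}")
        design = design.drop(columns=const)
    baseline = fit_cox_ph(design, surv)

    nodes = node_outputs.loc[surv.index].copy()
    if dichotomize:
        for col, thr in dichotomize.items():
            nodes[col] = (nodes[col] >= thr).astype(float)
    strata = None
    if stratify_on is not None:
        strata = nodes[stratify_on].astype(int)
        nodes = nodes.drop(columns=[stratify_on])
    aug_design = pd.concat([design, nodes], axis=1)
    xs = aug_design.to_numpy(float)
    sd = xs.std(axis=0)
    xs = (xs - xs.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    cond = float(np.linalg.cond(xs.T @ xs / len(xs)))
    if cond > 1e3:
        warnings.warn(f"augmented design is ill-conditioned (condition number "
                      f"{cond:.3g}); collinear covariates likely")
    augmented = fit_cox_ph(aug_design, surv, strata=strata)
    augmented.condition_number = cond
    return baseline, augmented
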