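"""Cox PH fitting, PH diagnostics, concordance, KM and log-rank."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from deepcoxsig import survstats as ss
from deepcoxsig._coxcore import cox_objective
from deepcoxsig.synthcohort import SyntheticConfig, generate_cohort

from conftest import make_surv


def _sim_cox(beta, n, seed, censor_rate=0.1):
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, float)
    X = rng.normal(size=(n, beta.size))
    t = rng.exponential(np.exp(-X @ beta)) + 1e-4
    c = rng.exponential(np.quantile(t, 1 - censor_rate) * 3, size=n)
    surv = make_surv(np.minimum(t, c), (t <= c).astype(int))
    cov = pd.DataFrame(X, index=surv.index,
                       columns=[f"x{j}" for j in range(beta.size)])
    return cov, surv


class TestFitCoxPH:
    def test_mirrored_groups_give_null_effect(self):
        times = np.array([1.0, 2, 3, 4, 5, 6])
        surv = make_surv(np.concatenate([times, times]), np.ones(12))
        cov = pd.DataFrame({"grp": [0.0] * 6 + [1.0] * 6}, index=surv.index)
        fit = ss.fit_cox_ph(cov, surv)
        assert abs(fit.beta["grp"]) < 1e-6
        assert np.isclose(fit.summary.loc["grp", "hazard_ratio"], 1.0)

    def test_matches_generic_optimizer(self):
        cov, surv = _sim_cox([0.8, -0.5], 30, seed=1)
        fit = ss.fit_cox_ph(cov, surv)
        X = cov.to_numpy()
        t, e = surv["time"].to_numpy(), surv["event"].to_numpy(int)
        res = minimize(lambda b: cox_objective(b, X, t, e)[0], np.zeros(2),
                       method="BFGS", options={"gtol": 1e-10})
        assert np.allclose(fit.beta.to_numpy(), res.x, atol=1e-5)

    def test_parameter_recovery_large_n(self):
        cov, surv = _sim_cox([0.8, -0.5], 2000, seed=2, censor_rate=0.05)
        fit = ss.fit_cox_ph(cov, surv)
        assert np.all(np.abs(fit.beta.to_numpy() - [0.8, -0.5]) < 0.1)
        assert fit.summary["wald_p"].between(0, 1).all()
        assert np.allclose(fit.summary["hazard_ratio"],
                           np.exp(fit.summary["beta"]))

    def test_constant_covariate_rejected(self):
        cov, surv = _sim_cox([0.5], 20, seed=3)
        cov["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            ss.fit_cox_ph(cov, surv)

    def test_translation_leaves_concordance_unchanged(self):
        cov, surv = _sim_cox([0.7], 100, seed=4)
        f1 = ss.fit_cox_ph(cov, surv)
        f2 = ss.fit_cox_ph(cov + 55.0, surv)
        assert np.isclose(f1.concordance, f2.concordance)

    def test_ci_coverage_simulation(self):
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            cov, surv = _sim_cox([0.5], 300, seed=1000 + rep)
            s = ss.fit_cox_ph(cov, surv).summary.iloc[0]
            hits += s["ci95_low"] <= np.exp(0.5) <= s["ci95_high"]
        assert 0.92 <= hits / n_rep <= 0.98

    def test_stratified_fit_runs(self):
        cov, surv = _sim_cox([0.6], 120, seed=5)
        strata = pd.Series(np.arange(120) % 2, index=surv.index)
        fit = ss.fit_cox_ph(cov, surv, strata=strata)
        assert abs(fit.beta["x0"] - 0.6) < 0.35


class TestPHAssumption:
    def test_type_one_error_calibrated(self):
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            cov, surv = _sim_cox([0.5, -0.3], 150, seed=2000 + rep)
            fit = ss.fit_cox_ph(cov, surv)
            p = ss.ph_assumption_test(fit, cov, surv)
            rejections += p.iloc[0] < 0.05
        assert 0.02 <= rejections / n_rep <= 0.10

    def test_detects_reversing_effect(self):
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            n = 500
            x = rng.normal(size=n)
            # piecewise hazard: effect +1 before t=c, -1 after
            c = 0.7
            u = rng.exponential(size=n)
            h1 = np.exp(x)
            t = np.where(u / h1 <= c, u / h1, c + (u - c * h1) / np.exp(-x))
            surv = make_surv(t + 1e-6, np.ones(n))
            cov = pd.DataFrame({"x": x}, index=surv.index)
            fit = ss.fit_cox_ph(cov, surv)
            hits += ss.ph_assumption_test(fit, cov, surv)["x"] < 0.05
        assert hits / n_rep >= 0.8

    def test_insufficient_events_rejected(self):
        cov, surv = _sim_cox([0.5], 10, seed=6)
        surv["event"] = 0
        surv.iloc[0, surv.columns.get_loc("event")] = 1
        fit_cov, fit_surv = _sim_cox([0.5], 30, seed=7)
        fit = ss.fit_cox_ph(fit_cov, fit_surv)
        with pytest.raises(ValueError, match="3 events"):
            ss.ph_assumption_test(fit, cov.iloc[:10], surv)


class TestConcordance:
    def test_perfect_ranking(self):
        surv = make_surv([1.0, 2, 3, 4], np.ones(4))
        assert ss.concordance_index([4.0, 3, 2, 1], surv) == 1.0

    def test_all_ties_give_half(self):
        surv = make_surv([1.0, 2, 3, 4], np.ones(4))
        assert ss.concordance_index([1.0, 1, 1, 1], surv) == 0.5

    def test_matches_bruteforce_pairs(self):
        rng = np.random.default_rng(12)
        t = np.round(rng.exponential(10, 50), 0) + 1
        e = rng.integers(0, 2, 50)
        e[np.argmax(t)] = 1
        r = np.round(rng.normal(size=50), 1)  # induce risk ties
        surv = make_surv(t, e)
        mine = ss.concordance_index(r, surv)
        num = den = 0.0
        for i in range(50):
            for j in range(50):
                if t[i] < t[j] and e[i] == 1:
                    den += 1
                    if r[i] > r[j]:
                        num += 1
                    elif r[i] == r[j]:
                        num += 0.5
        assert mine == num / den

    def test_complement_symmetry(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(10, 40) + 0.01  # continuous: tie-free
        e = rng.integers(0, 2, 40)
        e[np.argmax(t)] = 1
        r = rng.normal(size=40)
        surv = make_surv(t, e)
        assert np.isclose(ss.concordance_index(r, surv)
                          + ss.concordance_index(-r, surv), 1.0)

    def test_no_comparable_pairs_rejected(self):
        surv = make_surv([5.0, 5.0], [1, 1])
        with pytest.raises(ValueError, match="comparable"):
            ss.concordance_index([1.0, 2.0], surv)


class TestPrognosticIndexAndSplit:
    def _fit(self, beta, names):
        summary = pd.DataFrame({"beta": beta}, index=names)
        return ss.CoxModelResult(summary=summary, concordance=0.5,
                                 overall_lr_p=1.0, loglik=0.0,
                                 covariance=np.eye(len(beta)))

    def test_linear_predictor_arithmetic(self):
        fit = self._fit([1.0, -1.0], ["a", "b"])
        cov = pd.DataFrame({"a": [2.0], "b": [3.0]}, index=["S0"])
        assert ss.prognostic_index(fit, cov)["S0"] == -1.0

    def test_zero_coefficients_give_zero_pi(self):
        fit = self._fit([0.0, 0.0], ["a", "b"])
        cov = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)),
                           columns=["a", "b"])
        assert (ss.prognostic_index(fit, cov) == 0).all()

    def test_missing_term_rejected(self):
        fit = self._fit([1.0], ["a"])
        with pytest.raises(ValueError, match="missing terms"):
            ss.prognostic_index(fit, pd.DataFrame({"b": [1.0]}))

    def test_matrix_product_oracle(self):
        rng = np.random.default_rng(14)
        b = rng.normal(size=4)
        fit = self._fit(b, list("abcd"))
        cov = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        assert np.allclose(ss.prognostic_index(fit, cov),
                           cov.to_numpy() @ b)

    def test_median_split_balanced(self):
        pi = pd.Series(np.arange(1.0, 11.0))
        grp = ss.median_split(pi)
        assert (grp == "low_risk").sum() == 5
        assert (grp == "high_risk").sum() == 5

    def test_median_split_tie_convention(self):
        grp = ss.median_split(pd.Series([0.0, 0.0, 0.0, 1.0]))
        assert (grp == "low_risk").sum() == 3
        assert (grp == "high_risk").sum() == 1

    def test_median_split_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ss.median_split(pd.Series([2.0, 2.0, 2.0]))


class TestKMandLogrank:
    def test_product_limit_closed_form(self):
        surv = make_surv([1.0, 2, 3, 4], np.ones(4))
        km = ss.km_curve(surv)
        assert np.allclose(km["survival"], [0.75, 0.50, 0.25, 0.0])
        assert list(km["n_at_risk"]) == [4, 3, 2, 1]

    def test_all_censored_flat_curve(self):
        surv = make_surv([1.0, 2, 3], np.zeros(3))
        km = ss.km_curve(surv)
        assert len(km) == 0  # no drops: survival stays at 1 throughout

    def test_censoring_shrinks_risk_set_without_drop(self):
        surv = make_surv([1.0, 2.0, 3.0], [1, 0, 1])
        km = ss.km_curve(surv)
        assert np.allclose(km["survival"], [2 / 3, 0.0])

    def test_identical_groups_give_null_logrank(self):
        times = np.array([2.0, 4, 6, 8, 10])
        surv = make_surv(np.concatenate([times, times]),
                         [1, 1, 0, 1, 1] * 2)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=surv.index)
        res = ss.logrank_test(surv, groups)
        assert res.chi_square < 1e-10
        assert res.df == 1
        assert res.p_value > 0.999

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(15)
        t1 = rng.exponential(1.0, 200)
        t2 = rng.exponential(3.0, 200)  # hazard ratio 3
        surv = make_surv(np.concatenate([t1, t2]) + 1e-6, np.ones(400))
        groups = pd.Series(["high"] * 200 + ["low"] * 200, index=surv.index)
        assert ss.logrank_test(surv, groups).p_value < 0.001

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(16)
        t = np.ceil(rng.exponential(5, 20)).astype(float)
        e = rng.integers(0, 2, 20)
        e[:4] = 1
        g = np.array(["a", "b"] * 10)
        surv = make_surv(t, e)
        res = ss.logrank_test(surv, pd.Series(g, index=surv.index))
        # observed-minus-expected with hypergeometric variance, group a
        o_minus_e = var = 0.0
        for tt in np.unique(t[e == 1]):
            at_risk = t >= tt
            d = ((t == tt) & (e == 1)).sum()
            n = at_risk.sum()
            n_a = (at_risk & (g == "a")).sum()
            d_a = ((t == tt) & (e == 1) & (g == "a")).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        assert abs(res.chi_square - o_minus_e ** 2 / var) < 1e-10

    def test_single_group_rejected(self):
        surv = make_surv([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            ss.logrank_test(surv, pd.Series(["a", "a"], index=surv.index))


class TestAugmentedModel:
    def _cohort(self, seed=17, n=300):
        cfg = SyntheticConfig(n_tumor=n, n_genes=40, n_informative=8,
                              seed=seed)
        expr, surv, clinical, truth = generate_cohort(cfg)
        return expr, surv, clinical, truth

    def test_duplicated_covariate_warns_collinear(self):
        expr, surv, clinical, _ = self._cohort()
        nodes = pd.DataFrame({"node_0": clinical["age"].to_numpy()},
                             index=clinical.index)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            ss.augment_baseline_model(clinical, nodes, surv)

    def test_signal_nodes_improve_concordance(self):
        expr, surv, clinical, truth = self._cohort()
        nodes = pd.DataFrame(
            {"node_0": truth.true_linear_predictor.to_numpy()},
            index=clinical.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base, aug = ss.augment_baseline_model(clinical, nodes, surv)
        assert aug.concordance >= base.concordance

    def test_null_nodes_leave_concordance_unchanged(self):
        expr, surv, clinical, _ = self._cohort(seed=18)
        rng = np.random.default_rng(0)
        nodes = pd.DataFrame({"node_0": rng.normal(size=len(clinical))},
                             index=clinical.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base, aug = ss.augment_baseline_model(clinical, nodes, surv)
        assert abs(aug.concordance - base.concordance) <= 0.03

    def test_dichotomize_and_stratify(self):
        expr, surv, clinical, truth = self._cohort(seed=19)
        nodes = pd.DataFrame(
            {"node_0": truth.true_linear_predictor.to_numpy(),
             "node_1": np.random.default_rng(1).normal(size=len(clinical))},
            index=clinical.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base, aug = ss.augment_baseline_model(
                clinical, nodes, surv, dichotomize={"node_1": 0.0},
                stratify_on="node_1")
        assert "node_1" not in aug.terms
        assert "node_0" in aug.terms
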