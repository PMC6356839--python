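"""Network forward pass, partial-likelihood loss, training behaviour."""

import numpy as np
import pandas as pd
import pytest

from deepcoxsig import deepcox as dc
from deepcoxsig import genefilter as gf
from deepcoxsig import survstats
from deepcoxsig.deepcox import BN_EPS, DeepCoxModel, NetworkConfig
from deepcoxsig.synthcohort import SyntheticConfig, generate_cohort

from conftest import make_surv


def _expr(values):
    values = np.asarray(values, float)
    return pd.DataFrame(values,
                        index=[f"G{i}" for i in range(values.shape[0])],
                        columns=[f"S{j}" for j in range(values.shape[1])])


def _toy_model(weights, biases, n_hidden_nodes, gene_ids):
    """Hand-built model with neutral batch-norm and identity input scaling."""
    return DeepCoxModel(
        config=NetworkConfig(hidden_sizes=tuple(n_hidden_nodes), seed=0),
        input_gene_ids=list(gene_ids),
        weights=[np.asarray(w, float) for w in weights],
        biases=[np.asarray(b, float) for b in biases],
        bn_scale=[np.ones(k) for k in n_hidden_nodes],
        bn_shift=[np.zeros(k) for k in n_hidden_nodes],
        bn_means=[np.zeros(k) for k in n_hidden_nodes],
        bn_vars=[np.full(k, 1.0 - BN_EPS) for k in n_hidden_nodes],
        input_mean=np.zeros(len(gene_ids)),
        input_sd=np.ones(len(gene_ids)),
    )


class TestForward:
    def test_zero_weights_give_constant_bias_output(self):
        X = _expr(np.random.default_rng(0).normal(size=(3, 7)))
        model = _toy_model(
            weights=[np.zeros((3, 4)), np.zeros((4, 1))],
            biases=[np.zeros(4), np.array([2.5])],
            n_hidden_nodes=[4], gene_ids=X.index)
        out = dc.forward(model, X)
        assert np.allclose(out.risk, 2.5)
        assert np.allclose(out.hidden_activations[0],
                           out.hidden_activations[0][0])

    def test_single_gene_identity_model(self):
        X = _expr([[1.0, -2.0, 0.5, 3.0]])
        model = _toy_model(weights=[np.array([[1.0]])],
                           biases=[np.zeros(1)],
                           n_hidden_nodes=[], gene_ids=X.index)
        assert np.allclose(dc.forward(model, X).risk, X.iloc[0])

    def test_matches_matrix_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        X = _expr(rng.normal(7, 1, size=(6, 5)))
        surv = make_surv(rng.exponential(10, 5) + 0.1, np.ones(5))
        cfg = NetworkConfig(hidden_sizes=(4, 3), max_epochs=3, seed=2)
        model, _ = dc.train(cfg, X, surv, X, surv)
        out = dc.forward(model, X, mode="eval")
        # independent reimplementation of the eval-mode forward pass
        a = (X.to_numpy().T - model.input_mean) / model.input_sd
        for layer in range(2):
            z = a @ model.weights[layer] + model.biases[layer]
            zhat = (z - model.bn_means[layer]) / np.sqrt(
                model.bn_vars[layer] + BN_EPS)
            a = np.maximum(model.bn_scale[layer] * zhat
                           + model.bn_shift[layer], 0.0)
        risk = a @ model.weights[-1] + model.biases[-1]
        assert np.allclose(out.risk.to_numpy(), risk[:, 0], atol=1e-6)

    def test_eval_mode_pure_function(self):
        rng = np.random.default_rng(4)
        X = _expr(rng.normal(size=(5, 8)))
        surv = make_surv(rng.exponential(10, 8) + 0.1, np.ones(8))
        model, _ = dc.train(NetworkConfig(hidden_sizes=(3,), max_epochs=2,
                                          seed=0), X, surv, X, surv)
        r1 = dc.forward(model, X).risk
        r2 = dc.forward(model, X).risk
        assert np.array_equal(r1.to_numpy(), r2.to_numpy())

    def test_gene_mismatch_and_nan_weights_rejected(self):
        X = _expr(np.ones((2, 3)))
        model = _toy_model(weights=[np.ones((2, 1))], biases=[np.zeros(1)],
                           n_hidden_nodes=[], gene_ids=["G0", "OTHER"])
        with pytest.raises(ValueError, match="alignment"):
            dc.forward(model, X)
        model.input_gene_ids = list(X.index)
        model.weights[0][0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            dc.forward(model, X)


class TestPartialLikelihood:
    def test_two_events_equal_risk_closed_form(self):
        surv = make_surv([1.0, 2.0], [1, 1])
        assert np.isclose(dc.neg_log_partial_likelihood([0.0, 0.0], surv),
                          np.log(2.0))

    def test_single_event_risk_set_of_one(self):
        surv = make_surv([5.0], [1])
        assert dc.neg_log_partial_likelihood([1.7], surv) == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        surv = make_surv(rng.exponential(10, 30) + 0.1,
                         rng.integers(0, 2, 30) | (np.arange(30) == 0))
        r = rng.normal(size=30)
        a = dc.neg_log_partial_likelihood(r, surv)
        b = dc.neg_log_partial_likelihood(r + 123.456, surv)
        assert abs(a - b) < 1e-8

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            dc.neg_log_partial_likelihood([0.0, 0.0],
                                          make_surv([1.0, 2.0], [0, 0]))

    def test_gradient_matches_finite_differences(self):
        from deepcoxsig._coxcore import breslow_nll_grad
        rng = np.random.default_rng(6)
        t = np.round(rng.exponential(10, 20), 1) + 0.1  # ties likely
        e = rng.integers(0, 2, 20)
        e[0] = 1
        r = rng.normal(size=20)
        _, g = breslow_nll_grad(r, t, e)
        h = 1e-6
        for i in range(20):
            rp, rm = r.copy(), r.copy()
            rp[i] += h
            rm[i] -= h
            fd = (breslow_nll_grad(rp, t, e, with_grad=False)
                  - breslow_nll_grad(rm, t, e, with_grad=False)) / (2 * h)
            assert abs(g[i] - fd) <= 1e-5 * max(abs(fd), 1e-3)


class TestTraining:
    def _data(self, n=40, g=6, seed=7):
        rng = np.random.default_rng(seed)
        X = _expr(rng.normal(7, 1, size=(g, n)))
        lp = X.iloc[0].to_numpy() - 7.0
        t = rng.exponential(np.exp(-lp)) + 0.01
        surv = make_surv(t, np.ones(n))
        return X, surv

    def test_huge_l2_collapses_weights(self):
        X, surv = self._data()
        cfg = NetworkConfig(hidden_sizes=(4,), l2_coefficient=1e6,
                            max_epochs=20, seed=1)
        model, _ = dc.train(cfg, X, surv, X, surv)
        assert all(np.linalg.norm(w) < 1e-2 for w in model.weights)

    def test_zero_epochs_returns_initialization(self):
        X, surv = self._data()
        cfg = NetworkConfig(hidden_sizes=(4,), max_epochs=0, seed=3)
        model, hist = dc.train(cfg, X, surv, X, surv)
        ref = dc._init_model(cfg, list(X.index), model.input_mean,
                             model.input_sd)
        assert len(hist) == 0
        for w, wr in zip(model.weights, ref.weights):
            assert np.array_equal(w, wr)

    def test_training_deterministic_given_seed(self):
        X, surv = self._data()
        cfg = NetworkConfig(hidden_sizes=(3,), max_epochs=15, seed=5)
        m1, h1 = dc.train(cfg, X, surv, X, surv)
        m2, h2 = dc.train(cfg, X, surv, X, surv)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_full_batch_gd_loss_monotone_at_small_lr(self):
        X, surv = self._data(n=30)
        cfg = NetworkConfig(hidden_sizes=(4,), optimizer="gd",
                            learning_rate=1e-3, l2_coefficient=0.01,
                            max_epochs=60, seed=2)
        _, hist = dc.train(cfg, X, surv, X, surv)
        diffs = np.diff(hist["train_loss"].to_numpy())
        assert np.all(diffs <= 1e-10)

    def test_validation_concordance_on_planted_signal(self):
        cfg = SyntheticConfig(n_tumor=400, n_genes=500, n_informative=20,
                              seed=7)
        expr, surv, _, _ = generate_cohort(cfg)
        parts = gf.stratified_partition(surv, k=10, seed=1)
        tr = parts.index[parts > 1]
        va = parts.index[parts == 1]
        net = NetworkConfig(hidden_sizes=(82, 27), max_epochs=400, seed=1)
        _, hist = dc.train(net, expr[tr], surv.loc[tr], expr[va], surv.loc[va])
        assert hist["val_concordance"].max() >= 0.70

    def test_permuted_outcomes_give_chance_concordance(self):
        cfg = SyntheticConfig(n_tumor=220, n_genes=60, n_informative=10,
                              seed=19)
        expr, surv, _, _ = generate_cohort(cfg)
        rng = np.random.default_rng(0)
        perm_surv = surv.copy()
        perm_surv[["time", "event"]] = surv.sample(frac=1.0, random_state=1
                                                   ).to_numpy()
        tr = expr.columns[:160]
        te = expr.columns[160:]
        net = NetworkConfig(hidden_sizes=(8,), max_epochs=150, seed=4)
        model, _ = dc.train(net, expr[tr], perm_surv.loc[tr],
                            expr[te], perm_surv.loc[te])
        risk = dc.forward(model, expr[te]).risk
        c = survstats.concordance_index(risk.to_numpy(), surv.loc[te])
        assert abs(c - 0.5) <= 0.1


class TestModelSelection:
    def test_singleton_grid_returned(self, small_cohort, tmp_path):
        _, expr, surv, _, _ = small_cohort
        parts = gf.stratified_partition(surv, k=5, seed=2)
        cfg = NetworkConfig(hidden_sizes=(4,), max_epochs=5, seed=0)
        best, results = dc.hyperparameter_search([cfg], expr, surv, parts)
        assert best == cfg
        assert len(results) == 1

    def test_published_operating_point_encodes(self):
        cfg = NetworkConfig(hidden_sizes=(82, 27))
        assert cfg.hidden_sizes == (82, 27)
        with pytest.raises(ValueError, match="two hidden"):
            NetworkConfig(hidden_sizes=(8, 8, 8))

    def test_two_layer_model_wins_on_nonlinear_risk(self):
        cfg = SyntheticConfig(n_tumor=350, n_genes=60, n_informative=12,
                              nonlinear_fraction=0.5, effect_sizes=1.0,
                              seed=23)
        expr, surv, _, _ = generate_cohort(cfg)
        parts = gf.stratified_partition(surv, k=10, seed=4)
        linear = NetworkConfig(hidden_sizes=(), max_epochs=250, seed=1)
        deep = NetworkConfig(hidden_sizes=(82, 27), max_epochs=250, seed=1)
        best, results = dc.hyperparameter_search([linear, deep], expr, surv,
                                                 parts)
        c = dict(zip(results["hidden_sizes"], results["val_concordance"]))
        assert c["(82, 27)"] >= c["()"]

    def test_rotate_validation_constant_predictor(self, small_cohort):
        _, expr, surv, _, _ = small_cohort
        parts = gf.stratified_partition(surv, k=5, seed=6)
        cfg = NetworkConfig(hidden_sizes=(3,), l2_coefficient=1e9,
                            max_epochs=2, seed=0)
        cs, mean, sd = dc.rotate_validation(cfg, expr, surv, parts)
        assert np.allclose(cs, 0.5)

    def test_rotate_validation_stable_on_signal(self, small_cohort):
        _, expr, surv, _, _ = small_cohort
        parts = gf.stratified_partition(surv, k=6, seed=8)
        cfg = NetworkConfig(hidden_sizes=(8,), max_epochs=120, seed=1)
        cs, mean, sd = dc.rotate_validation(cfg, expr, surv, parts)
        assert len(cs) == 5  # test partition excluded
        assert sd < 0.15


def test_model_round_trip_serialization(tmp_path):
    rng = np.random.default_rng(9)
    X = _expr(rng.normal(size=(4, 10)))
    surv = make_surv(rng.exponential(10, 10) + 0.1, np.ones(10))
    model, _ = dc.train(NetworkConfig(hidden_sizes=(3,), max_epochs=4, seed=0),
                        X, surv, X, surv)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = dc.DeepCoxModel.load(path)
    assert np.array_equal(dc.forward(model, X).risk.to_numpy(),
                          dc.forward(loaded, X).risk.to_numpy())
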