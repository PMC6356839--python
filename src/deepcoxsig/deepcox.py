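"""Feed-forward survival network trained on the Cox partial likelihood.

The model is a small multilayer perceptron (at most two ReLU hidden layers,
batch normalization on each) ending in a single linear output node whose
value is the log-risk score of a sample.  Training minimizes the negative
Breslow log partial likelihood (averaged over events) plus an L2 penalty on
all weights, by full-batch Adam with hand-written backpropagation; the
parameters kept are those of the epoch with the best validation concordance.

Inputs are per-gene z-scored with statistics frozen on the training split.
Inference always uses stored batch-norm running statistics, so the forward
pass in eval mode is a pure, deterministic function — a property the
permutation-importance stage depends on.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._coxcore import breslow_nll_grad
from .survstats import concordance_index

__all__ = [
    "NetworkConfig",
    "DeepCoxModel",
    "RiskOutput",
    "neg_log_partial_likelihood",
    "forward",
    "train",
    "hyperparameter_search",
    "rotate_validation",
]


@dataclass(frozen=True)
class NetworkConfig:
    hidden_sizes: tuple[int, ...] = (82, 27)
    learning_rate: float = 0.01
    l2_coefficient: float = 0.3
    max_epochs: int = 1000
    batch_mode: str = "full"  # {"full", "minibatch"}
    batch_size: int = 64
    optimizer: str = "adam"  # {"adam", "gd"}
    bn_momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        hs = tuple(int(h) for h in self.hidden_sizes)
        object.__setattr__(self, "hidden_sizes", hs)
        if len(hs) > 2:
            raise ValueError("configuration error: at most two hidden layers")
        if any(h <= 0 for h in hs):
            raise ValueError("configuration error: hidden sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("configuration error: learning_rate must be positive")
        if self.l2_coefficient < 0:
            raise ValueError("configuration error: l2_coefficient must be >= 0")
        if self.max_epochs < 0:
            raise ValueError("configuration error: max_epochs must be >= 0")
        if self.batch_mode not in ("full", "minibatch"):
            raise ValueError("configuration error: unknown batch_mode")
        if self.optimizer not in ("adam", "gd"):
            raise ValueError("configuration error: unknown optimizer")

    def n_parameters(self, n_inputs: int) -> int:
        sizes = [n_inputs, *self.hidden_sizes, 1]
        n = sum(sizes[i] * sizes[i + 1] + sizes[i + 1]
                for i in range(len(sizes) - 1))
        n += 4 * sum(self.hidden_sizes)  # batch-norm scale/shift/running stats
        return n


@dataclass
class DeepCoxModel:
    config: NetworkConfig
    input_gene_ids: list[str]
    weights: list[np.ndarray]  # one per layer, hidden layers then output
    biases: list[np.ndarray]
    bn_scale: list[np.ndarray]  # gamma per hidden layer
    bn_shift: list[np.ndarray]  # beta per hidden layer
    bn_means: list[np.ndarray]  # running means
    bn_vars: list[np.ndarray]  # running variances
    input_mean: np.ndarray = field(default=None)
    input_sd: np.ndarray = field(default=None)

    @property
    def n_hidden_layers(self) -> int:
        return len(self.weights) - 1

    def node_ids(self) -> list[str]:
        """Names of the last hidden layer's nodes (the learned features)."""
        if self.n_hidden_layers == 0:
            return []
        return [f"node_{i}" for i in range(self.weights[-1].shape[0])]

    def to_dict(self) -> dict:
        d = {"config": asdict(self.config),
             "input_gene_ids": list(self.input_gene_ids)}
        for name in ("weights", "biases", "bn_scale", "bn_shift",
                     "bn_means", "bn_vars"):
            d[name] = [a.tolist() for a in getattr(self, name)]
        d["input_mean"] = self.input_mean.tolist()
        d["input_sd"] = self.input_sd.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DeepCoxModel":
        cfg = dict(d["config"])
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            config=NetworkConfig(**cfg),
            input_gene_ids=list(d["input_gene_ids"]),
            weights=[np.asarray(a, dtype=float) for a in d["weights"]],
            biases=[np.asarray(a, dtype=float) for a in d["biases"]],
            bn_scale=[np.asarray(a, dtype=float) for a in d["bn_scale"]],
            bn_shift=[np.asarray(a, dtype=float) for a in d["bn_shift"]],
            bn_means=[np.asarray(a, dtype=float) for a in d["bn_means"]],
            bn_vars=[np.asarray(a, dtype=float) for a in d["bn_vars"]],
            input_mean=np.asarray(d["input_mean"], dtype=float),
            input_sd=np.asarray(d["input_sd"], dtype=float),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "DeepCoxModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RiskOutput:
    sample_ids: list[str]
    risk: pd.Series
    hidden_activations: list[np.ndarray]  # per hidden layer, samples x nodes

    def last_hidden(self) -> np.ndarray:
        if not self.hidden_activations:
            raise ValueError("model has no hidden layers")
        return self.hidden_activations[-1]


BN_EPS = 1e-5


def neg_log_partial_likelihood(risk, surv: pd.DataFrame) -> float:
    """Negative Breslow log partial likelihood (sum over events).

    ``loss = - sum_{i: event} [risk_i - log sum_{j: t_j >= t_i} exp(risk_j)]``
    with tied event times sharing a denominator; the log-sum-exp is computed
    stably.  Invariant to adding a constant to every risk score.
    """
    r = np.asarray(risk, dtype=float)
    return float(breslow_nll_grad(r, surv["time"].to_numpy(float),
                                  surv["event"].to_numpy(int),
                                  with_grad=False))


def _init_model(config: NetworkConfig, gene_ids, input_mean,
                input_sd) -> DeepCoxModel:
    rng = np.random.default_rng(config.seed)
    sizes = [len(gene_ids), *config.hidden_sizes, 1]
    weights, biases = [], []
    for i in range(len(sizes) - 1):
        fan_in = sizes[i]
        scale = np.sqrt(2.0 / fan_in) if i < len(sizes) - 2 else 1.0 / np.sqrt(fan_in)
        weights.append(rng.normal(0.0, scale, size=(sizes[i], sizes[i + 1])))
        biases.append(np.zeros(sizes[i + 1]))
    h = config.hidden_sizes
    return DeepCoxModel(
        config=config,
        input_gene_ids=list(gene_ids),
        weights=weights,
        biases=biases,
        bn_scale=[np.ones(k) for k in h],
        bn_shift=[np.zeros(k) for k in h],
        bn_means=[np.zeros(k) for k in h],
        bn_vars=[np.ones(k) for k in h],
        input_mean=np.asarray(input_mean, dtype=float),
        input_sd=np.asarray(input_sd, dtype=float),
    )


def _forward_internal(model: DeepCoxModel, A: np.ndarray, mode: str,
                      update_running: bool = False):
    """Forward pass on an already standardized samples x genes array.

    Returns (risk, hidden_activations, caches); caches hold what backprop
    needs for the train-mode batch statistics path.
    """
    caches = []
    hidden = []
    cfg = model.config
    for layer in range(model.n_hidden_layers):
        Z = A @ model.weights[layer] + model.biases[layer]
        if mode == "train":
            mu = Z.mean(axis=0)
            var = Z.var(axis=0)
            if update_running:
                m = cfg.bn_momentum
                model.bn_means[layer] = m * model.bn_means[layer] + (1 - m) * mu
                model.bn_vars[layer] = m * model.bn_vars[layer] + (1 - m) * var
        else:
            mu = model.bn_means[layer]
            var = model.bn_vars[layer]
        inv_sd = 1.0 / np.sqrt(var + BN_EPS)
        Zhat = (Z - mu) * inv_sd
        Y = model.bn_scale[layer] * Zhat + model.bn_shift[layer]
        H = np.maximum(Y, 0.0)
        caches.append({"A": A, "Z": Z, "Zhat": Zhat, "inv_sd": inv_sd, "Y": Y})
        hidden.append(H)
        A = H
    risk = A @ model.weights[-1] + model.biases[-1]
    caches.append({"A": A})
    return risk[:, 0], hidden, caches


def _standardize(model: DeepCoxModel, X: pd.DataFrame) -> np.ndarray:
    if list(X.index) != list(model.input_gene_ids):
        if set(X.index) != set(model.input_gene_ids):
            raise ValueError("alignment error: gene ids do not match model inputs")
        X = X.loc[model.input_gene_ids]
    A = X.to_numpy(float).T  # samples x genes
    return (A - model.input_mean) / model.input_sd


def forward(model: DeepCoxModel, X: pd.DataFrame, mode: str = "eval") -> RiskOutput:
    """Run the network on a gene x sample expression matrix.

    ``mode='train'`` normalizes each hidden layer with the current batch's
    statistics; ``mode='eval'`` uses the stored running statistics and is a
    pure deterministic function of (model, X).
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    for w in model.weights:
        if not np.all(np.isfinite(w)):
            raise ValueError("model-state error: non-finite weights")
    A = _standardize(model, X)
    risk, hidden, _ = _forward_internal(model, A, mode)
    samples = list(X.columns)
    return RiskOutput(sample_ids=samples,
                      risk=pd.Series(risk, index=samples, name="risk"),
                      hidden_activations=hidden)


def _backward(model: DeepCoxModel, caches, hidden, drisk: np.ndarray):
    """Backprop of d(loss)/d(risk) through output layer, ReLU and batch norm."""
    grads_w = [None] * len(model.weights)
    grads_b = [None] * len(model.biases)
    grads_gamma = [None] * model.n_hidden_layers
    grads_beta = [None] * model.n_hidden_layers
    dZout = drisk[:, None]  # (n, 1)
    A_last = caches[-1]["A"]
    grads_w[-1] = A_last.T @ dZout
    grads_b[-1] = dZout.sum(axis=0)
    dA = dZout @ model.weights[-1].T
    for layer in range(model.n_hidden_layers - 1, -1, -1):
        c = caches[layer]
        n = c["Z"].shape[0]
        dH = dA
        dY = dH * (c["Y"] > 0)
        grads_gamma[layer] = (dY * c["Zhat"]).sum(axis=0)
        grads_beta[layer] = dY.sum(axis=0)
        dZhat = dY * model.bn_scale[layer]
        # batch-norm backward (batch statistics path)
        dZ = (c["inv_sd"] / n) * (
            n * dZhat - dZhat.sum(axis=0)
            - c["Zhat"] * (dZhat * c["Zhat"]).sum(axis=0)
        )
        grads_w[layer] = c["A"].T @ dZ
        grads_b[layer] = dZ.sum(axis=0)
        dA = dZ @ model.weights[layer].T
    return grads_w, grads_b, grads_gamma, grads_beta


def train(config: NetworkConfig, X_train: pd.DataFrame, surv_train: pd.DataFrame,
          X_valid: pd.DataFrame, surv_valid: pd.DataFrame):
    """Train a network; keep the epoch with best validation concordance.

    The training objective is NLL / n_events + l2_coefficient * sum ||W||^2.
    Returns ``(model, history)`` where history is a per-epoch DataFrame with
    ``train_loss`` (penalized) and ``val_concordance``.  Identical config and
    data give an identical model.
    """
    time_tr = surv_train["time"].to_numpy(float)
    event_tr = surv_train["event"].to_numpy(int)
    if event_tr.sum() < 1 or surv_train["event"].sum() < 1:
        raise ValueError("undefined likelihood: zero events in training set")
    if surv_valid["event"].sum() < 1:
        raise ValueError("undefined likelihood: zero events in validation set")

    Xa = X_train.to_numpy(float).T
    mean = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    model = _init_model(config, list(X_train.index), mean, sd)
    if config.max_epochs == 0:
        return model, pd.DataFrame(columns=["epoch", "train_loss",
                                            "val_concordance"])

    A_full = (Xa - mean) / sd
    n = A_full.shape[0]
    rng = np.random.default_rng((config.seed, 17))
    params = (model.weights + model.biases + model.bn_scale + model.bn_shift)
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    t_adam = 0
    best = {"c": -np.inf, "epoch": -1, "state": None}
    history = []

    def current_params():
        return model.weights + model.biases + model.bn_scale + model.bn_shift

    for epoch in range(1, config.max_epochs + 1):
        if config.batch_mode == "full":
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = [perm[i:i + config.batch_size]
                       for i in range(0, n, config.batch_size)]
            batches = [b for b in batches if event_tr[b].sum() >= 1]
        epoch_loss = 0.0
        for idx in batches:
            A = A_full[idx]
            risk, hidden, caches = _forward_internal(model, A, "train",
                                                     update_running=True)
            nll, dr = breslow_nll_grad(risk, time_tr[idx], event_tr[idx])
            d = event_tr[idx].sum()
            dr = dr / d
            penalty = config.l2_coefficient * sum(float(np.sum(w * w))
                                                  for w in model.weights)
            epoch_loss += (nll / d + penalty) * (len(idx) / n)
            gw, gb, gg, gs = _backward(model, caches, hidden, dr)
            plist = current_params()
            if config.optimizer == "adam":
                # decoupled weight decay: Adam's per-parameter rescaling would
                # otherwise neutralize a gradient-coupled L2 term
                grads = gw + gb + gg + gs
                t_adam += 1
                for i, (p, g) in enumerate(zip(plist, grads)):
                    m_adam[i] = 0.9 * m_adam[i] + 0.1 * g
                    v_adam[i] = 0.999 * v_adam[i] + 0.001 * g * g
                    mhat = m_adam[i] / (1 - 0.9 ** t_adam)
                    vhat = v_adam[i] / (1 - 0.999 ** t_adam)
                    p -= config.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
                decay = max(0.0, 1.0 - 2.0 * config.learning_rate
                            * config.l2_coefficient)
                for w in model.weights:
                    w *= decay
            else:  # plain gradient descent on the penalized objective
                gw = [g + 2.0 * config.l2_coefficient * w
                      for g, w in zip(gw, model.weights)]
                for p, g in zip(plist, gw + gb + gg + gs):
                    p -= config.learning_rate * g
        if not np.isfinite(epoch_loss):
            raise RuntimeError(f"training error: loss diverged at epoch {epoch}")
        val_risk = forward(model, X_valid, mode="eval").risk
        val_c = concordance_index(val_risk.to_numpy(), surv_valid)
        history.append((epoch, epoch_loss, val_c))
        if val_c > best["c"]:
            best = {"c": val_c, "epoch": epoch,
                    "state": copy.deepcopy(
                        (model.weights, model.biases, model.bn_scale,
                         model.bn_shift, model.bn_means, model.bn_vars))}
    if best["state"] is not None:
        (model.weights, model.biases, model.bn_scale, model.bn_shift,
         model.bn_means, model.bn_vars) = best["state"]
    hist = pd.DataFrame(history, columns=["epoch", "train_loss",
                                          "val_concordance"])
    hist.attrs["best_epoch"] = best["epoch"]
    return model, hist


def _split_by_partition(X, surv, partitions, valid_partition, test_partition):
    part = partitions.loc[surv.index]
    valid_ids = part.index[part == valid_partition]
    train_ids = part.index[(part != valid_partition) & (part != test_partition)]
    return (X[train_ids], surv.loc[train_ids], X[valid_ids], surv.loc[valid_ids])


def hyperparameter_search(grid, X: pd.DataFrame, surv: pd.DataFrame,
                          partitions: pd.Series, valid_partition: int = 1,
                          test_partition: int = 0):
    """Exhaustive grid evaluation by validation concordance.

    Trains every configuration on the non-test, non-validation partitions and
    scores it on the validation partition.  Best = maximum validation
    concordance; ties prefer the configuration with fewer parameters, then
    earlier grid position.  Returns ``(best_config, results)``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("configuration error: empty grid")
    Xt, st, Xv, sv = _split_by_partition(X, surv, partitions,
                                         valid_partition, test_partition)
    rows = []
    for i, cfg in enumerate(grid):
        try:
            _, hist = train(cfg, Xt, st, Xv, sv)
            c = hist["val_concordance"].max() if len(hist) else 0.5
        except RuntimeError:  # diverged configuration scores worst
            c = -np.inf
        rows.append((i, cfg, float(c), cfg.n_parameters(X.shape[0])))
    results = pd.DataFrame(
        [(i, str(cfg.hidden_sizes), c, npar) for i, cfg, c, npar in rows],
        columns=["grid_index", "hidden_sizes", "val_concordance", "n_parameters"],
    )
    best = max(rows, key=lambda r: (r[2], -r[3], -r[0]))
    return best[1], results


def rotate_validation(config: NetworkConfig, X: pd.DataFrame,
                      surv: pd.DataFrame, partitions: pd.Series,
                      test_partition: int = 0):
    """Validation-concordance spread across partition rotations.

    Rotates every non-test partition through the validation role, training on
    the remainder each time.  Returns ``(per_rotation, mean, sd)``.
    """
    ks = sorted(p for p in partitions.unique() if p != test_partition)
    cs = []
    for v in ks:
        Xt, st, Xv, sv = _split_by_partition(X, surv, partitions, v,
                                             test_partition)
        model, _ = train(config, Xt, st, Xv, sv)
        risk = forward(model, Xv, mode="eval").risk
        cs.append(concordance_index(risk.to_numpy(), sv))
    cs = np.asarray(cs)
    return cs, float(cs.mean()), float(cs.std(ddof=1) if len(cs) > 1 else 0.0)
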