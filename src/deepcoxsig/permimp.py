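"""Hidden-layer permutation importance and gene-signature extraction.

A trained survival network is probed by permuting one input gene at a time
across samples (breaking its association with the outcome while preserving
its marginal distribution) and recording the mean absolute change this
causes at every node of the last hidden layer and at the output risk score.
Genes whose impact at a node is an across-gene outlier are flagged important
there; counting flags across nodes gives each gene an occurrence frequency;
a binomial null on those occurrences yields the minimum frequency ``k_min``
at which occurrence is unlikely by chance, and the genes at or above it form
the prognostic signature.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deepcox import DeepCoxModel, _forward_internal, _standardize

__all__ = [
    "Signature",
    "permutation_deltas",
    "flag_important_genes",
    "gene_frequency",
    "occurrence_threshold",
    "extract_signature",
    "discover_signature",
]

OUTPUT_NODE = "output"


@dataclass
class Signature:
    gene_ids: list[str]
    k_min: int
    p_threshold: float | None = None

    def __len__(self):
        return len(self.gene_ids)

    def __contains__(self, gene):
        return gene in set(self.gene_ids)


def permutation_deltas(model: DeepCoxModel, X: pd.DataFrame,
                       n_repeats: int = 5, seed: int = 0,
                       permute=None) -> pd.DataFrame:
    """Mean absolute activation change per (gene, node) under permutation.

    For each gene and repeat, the gene's values are shuffled across samples
    (seeded per (gene, repeat) by a counter scheme, so results do not depend
    on gene iteration order), the network is re-run in eval mode, and the
    mean absolute change over samples is recorded at every last-hidden-layer
    node and at the output.  Deltas are averaged over repeats.  ``permute``
    may be a callable ``(gene_index, repeat, rng, n) -> permutation`` to
    override the shuffling (used for controlled experiments).

    Returns a DataFrame indexed by gene id with one column per last-hidden
    node plus ``"output"``.  The input matrix is never mutated.
    """
    if n_repeats < 1:
        raise ValueError("configuration error: n_repeats must be >= 1")
    A = _standardize(model, X)  # samples x genes copy
    n, g = A.shape
    base_risk, base_hidden, _ = _forward_internal(model, A, "eval")
    base_last = base_hidden[-1] if base_hidden else None
    node_ids = model.node_ids()
    deltas = np.zeros((g, len(node_ids) + 1))
    # seed stream keyed on the gene *identity* (stable CRC of the id), so
    # deltas do not depend on gene order and relabeling permutes rows exactly
    gene_keys = [zlib.crc32(gid.encode()) for gid in model.input_gene_ids]
    for gi in range(g):
        col = A[:, gi].copy()
        for rep in range(n_repeats):
            rng = np.random.default_rng((seed, gene_keys[gi], rep))
            perm = rng.permutation(n) if permute is None else permute(gi, rep, rng, n)
            A[:, gi] = col[perm]
            risk, hidden, _ = _forward_internal(model, A, "eval")
            if base_last is not None:
                deltas[gi, :-1] += np.mean(np.abs(hidden[-1] - base_last), axis=0)
            deltas[gi, -1] += np.mean(np.abs(risk - base_risk))
        A[:, gi] = col
    deltas /= n_repeats
    return pd.DataFrame(deltas, index=pd.Index(model.input_gene_ids,
                                               name="gene_id"),
                        columns=node_ids + [OUTPUT_NODE])


def flag_important_genes(imp: pd.DataFrame, node: str,
                         ci_level: float = 0.95) -> pd.Series:
    """Flag genes whose delta at ``node`` is an across-gene outlier.

    A gene is important at a node when its delta exceeds the across-gene mean
    by more than z standard deviations, z being the two-sided normal quantile
    of ``ci_level`` (1.96 at 0.95); the comparison is one-sided because
    deltas are nonnegative.
    """
    if node not in imp.columns:
        raise ValueError(f"node {node!r} not present in importance matrix")
    if len(imp) < 10:
        raise ValueError("insufficient data: need >= 10 genes to flag outliers")
    d = imp[node]
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return (d > d.mean() + z * d.std(ddof=1)).rename(node)


def gene_frequency(flags: pd.DataFrame) -> pd.Series:
    """Count, per gene, the nodes at which it was flagged important.

    ``flags`` is a boolean genes x nodes DataFrame (one column per node).
    Returns a Series ordered by descending frequency, then gene id.
    """
    if isinstance(flags, dict):
        idx = None
        for node, s in flags.items():
            if idx is None:
                idx = s.index
            elif not s.index.equals(idx):
                raise ValueError("alignment error: gene universes differ "
                                 "across nodes")
        flags = pd.DataFrame(flags)
    freq = flags.sum(axis=1).astype(int)
    order = sorted(freq.index, key=lambda gid: (-freq[gid], gid))
    return freq.loc[order].rename("frequency")


def occurrence_threshold(freq: pd.Series, n_nodes: int = 27,
                         p_threshold: float = 0.01) -> int:
    """Minimum occurrence count that is unlikely under a binomial null.

    The null treats each (gene, node) flag as an independent Bernoulli draw
    with pooled rate q_hat = (total flags) / (n_genes * n_nodes); k_min is
    the smallest k with upper-tail P(K >= k) < ``p_threshold`` for
    K ~ Binomial(n_nodes, q_hat).
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    q_hat = float(freq.sum()) / (len(freq) * n_nodes)
    return occurrence_threshold_from_rate(q_hat, n_nodes, p_threshold)


def occurrence_threshold_from_rate(q_hat: float, n_nodes: int = 27,
                                   p_threshold: float = 0.01) -> int:
    if q_hat == 0.0:
        warnings.warn("no flags at any node; occurrence threshold defaults to 1")
        return 1
    for k in range(1, n_nodes + 2):
        if stats.binom.sf(k - 1, n_nodes, q_hat) < p_threshold:
            return k
    return n_nodes + 1


def extract_signature(freq: pd.Series, k_min: int,
                      p_threshold: float | None = None) -> Signature:
    """Genes occurring at >= k_min nodes, in descending-frequency order."""
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    members = freq[freq >= k_min]
    order = sorted(members.index, key=lambda gid: (-members[gid], gid))
    return Signature(gene_ids=list(order), k_min=int(k_min),
                     p_threshold=p_threshold)


def discover_signature(model: DeepCoxModel, X: pd.DataFrame,
                       n_repeats: int = 5, seed: int = 0,
                       ci_level: float = 0.95, p_threshold: float = 0.01):
    """Full discovery chain: deltas -> flags -> frequency -> k_min -> signature.

    Returns ``(imp, freq, k_min, signature)``.  Flags are computed at every
    last-hidden-layer node (the output column contributes to the importance
    matrix but not to the occurrence count).
    """
    imp = permutation_deltas(model, X, n_repeats=n_repeats, seed=seed)
    node_cols = [c for c in imp.columns if c != OUTPUT_NODE]
    if not node_cols:
        raise ValueError("model has no hidden layer to analyze")
    flags = pd.DataFrame({node: flag_important_genes(imp, node, ci_level)
                          for node in node_cols})
    freq = gene_frequency(flags)
    k_min = occurrence_threshold(freq, n_nodes=len(node_cols),
                                 p_threshold=p_threshold)
    sig = extract_signature(freq, k_min, p_threshold=p_threshold)
    return imp, freq, k_min, sig
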