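# deepcoxsig

Prognostic gene discovery from tumor expression data with a Cox
partial-likelihood neural network, hidden-layer permutation importance, and
penalized-Cox comparators.

## The problem

Given a log2 gene × sample expression matrix for a tumor cohort (plus a
small normal-tissue reference), right-censored overall-survival outcomes and
clinical covariates, the goal is to find a compact set of genes that carries
prognostic information beyond known clinical factors. The approach modeled
here, developed for glioblastoma cohorts, is:

1. **Filter**: per-gene Welch t-test of tumor vs normal, selected at
   p < 0.01 with ≥ 2-fold change (|log2 FC| ≥ 1); the p-value histogram is
   modeled as a beta-uniform mixture (BUM),
   f(p) = λ + (1−λ)·a·p^(a−1), giving an estimated FDR at the cutoff;
   genes with pairwise |r| > 0.8 collapse to one representative.
2. **Model**: a feed-forward network (≤ 2 ReLU hidden layers with batch
   normalization; the published operating point is 82 then 27 nodes) maps
   z-scored expression x to a scalar log-risk score g(x), trained by
   minimizing the negative Breslow log partial likelihood

   L = − Σ_{i: δᵢ=1} [ g(xᵢ) − log Σ_{j: tⱼ ≥ tᵢ} exp g(xⱼ) ] + λ‖W‖²

   on survival-time-stratified 80/10/10 train/validation/test partitions,
   keeping the epoch with the best validation concordance (Harrell's C).
3. **Probe**: permutation importance at the *last hidden layer* — each input
   gene is shuffled across samples (5 repeats) and the mean |activation
   change| at each of the 27 nodes (and the output) is recorded. Genes
   exceeding the across-gene mean by 1.96 SD at a node are flagged there;
   a binomial null on the number of nodes flagging a gene yields the minimum
   occurrence count k_min (tail probability < 0.01), and genes at or above
   it form the signature.
4. **Compare & validate**: ridge, adaptive-lasso and elastic-net Cox models
   (9-fold CV, λ at minimum deviance) serve as comparators; the signature is
   evaluated with a Cox model whose prognostic index x'β is split at the
   median into low/high-risk groups compared by Kaplan–Meier curves and the
   log-rank test, and node activations are added to a clinical baseline Cox
   model to measure the gain in concordance.

A synthetic cohort generator with planted prognostic genes (Weibull
proportional hazards, calibrated censoring, block-correlated expression)
provides ground truth for every stage, so the whole pipeline is testable
without any data download. A packaged reference table (the published
occurrence frequencies of the top 100 genes across 27 network nodes, and
the derived 39-gene signature headed by *TNR*) anchors the signature
extraction as a worked example.

## Worked example

```python
from deepcoxsig import (SyntheticConfig, NetworkConfig, generate_cohort,
                        deepcox, genefilter, permimp)

cfg = SyntheticConfig(n_tumor=400, n_genes=500, n_informative=20, seed=7)
expr, surv, clinical, truth = generate_cohort(cfg)
parts = genefilter.stratified_partition(surv, k=10, seed=1)
tr, va = parts.index[parts > 1], parts.index[parts == 1]
model, hist = deepcox.train(NetworkConfig(seed=1), expr[tr], surv.loc[tr],
                            expr[va], surv.loc[va])
imp, freq, k_min, sig = permimp.discover_signature(model, expr, seed=2)
print(hist["val_concordance"].max(), k_min, len(sig))
```

This prints a best validation concordance of `0.754` (0.5 would be random;
~0.75 means the network orders patient risk well), an occurrence threshold
`k_min = 5` of 27 nodes, and a signature of `38` genes — 18 of the 20
planted prognostic genes plus correlated or borderline genes that the
occurrence analysis does not screen out (see `docs/methods.md` for why).
Running `examples/04_signature_discovery.py` reproduces these numbers along
with the packaged worked example (39 reference genes at k_min = 10, top
entry *TNR* flagged at 17/27 nodes). The other scripts under `examples/`
each demonstrate one capability: cohort generation, filtering, training,
comparators, survival evaluation and the one-call pipeline.

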