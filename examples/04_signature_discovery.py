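"""Permutation importance at the last hidden layer and signature extraction.

Each gene is shuffled across samples (5 repeats) and the mean absolute
change of every last-hidden-layer node and of the output risk is recorded.
Genes whose impact at a node exceeds the across-gene mean by 1.96 SD are
flagged; a binomial null on the per-gene occurrence count yields the
minimum frequency k_min, and genes at or above it form the signature.

Also reproduces the packaged worked example: thresholding the published
glioblastoma occurrence table at frequency >= 10 yields the 39-gene
signature headed by TNR.
"""

from deepcoxsig import NetworkConfig, SyntheticConfig, generate_cohort
from deepcoxsig import deepcox, genefilter, permimp
from deepcoxsig.io import load_reference_frequency_table

cfg = SyntheticConfig(n_tumor=400, n_genes=500, n_informative=20, seed=7)
expr, surv, _, truth = generate_cohort(cfg)
parts = genefilter.stratified_partition(surv, k=10, seed=1)
valid = parts.index[parts == 1]
train_ids = parts.index[parts > 1]
model, _ = deepcox.train(NetworkConfig(seed=1), expr[train_ids],
                         surv.loc[train_ids], expr[valid], surv.loc[valid])

imp, freq, k_min, sig = permimp.discover_signature(model, expr, n_repeats=5,
                                                   seed=2)
informative = set(truth.informative_gene_ids)
top50 = set(imp["output"].nlargest(50).index)
print(f"top-50 output-importance genes contain "
      f"{len(top50 & informative)}/20 planted genes")
print(f"occurrence threshold k_min = {k_min} of 27 nodes")
print(f"signature: {len(sig)} genes, "
      f"{len(set(sig.gene_ids) & informative)} of them planted")

ref = load_reference_frequency_table()
ref_sig = permimp.extract_signature(ref, k_min=10)
print(f"reference table at k_min=10 -> {len(ref_sig)} genes, "
      f"top entry {ref_sig.gene_ids[0]} "
      f"(flagged at {ref[ref_sig.gene_ids[0]]}/27 nodes)")
# High planted-gene recall in the top-50 shows importance ranks real signal
# first; the signature still admits correlated proxy genes, which is why
# the occurrence analysis is reported together with the raw ranking.
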