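"""Differential-expression filtering with a BUM-estimated FDR.

Welch t-tests compare each gene's tumor expression against the normal
reference; a beta-uniform mixture fitted to the p-value histogram estimates
the false-discovery rate at the p < 0.01 cutoff; genes also need at least a
2-fold change (|log2 FC| >= 1).  Correlated survivors (|r| > 0.8) collapse
to one representative.
"""

from deepcoxsig import SyntheticConfig, generate_cohort, generate_normal_reference
from deepcoxsig import genefilter as gf

cfg = SyntheticConfig(n_tumor=300, n_genes=500, n_informative=20, seed=1)
expr, surv, _, truth = generate_cohort(cfg)
normal = generate_normal_reference(cfg)

de = gf.diff_expression(expr, normal)
bum = gf.fit_bum(de["p_value"].clip(lower=1e-300))
fdr = gf.bum_fdr(bum, 0.01)
selected = gf.select_de_genes(de, p_max=0.01, min_abs_log2fc=1.0)
pruned = gf.correlation_prune(expr.loc[selected], r_max=0.8)
hits = len(set(selected) & set(truth.informative_gene_ids))

print(f"BUM fit: lambda = {bum.lambda_mix:.3f}, a = {bum.a_shape:.3f}")
print(f"estimated FDR among genes with p < 0.01: {fdr:.4f}")
print(f"selected {len(selected)} genes (p < 0.01 and >= 2-fold); "
      f"{hits}/20 planted genes recovered")
print(f"{len(pruned)} genes remain after correlation pruning")
# A low FDR plus near-complete recovery of the planted genes shows the
# two-arm filter isolates the differentially expressed signal.

parts = gf.stratified_partition(surv, k=10, seed=2)
print("partition sizes:", parts.value_counts().sort_index().tolist(),
      "(survival-time distribution preserved in each)")
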