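"""End-to-end orchestration of the discovery pipeline.

Order of stages: differential-expression filtering against the normal
reference -> correlation pruning -> survival-time-stratified partitioning ->
deep Cox network training (optionally a small architecture search) ->
hidden-layer permutation importance -> occurrence-based signature
extraction -> penalized-Cox comparators -> signature Cox evaluation with
prognostic-index median split, log-rank test and Kaplan-Meier curves.

Every stage receives a seed derived from the single global seed by a fixed
offset scheme, and ``run_pipeline`` writes a manifest recording every seed,
threshold and output-file hash, so a run is fully reproducible from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coxpen, deepcox, genefilter, io, permimp, survstats
from .synthcohort import SyntheticConfig, generate_cohort, generate_normal_reference

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

# fixed per-stage seed offsets fanned out from the global seed
_STAGE_OFFSET = {"partition": 11, "train": 23, "permimp": 37, "coxpen": 53}


@dataclass
class PipelineConfig:
    synth: SyntheticConfig | None = None
    expression_path: str | None = None
    normal_path: str | None = None
    survival_path: str | None = None
    clinical_path: str | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0
    # gene filtering
    p_max: float = 0.01
    min_abs_log2fc: float = 1.0
    r_max: float = 0.8
    apply_de_filter: bool = True
    # partitioning / training
    k_partitions: int = 10
    network_grid: tuple = ()  # empty -> single default NetworkConfig
    network: deepcox.NetworkConfig | None = None
    # importance
    n_repeats: int = 5
    ci_level: float = 0.95
    p_threshold: float = 0.01
    # comparators
    penalties: tuple = ("ridge", "adaptive_lasso", "elastic_net")
    n_cv_folds: int = 9
    run_comparators: bool = True

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) * 100 + _STAGE_OFFSET[stage]


@dataclass
class PipelineResult:
    selected_genes: list[str]
    bum_fdr_at_pmax: float
    partitions: pd.Series
    model: deepcox.DeepCoxModel
    history: pd.DataFrame
    validation_concordance: float
    test_concordance: float
    importance: pd.DataFrame
    frequency: pd.Series
    k_min: int
    signature: permimp.Signature
    comparator_concordance: dict
    logrank: survstats.LogRankResult | None
    manifest: dict = field(default_factory=dict)


def _load_inputs(cfg: PipelineConfig):
    if cfg.synth is not None:
        expr, surv, clinical, truth = generate_cohort(cfg.synth)
        normal = generate_normal_reference(cfg.synth)
        return expr, normal, surv, clinical, truth
    expr = io.read_expression(cfg.expression_path)
    normal = io.read_expression(cfg.normal_path)
    surv = io.read_survival(cfg.survival_path)
    clinical = (io.read_clinical(cfg.clinical_path)
                if cfg.clinical_path else None)
    return expr, normal, surv, clinical, None


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, normal, surv, clinical, truth = _load_inputs(cfg)

    # 1. differential expression + BUM-estimated FDR at the cutoff
    de = genefilter.diff_expression(expr, normal)
    try:
        bum = genefilter.fit_bum(de["p_value"].clip(lower=1e-300))
        fdr = genefilter.bum_fdr(bum, cfg.p_max)
    except ValueError:
        fdr = float("nan")  # too few genes for a stable mixture fit
    if cfg.apply_de_filter:
        selected = genefilter.select_de_genes(de, cfg.p_max, cfg.min_abs_log2fc)
        if len(selected) < 2:
            warnings.warn("DE filter kept < 2 genes; using all genes")
            selected = list(expr.index)
    else:
        selected = list(expr.index)

    # 2. correlation pruning on the selected genes
    pruned = genefilter.correlation_prune(expr.loc[selected], cfg.r_max)
    X = expr.loc[pruned]

    # 3. survival-time-stratified partitions (0 = test, 1 = validation)
    parts = genefilter.stratified_partition(surv, k=cfg.k_partitions,
                                            seed=cfg.stage_seed("partition"))

    # 4. train (or tune) the deep Cox network
    test_ids = parts.index[parts == 0]
    valid_ids = parts.index[parts == 1]
    train_ids = parts.index[parts > 1]
    if cfg.network_grid:
        best_cfg, _ = deepcox.hyperparameter_search(cfg.network_grid, X, surv,
                                                    parts)
    else:
        best_cfg = cfg.network or deepcox.NetworkConfig(
            seed=cfg.stage_seed("train"))
    model, history = deepcox.train(best_cfg, X[train_ids], surv.loc[train_ids],
                                   X[valid_ids], surv.loc[valid_ids])
    val_c = float(history["val_concordance"].max()) if len(history) else 0.5
    test_risk = deepcox.forward(model, X[test_ids]).risk
    test_c = survstats.concordance_index(test_risk.to_numpy(),
                                         surv.loc[test_ids])

    # 5. permutation importance -> occurrence signature
    imp, freq, k_min, sig = permimp.discover_signature(
        model, X, n_repeats=cfg.n_repeats, seed=cfg.stage_seed("permimp"),
        ci_level=cfg.ci_level, p_threshold=cfg.p_threshold)

    # 6. penalized-Cox comparators on the same partitions
    comparator_c = {}
    if cfg.run_comparators:
        Xmat = X.T  # samples x genes
        surv_tr = surv.loc[parts.index[parts > 1]]
        for kind in cfg.penalties:
            spec = coxpen.PenaltySpec(kind=kind)
            if kind == "adaptive_lasso":
                ridge_path = coxpen.cv_lambda_path(
                    Xmat.loc[surv_tr.index], surv_tr,
                    coxpen.PenaltySpec("ridge"), n_folds=cfg.n_cv_folds,
                    seed=cfg.stage_seed("coxpen"))
                ridge_fit = coxpen.fit_penalized_cox(
                    Xmat.loc[surv_tr.index], surv_tr,
                    coxpen.PenaltySpec("ridge"), ridge_path.lambda_min)
                spec = coxpen.PenaltySpec(
                    kind=kind, weights=coxpen.adaptive_weights(ridge_fit))
            path = coxpen.cv_lambda_path(Xmat.loc[surv_tr.index], surv_tr,
                                         spec, n_folds=cfg.n_cv_folds,
                                         seed=cfg.stage_seed("coxpen"))
            fit = coxpen.fit_penalized_cox(Xmat.loc[surv_tr.index], surv_tr,
                                           spec, path.lambda_min)
            lp = Xmat.loc[test_ids].to_numpy(float) @ fit.beta.to_numpy()
            comparator_c[kind] = survstats.concordance_index(
                lp, surv.loc[test_ids])

    # 7. signature Cox evaluation: PI median split, log-rank, KM
    logrank = None
    if len(sig) >= 1:
        sig_fit = None
        try:
            sig_fit = survstats.fit_cox_ph(X.loc[sig.gene_ids].T, surv)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            warnings.warn("signature Cox fit failed; skipping median-split "
                          "validation")
        if sig_fit is not None:
            pi = survstats.prognostic_index(sig_fit, X.loc[sig.gene_ids].T)
            try:
                groups = survstats.median_split(pi)
                logrank = survstats.logrank_test(surv, groups)
                for label in ("low_risk", "high_risk"):
                    km = survstats.km_curve(surv.loc[groups == label])
                    km.to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
            except ValueError:
                pass

    # outputs + manifest
    (out / "selected_genes.txt").write_text("\n".join(pruned) + "\n")
    parts.to_csv(out / "partitions.tsv", sep="\t")
    model.save(out / "model.json")
    imp.to_csv(out / "importance.tsv", sep="\t")
    freq.to_csv(out / "frequency.tsv", sep="\t")
    (out / "signature.txt").write_text("\n".join(sig.gene_ids) + "\n")

    manifest = {
        "config": _jsonable_config(cfg),
        "stage_seeds": {s: cfg.stage_seed(s) for s in _STAGE_OFFSET},
        "thresholds": {"p_max": cfg.p_max, "min_abs_log2fc": cfg.min_abs_log2fc,
                       "r_max": cfg.r_max, "ci_level": cfg.ci_level,
                       "p_threshold": cfg.p_threshold},
        "n_genes_selected": len(pruned),
        "bum_fdr_at_pmax": None if np.isnan(fdr) else fdr,
        "k_min": int(k_min),
        "signature_size": len(sig),
        "validation_concordance": val_c,
        "test_concordance": test_c,
        "comparator_concordance": comparator_c,
        "logrank_p": None if logrank is None else logrank.p_value,
        "files": {},
    }
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.txt")) + [out / "model.json"]:
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return PipelineResult(
        selected_genes=pruned, bum_fdr_at_pmax=fdr, partitions=parts,
        model=model, history=history, validation_concordance=val_c,
        test_concordance=test_c, importance=imp, frequency=freq,
        k_min=k_min, signature=sig, comparator_concordance=comparator_c,
        logrank=logrank, manifest=manifest,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _jsonable_config(cfg: PipelineConfig) -> dict:
    return _jsonable(asdict(cfg))
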