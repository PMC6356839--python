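"""Tab-delimited readers/writers and packaged reference fixtures.

All on-disk tables are plain tab-delimited text with a header row and the
identifier in the first column; expression is genes x samples.  Readers
validate types and invariants (unique ids, positive survival times, known
category levels) and raise errors naming the offending row or column.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .synthcohort import SUBTYPE_LEVELS, THERAPY_LEVELS

__all__ = [
    "read_expression", "write_expression",
    "read_survival", "write_survival",
    "read_clinical", "write_clinical",
    "load_reference_frequency_table", "load_reference_signature",
]


def _read_table(path, index_name):
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"parse error: duplicated id {dup!r} in {path}")
    df.index.name = index_name
    return df


def read_expression(path) -> pd.DataFrame:
    """Read a log2 gene x sample expression matrix."""
    df = _read_table(path, "gene_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"parse error: non-numeric expression value "
                         f"in {path}: {exc}") from None
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"parse error: missing value at gene {gene!r}")
    if df.columns.has_duplicates:
        raise ValueError("parse error: duplicated sample id in header")
    if df.shape[0] and df.shape[1] and df.shape[0] < df.shape[1] / 20:
        raise ValueError("expression matrix looks transposed (far more "
                         "columns than rows); expected genes as rows")
    return df


def write_expression(expr: pd.DataFrame, path):
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_survival(path) -> pd.DataFrame:
    """Read a per-sample survival table with columns ``time`` and ``event``."""
    df = _read_table(path, "sample_id")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"parse error: missing required column {col!r}")
    try:
        df = df[["time", "event"]].astype({"time": float, "event": int})
    except ValueError as exc:
        raise ValueError(f"parse error: non-numeric survival value: {exc}") from None
    if np.any(df["time"] <= 0):
        bad = df.index[df["time"] <= 0][0]
        raise ValueError(f"validation error: non-positive time at sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])][0]
        raise ValueError(f"validation error: event must be 0/1 at sample {bad!r}")
    return df


def write_survival(surv: pd.DataFrame, path):
    surv.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical covariate table, checking category levels."""
    df = _read_table(path, "sample_id")
    required = ["age", "gender", "kps", "therapy", "subtype", "mgmt",
                "gcimp", "idh_mutation"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"parse error: missing required column {col!r}")
    for col, levels in (("therapy", THERAPY_LEVELS), ("subtype", SUBTYPE_LEVELS)):
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"validation error: unknown {col} level(s) {bad}")
    for col in ("gender", "mgmt", "gcimp", "idh_mutation"):
        if not df[col].isin([0, 1]).all():
            raise ValueError(f"validation error: column {col!r} must be 0/1")
    return df[required]


def write_clinical(clinical: pd.DataFrame, path):
    clinical.to_csv(path, sep="\t", index_label="sample_id")


def _fixture_path(name: str):
    return resources.files("deepcoxsig") / "fixtures" / name


def load_reference_frequency_table() -> pd.Series:
    """Published glioblastoma gene-occurrence frequencies (top 100 genes).

    Counts of how often each gene was flagged important across the 27
    last-hidden-layer nodes of a deep survival network trained on a
    glioblastoma expression cohort; used as a worked reference input for the
    signature-extraction stage.
    """
    with resources.as_file(_fixture_path("gbm_node_occurrence_top100.tsv")) as p:
        df = pd.read_csv(p, sep="\t", index_col=0)
    return df["frequency"].astype(int)


def load_reference_signature() -> list[str]:
    """The published 39-gene glioblastoma prognostic signature."""
    with resources.as_file(_fixture_path("gbm_signature_39.txt")) as p:
        return [line.strip() for line in open(p) if line.strip()]
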