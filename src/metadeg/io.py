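"""Tab-separated interchange formats for expression matrices and annotations.

Expression TSV: rows are genes, first column the gene identifier, header row
the sample identifiers.  Annotation TSV: one row per sample with columns
``sample_id, group, pair_id, os_time, os_event, age, sex, stage``.
Missing values are written as empty fields and read back as NaN.
"""

from __future__ import annotations

import pandas as pd

ANNOTATION_COLUMNS = [
    "group",
    "pair_id",
    "os_time",
    "os_event",
    "age",
    "sex",
    "stage",
]


def read_expression(path) -> pd.DataFrame:
    """Read a genes × samples expression matrix (log2 scale) from TSV."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    if expr.index.has_duplicates:
        raise ValueError(f"duplicate gene ids in {path}")
    if expr.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return expr.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_annotation(path) -> pd.DataFrame:
    """Read the per-sample annotation table, indexed by sample_id."""
    ann = pd.read_csv(
        path, sep="\t", index_col="sample_id", dtype={"pair_id": str, "stage": str}
    )
    ann.index = ann.index.astype(str)
    if ann.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            ann[col] = pd.NA
    return ann[ANNOTATION_COLUMNS]


def write_annotation(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")
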