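"""Readers and writers for the pipeline's file formats.

GMT gene-set files (Broad dialect: name, description, member genes; ``#``
comment lines ignored), tab-separated expression matrices (header row of
sample ids, first column of gene ids), CSV clinical tables, and the TSV
result tables the pipeline emits.  Decimal point is ``.``; a missing CDAI
is an empty cell, never 0.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    DISCONTINUATION_REASONS,
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_csv",
    "write_clinical_csv",
    "write_results",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Each non-comment line must carry at least three tab-separated fields:
    set name, description, then one or more gene symbols.  Duplicate genes
    within one set are deduplicated preserving first occurrence; duplicate
    set names are an error.
    """
    collection = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]  # trailing empty fields tolerated
            if not genes:
                raise ParseError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            deduped = list(dict.fromkeys(genes))
            if name in collection:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            collection.add(GeneSet(name, description, tuple(deduped)))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
    return path


def read_expression_tsv(
    path: str | os.PathLike,
    present_path: str | os.PathLike | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    When ``present_path`` is given it must be a TSV of 0/1 or true/false
    flags with identical row and column ids.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ParseError(
            f"{path}: non-numeric value {values.loc[gene, sample]!r} "
            f"at gene {gene!r}, sample {sample!r}"
        )
    if numeric.isna().any().any():
        raise ParseError(f"{path}: empty cells are not allowed in an expression matrix")
    present = None
    if present_path is not None:
        pres = pd.read_csv(present_path, sep="\t", index_col=0)
        pres.index = pres.index.astype(str)
        pres.columns = pres.columns.astype(str)
        if pres.shape != numeric.shape:
            raise ParseError(
                f"{present_path}: present-call shape {pres.shape} does not match "
                f"expression shape {numeric.shape}"
            )
        present = pres.replace({"true": 1, "false": 0, "True": 1, "False": 0})
        present = present.astype(float).astype(bool)
        present.index = numeric.index
        present.columns = numeric.columns
    return ExpressionMatrix(numeric, present)


def write_expression_tsv(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    present_path: str | os.PathLike | None = None,
) -> Path:
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if present_path is not None:
        if matrix.present is None:
            raise ValueError("matrix carries no present calls to write")
        matrix.present.astype(int).to_csv(present_path, sep="\t", index_label="gene_id")
    return path


def read_clinical_csv(path: str | os.PathLike) -> ClinicalTable:
    """Read a clinical CSV keyed by ``sample_id``.

    Requires ``sample_id`` and ``drug_arm`` columns plus month-indexed
    ``cdai_<month>`` columns; blank CDAI cells are recorded as absent so
    downstream last-observation-carried-forward imputation can resolve them.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing sample_id column")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample_id: {dupes}")
    if "drug_arm" not in df.columns:
        raise ParseError(f"{path}: missing drug_arm column")
    cdai_cols = [c for c in df.columns if c.startswith("cdai_")]
    if not cdai_cols:
        raise ParseError(f"{path}: no month-indexed cdai_<month> columns found")
    df = df.set_index("sample_id")
    for c in cdai_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return ClinicalTable(df)


def write_clinical_csv(table: ClinicalTable, path: str | os.PathLike) -> Path:
    path = Path(path)
    table.data.to_csv(path, index_label="sample_id")
    return path


def _gsea_results_frame(results: Iterable) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "name": r.set_name,
                "size": r.size,
                "ES": r.es,
                "NES": r.nes,
                "p": r.p_nominal,
                "q": r.q_fdr,
                "direction": r.direction,
                "core_genes": ",".join(r.core_genes),
            }
        )
    return pd.DataFrame(
        rows, columns=["name", "size", "ES", "NES", "p", "q", "direction", "core_genes"]
    )


def write_results(
    out_dir: str | os.PathLike,
    gsea_results: Iterable | None = None,
    association_table: pd.DataFrame | None = None,
    roc_metrics: pd.DataFrame | None = None,
    group_table: pd.DataFrame | None = None,
    zscore_matrix: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the pipeline's result tables as TSVs into ``out_dir``.

    Emits whichever of the per-gene-set enrichment statistics, odds-ratio
    table, ROC/cutoff metrics, patient-group table, and z-score matrix
    (for external heat-mapping) are provided; returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if gsea_results is not None:
        p = out_dir / "gsea_results.tsv"
        _gsea_results_frame(gsea_results).to_csv(p, sep="\t", index=False)
        written["gsea_results"] = p
    if association_table is not None:
        p = out_dir / "association.tsv"
        association_table.to_csv(p, sep="\t", index=False)
        written["association"] = p
    if roc_metrics is not None:
        p = out_dir / "roc_metrics.tsv"
        roc_metrics.to_csv(p, sep="\t", index=False)
        written["roc_metrics"] = p
    if group_table is not None:
        p = out_dir / "groups.tsv"
        group_table.to_csv(p, sep="\t", index=False)
        written["groups"] = p
    if zscore_matrix is not None:
        p = out_dir / "zscores.tsv"
        zscore_matrix.to_csv(p, sep="\t", index_label="gene_id")
        written["zscores"] = p
    return written
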