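"""Per-cell quality-control metrics and threshold filtering.

Cells are kept only when they pass every gate: enough genes detected,
enough total UMIs, low mitochondrial fraction, a sufficiently high novelty
index (genes detected per UMI — low novelty marks low-complexity libraries
such as dying cells or ambient droplets), and, when the annotation carries
them, a doublet score and empty-droplet FDR below their cutoffs. Doublet
and empty-droplet detection themselves are not recomputed here; their
scores are consumed as optional annotation columns produced upstream.

Default thresholds: at least 500 genes, at least 750 UMIs, at most 15%
mitochondrial reads, novelty at least 0.4, doublet score at most 0.25,
empty-droplet FDR at most 0.01. All thresholds are inclusive on the
passing side.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SchemaError

__all__ = ["QCThresholds", "compute_qc_metrics", "filter_cells"]


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 500
    min_counts: int = 750
    max_pct_mito: float = 15.0
    min_novelty: float = 0.4
    max_doublet_score: float = 0.25
    max_empty_fdr: float = 0.01

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"threshold {f.name} must be nonnegative")


def compute_qc_metrics(counts: CountMatrix, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode QC metrics: n_genes, n_counts, pct_mito, novelty.

    ``genes`` is a validated gene-annotation table whose gene set must
    match the count matrix. Novelty is n_genes / n_counts, defined as 0
    for zero-count cells so they fail the novelty gate rather than
    dividing by zero.
    """
    annot_genes = set(genes["gene"])
    matrix_genes = set(counts.gene_ids)
    if annot_genes != matrix_genes:
        missing = sorted(matrix_genes - annot_genes)[:3]
        extra = sorted(annot_genes - matrix_genes)[:3]
        raise SchemaError(
            f"gene annotation does not match count matrix "
            f"(unannotated e.g. {missing}, extra e.g. {extra})"
        )
    csc = counts.values.tocsc()
    n_counts = np.asarray(csc.sum(axis=0)).ravel()
    n_genes = np.diff(csc.indptr)  # nonzeros per column
    is_mito = genes.set_index("gene").loc[counts.gene_ids, "is_mito"].to_numpy()
    mito_counts = np.asarray(csc[np.flatnonzero(is_mito), :].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_mito = np.where(n_counts > 0, 100.0 * mito_counts / n_counts, 0.0)
        novelty = np.where(n_counts > 0, n_genes / n_counts, 0.0)
    return pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "n_genes": n_genes.astype(int),
            "n_counts": n_counts.astype(int),
            "pct_mito": pct_mito,
            "novelty": novelty,
        }
    )


def filter_cells(
    metrics: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[str], pd.DataFrame]:
    """Apply every QC gate; return kept barcodes and a rejection report.

    The report has one row per barcode with boolean ``kept`` and a
    semicolon-joined ``reasons`` column listing every failed gate
    (min_genes, min_counts, max_pct_mito, min_novelty, doublet, empty).
    Missing doublet/empty columns never reject a cell.
    """
    ann = annotation.set_index("barcode")
    missing = [b for b in metrics["barcode"] if b not in ann.index]
    if missing:
        raise SchemaError(f"annotation missing barcodes e.g. {missing[:3]}")
    t = thresholds
    rows = []
    for rec in metrics.itertuples(index=False):
        reasons = []
        if rec.n_genes < t.min_genes:
            reasons.append("min_genes")
        if rec.n_counts < t.min_counts:
            reasons.append("min_counts")
        if rec.pct_mito > t.max_pct_mito:
            reasons.append("max_pct_mito")
        if rec.novelty < t.min_novelty:
            reasons.append("min_novelty")
        cell = ann.loc[rec.barcode]
        dscore = cell.get("doublet_score", np.nan)
        if pd.notna(dscore) and dscore > t.max_doublet_score:
            reasons.append("doublet")
        efdr = cell.get("empty_fdr", np.nan)
        if pd.notna(efdr) and efdr > t.max_empty_fdr:
            reasons.append("empty")
        rows.append((rec.barcode, not reasons, ";".join(reasons)))
    report = pd.DataFrame(rows, columns=["barcode", "kept", "reasons"])
    kept = report.loc[report["kept"], "barcode"].tolist()
    return kept, report
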