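"""Normalization, group average expression and Wilcoxon rank-sum DE.

Counts are log-normalized to 10,000 transcripts per cell (CP10K):
``value(g, c) = ln(1 + count(g, c) * 10000 / total(c))``. Natural log is
used for the stored matrix; fold changes are reported in log2.

Differential expression follows the marker-gene convention of the
droplet-scRNA-seq ecosystem: a gene is tested only if it is detected in at
least ``min_pct`` of one group and its |avg_log2FC| clears
``logfc_threshold`` (the 0.6 gate corresponds to a >1.5-fold linear
change, 2**0.6 ~ 1.516); p-values come from the two-sided Wilcoxon
rank-sum test — exact enumeration of rank assignments for small groups
(n_a + n_b <= 20, ties handled by mid-ranks), a tie-corrected normal
approximation otherwise — and multiple-testing adjustment is applied over
the tested genes only.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, FormatError

__all__ = [
    "NormalizedMatrix",
    "normalize",
    "average_expression",
    "avg_log2fc",
    "wilcoxon_de",
    "wilcoxon_pvalue",
    "DE_COLUMNS",
]

SCALE_FACTOR = 10_000.0

DE_COLUMNS = [
    "gene",
    "group_a",
    "group_b",
    "avg_log2fc",
    "pct_a",
    "pct_b",
    "p_value",
    "p_adjusted",
]


@dataclass
class NormalizedMatrix:
    """log1p-CP10K expression matrix (genes x cells), sparse float."""

    values: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.barcodes = list(self.barcodes)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError("normalized matrix shape does not match identifiers")

    def barcode_index(self) -> dict[str, int]:
        return {b: j for j, b in enumerate(self.barcodes)}

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def normalize(counts: CountMatrix) -> NormalizedMatrix:
    """log1p of counts scaled to 10,000 per cell; zero-total cells map to 0."""
    csc = counts.values.tocsc().astype(np.float64)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    scale = np.zeros_like(totals)
    nz = totals > 0
    scale[nz] = SCALE_FACTOR / totals[nz]
    csc = csc @ sp.diags(scale)
    csc.data = np.log1p(csc.data)
    return NormalizedMatrix(csc.tocsr(), counts.gene_ids, counts.barcodes)


def _column_indices(matrix: NormalizedMatrix, barcodes: Sequence[str]) -> np.ndarray:
    index = matrix.barcode_index()
    try:
        return np.array([index[b] for b in barcodes], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"barcode {exc.args[0]!r} not in matrix")


def average_expression(
    matrix: NormalizedMatrix,
    groups: Mapping[str, str],
    scale: str = "linear",
) -> pd.DataFrame:
    """Gene x group average-expression profile.

    ``scale="linear"`` averages de-logged values (exp(value) - 1), i.e.
    mean CP10K — the scale on which interaction scores are computed.
    ``scale="log"`` averages the log1p values directly.
    """
    if scale not in ("linear", "log"):
        raise ValueError(f"scale must be 'linear' or 'log', got {scale!r}")
    labels = sorted(set(groups.values()))
    by_label: dict[str, list[str]] = {lab: [] for lab in labels}
    for barcode, label in groups.items():
        by_label[label].append(barcode)
    out = {}
    for label in labels:
        barcodes = by_label[label]
        if not barcodes:
            raise ValueError(f"group {label!r} is empty")
        cols = _column_indices(matrix, barcodes)
        sub = matrix.values[:, cols]
        if scale == "linear":
            sub = sub.copy()
            sub.data = np.expm1(sub.data)
        out[label] = np.asarray(sub.mean(axis=1)).ravel()
    return pd.DataFrame(out, index=pd.Index(matrix.gene_ids, name="gene"))


def _group_mean_cp10k(matrix: NormalizedMatrix, cols: np.ndarray) -> np.ndarray:
    sub = matrix.values[:, cols].copy()
    sub.data = np.expm1(sub.data)
    return np.asarray(sub.mean(axis=1)).ravel()


def avg_log2fc(
    matrix: NormalizedMatrix,
    gene: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> float:
    """log2((mean CP10K in A + pc) / (mean CP10K in B + pc)), pc = 1.

    The pseudocount sits on the de-logged mean scale, so the statistic is
    antisymmetric in its groups and zero for equal means.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("groups must be non-empty")
    gi = matrix.gene_index()[gene]
    mean_a = _group_mean_cp10k(matrix, _column_indices(matrix, group_a))[gi]
    mean_b = _group_mean_cp10k(matrix, _column_indices(matrix, group_b))[gi]
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum p-values
# ---------------------------------------------------------------------------

#: Largest pooled size for which the exact null is enumerated.
EXACT_LIMIT = 20


@functools.lru_cache(maxsize=32)
def _combination_matrix(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets as a (C(n,k), k) int array."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _exact_pvalue(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-sided exact p by enumeration of all rank assignments.

    Ties enter through mid-ranks of the pooled sample; the null permutes
    group labels over the pooled values, so the p-value is the doubled
    smaller tail mass of the group-A mid-rank sum (capped at 1).
    """
    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)
    n, n_a = len(pooled), len(values_a)
    w_obs = ranks[:n_a].sum()
    combos = _combination_matrix(n, n_a)
    w_all = ranks[combos].sum(axis=1)
    eps = 1e-9
    lower = np.mean(w_all <= w_obs + eps)
    upper = np.mean(w_all >= w_obs - eps)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _normal_pvalue(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-sided normal approximation with mid-rank tie correction."""
    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)
    n, n_a = len(pooled), len(values_a)
    n_b = n - n_a
    w = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1.0))
    var = n_a * n_b / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_pvalue(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when n_a + n_b <= 20, tie-corrected normal
    approximation (no continuity correction) otherwise.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if len(values_a) == 0 or len(values_b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(values_a) + len(values_b) <= EXACT_LIMIT:
        return _exact_pvalue(values_a, values_b)
    return _normal_pvalue(values_a, values_b)


def wilcoxon_de(
    matrix: NormalizedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_pct: float = 0.25,
    logfc_threshold: float = 0.6,
    only_pos: bool = False,
    adjust: str = "bh",
    label_a: str = "A",
    label_b: str = "B",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Gated Wilcoxon rank-sum differential expression between two groups.

    Gates are applied before testing — detection fraction first
    (max(pct_a, pct_b) >= min_pct), then effect size (avg_log2fc >=
    logfc_threshold when ``only_pos``, |avg_log2fc| >= threshold
    otherwise) — so the multiple-testing adjustment runs over the tested
    set only. Returns one row per reported gene (columns ``DE_COLUMNS``),
    sorted by adjusted then raw p-value.
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError(f"adjust must be 'bh' or 'bonferroni', got {adjust!r}")
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    cols_a = _column_indices(matrix, group_a)
    cols_b = _column_indices(matrix, group_b)
    sub_a = matrix.values[:, cols_a]
    sub_b = matrix.values[:, cols_b]
    pct_a = np.diff(sub_a.tocsr().indptr) / len(cols_a)
    pct_b = np.diff(sub_b.tocsr().indptr) / len(cols_b)
    mean_a = _group_mean_cp10k(matrix, cols_a)
    mean_b = _group_mean_cp10k(matrix, cols_b)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    pct_gate = np.maximum(pct_a, pct_b) >= min_pct
    fc_gate = (lfc >= logfc_threshold) if only_pos else (np.abs(lfc) >= logfc_threshold)
    tested = np.flatnonzero(pct_gate & fc_gate)

    dense_a = np.asarray(sub_a[tested, :].todense()) if tested.size else None
    dense_b = np.asarray(sub_b[tested, :].todense()) if tested.size else None
    pvals = np.array(
        [wilcoxon_pvalue(dense_a[i], dense_b[i]) for i in range(tested.size)]
    )
    if tested.size:
        method = "fdr_bh" if adjust == "bh" else "bonferroni"
        padj = multipletests(pvals, method=method)[1]
        padj = np.maximum(padj, pvals)  # adjusted p never below raw p
    else:
        padj = pvals
    result = pd.DataFrame(
        {
            "gene": [matrix.gene_ids[i] for i in tested],
            "group_a": label_a,
            "group_b": label_b,
            "avg_log2fc": lfc[tested],
            "pct_a": pct_a[tested],
            "pct_b": pct_b[tested],
            "p_value": pvals,
            "p_adjusted": padj,
        }
    )
    return result.sort_values(
        ["p_adjusted", "p_value", "gene"], kind="stable"
    ).reset_index(drop=True)
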