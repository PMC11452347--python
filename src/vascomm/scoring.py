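"""Ligand-receptor interaction scoring with a bootstrap-calibrated cutoff.

The interaction score for an ordered ligand-receptor pair is the product
of the ligand's average expression in the sender subtype and the
receptor's average expression in the receiver subtype, both on the linear
CP10K scale (mean of exp(log1p value) - 1). Significance is calibrated
against a bootstrap null: per iteration, cells are resampled with
replacement independently within sender and receiver, average expression
is recomputed, and scores are formed between randomly drawn ligands and
as many random pseudo-receptor genes as the database holds; pooling
across iterations yields the null distribution. Each observed score gets
a one-sided upper-tail empirical p-value with the add-one estimator,
Bonferroni-corrected over the pairs scored in the comparison.

A receiver profile may alternatively come from an external segment-level
average-expression table (e.g. spatial profiling of a subtype the
droplet data undersamples); such a profile is used as-is and is not
resampled in the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import NormalizedMatrix, normalize
from .io_formats import CountMatrix
from .lr_database import LRDatabase

__all__ = [
    "ComparisonSpec",
    "NullDistribution",
    "interaction_score",
    "bootstrap_null",
    "empirical_pvalue",
    "determine_cutoff",
    "score_pairs",
    "exclude_nonspecific",
    "summarize",
    "ingest_external_profile",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "ligand",
    "receptor",
    "display_name",
    "provenance",
    "sender",
    "receiver",
    "region",
    "score",
    "p_raw",
    "p_bonferroni",
    "significant",
    "excluded_nonspecific",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """One sender -> receiver comparison, within a single region.

    Cross-region comparisons are disallowed by default: signaling is
    modeled between physically adjacent cells.
    """

    sender_region: str
    sender_subtype: str
    receiver_region: str
    receiver_subtype: str
    receiver_profile_source: str = "cells"  # "cells" | "external_profile"
    allow_cross_region: bool = False

    def __post_init__(self) -> None:
        if self.receiver_profile_source not in ("cells", "external_profile"):
            raise ValueError(
                f"invalid receiver_profile_source {self.receiver_profile_source!r}"
            )
        if self.sender_region != self.receiver_region and not self.allow_cross_region:
            raise ValueError(
                "cross-region comparison "
                f"{self.sender_region}->{self.receiver_region} disallowed by default"
            )

    @property
    def sender(self) -> tuple[str, str]:
        return (self.sender_region, self.sender_subtype)

    @property
    def receiver(self) -> tuple[str, str]:
        return (self.receiver_region, self.receiver_subtype)


@dataclass
class NullDistribution:
    """Pooled bootstrap null scores: |scores| = n_iterations x n_random_genes."""

    scores: np.ndarray
    n_iterations: int
    n_random_genes: int
    seed: int
    _sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if self.scores.size != self.n_iterations * self.n_random_genes:
            raise ValueError(
                f"null has {self.scores.size} scores, expected "
                f"{self.n_iterations} x {self.n_random_genes}"
            )
        if self.scores.size and self.scores.min() < 0:
            raise ValueError("null scores must be nonnegative")
        self._sorted = np.sort(self.scores)


def _as_normalized(matrix: CountMatrix | NormalizedMatrix) -> NormalizedMatrix:
    if isinstance(matrix, CountMatrix):
        return normalize(matrix)
    return matrix


def _group_columns(
    annotation: pd.DataFrame, region: str, subtype: str
) -> np.ndarray:
    mask = (annotation["region"] == region) & (annotation["subtype"] == subtype)
    return np.flatnonzero(mask.to_numpy())


def _linear_dense(matrix: NormalizedMatrix, cols: np.ndarray) -> np.ndarray:
    """Dense genes x cells CP10K block for the given columns."""
    sub = matrix.values[:, cols].copy()
    sub.data = np.expm1(sub.data)
    return np.asarray(sub.todense())


def group_profile(
    matrix: CountMatrix | NormalizedMatrix,
    annotation: pd.DataFrame,
    region: str,
    subtype: str,
) -> pd.Series:
    """Linear average-expression profile of one (region, subtype) group."""
    norm_mat = _as_normalized(matrix)
    cols = _group_columns(annotation, region, subtype)
    if cols.size == 0:
        raise ValueError(f"no cells for group ({region!r}, {subtype!r})")
    means = _linear_dense(norm_mat, cols).mean(axis=1)
    return pd.Series(means, index=norm_mat.gene_ids, name=f"{region}:{subtype}")


def interaction_score(
    profiles: Mapping[tuple[str, str], pd.Series],
    ligand: str,
    receptor: str,
    comparison: ComparisonSpec,
) -> float | None:
    """avg ligand expression (sender) x avg receptor expression (receiver).

    Returns None (pair skipped, with a warning) when either gene is
    missing from its profile.
    """
    sender_profile = profiles[comparison.sender]
    receiver_profile = profiles[comparison.receiver]
    if ligand not in sender_profile.index:
        logger.warning("ligand %r missing from sender profile; pair skipped", ligand)
        return None
    if receptor not in receiver_profile.index:
        logger.warning(
            "receptor %r missing from receiver profile; pair skipped", receptor
        )
        return None
    return float(sender_profile[ligand] * receiver_profile[receptor])


def _bootstrap_means(
    block: np.ndarray, n_iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """Genes x n_iterations matrix of resampled-with-replacement means."""
    n_cells = block.shape[1]
    # multinomial cell weights are equivalent to drawing n_cells cells
    # with replacement, but let the resampled mean be a single matmul
    weights = rng.multinomial(n_cells, np.full(n_cells, 1.0 / n_cells), size=n_iterations)
    return block @ (weights.T / n_cells)


def bootstrap_null(
    matrix: CountMatrix | NormalizedMatrix,
    annotation: pd.DataFrame,
    comparison: ComparisonSpec,
    database_size: int,
    ligand_pool: Sequence[str],
    n_iterations: int = 1000,
    seed: int = 0,
    external_profile: pd.Series | None = None,
) -> NullDistribution:
    """Bootstrap null distribution of interaction scores.

    Per iteration: resample cells with replacement independently within
    sender and receiver, recompute linear average expression, draw
    ``database_size`` pseudo-receptor genes uniformly without replacement
    from the detected genes, pair each with a ligand drawn uniformly from
    ``ligand_pool``, and record the product scores. Scores are pooled
    over iterations.

    When the comparison's receiver comes from an external profile, the
    receiver side is the fixed profile (pseudo-receptors are drawn from
    its genes) and only the sender is resampled.

    Randomness is consumed in a fixed, documented order from a single
    ``numpy`` generator seeded with ``seed``: (1) one multinomial of cell
    weights per sender iteration (a single call of size n_iterations),
    (2) the same for the receiver (skipped for an external profile),
    (3) one uniform key per (iteration, gene) — the ``database_size``
    genes with the smallest keys are that iteration's pseudo-receptors,
    in ascending key order, (4) one uniform ligand index per
    (iteration, pseudo-receptor). This contract is what makes the null
    reproducible by an independent reference implementation.
    """
    norm_mat = _as_normalized(matrix)
    rng = np.random.default_rng(seed)
    gene_index = norm_mat.gene_index()

    sender_cols = _group_columns(
        annotation, comparison.sender_region, comparison.sender_subtype
    )
    if sender_cols.size == 0:
        raise ValueError(f"sender group {comparison.sender} is empty")
    sender_block = _linear_dense(norm_mat, sender_cols)

    pool = [g for g in ligand_pool if g in gene_index]
    if len(pool) < len(ligand_pool):
        logger.warning(
            "%d ligand-pool genes absent from matrix; ignored",
            len(ligand_pool) - len(pool),
        )
    if not pool:
        raise ValueError("ligand pool is empty after matching to the matrix")
    pool_rows = np.array([gene_index[g] for g in pool], dtype=np.intp)

    use_external = comparison.receiver_profile_source == "external_profile"
    if use_external:
        if external_profile is None:
            raise ValueError("comparison requires an external receiver profile")
        receiver_values = external_profile.to_numpy(dtype=float)
        n_receiver_genes = receiver_values.size
    else:
        receiver_cols = _group_columns(
            annotation, comparison.receiver_region, comparison.receiver_subtype
        )
        if receiver_cols.size == 0:
            raise ValueError(f"receiver group {comparison.receiver} is empty")
        receiver_block = _linear_dense(norm_mat, receiver_cols)
        # pseudo-receptors come from genes detected anywhere in the dataset
        detected = np.flatnonzero(
            np.asarray((norm_mat.values > 0).sum(axis=1)).ravel() > 0
        )
        n_receiver_genes = detected.size
    if database_size > n_receiver_genes:
        raise ValueError(
            f"database_size {database_size} exceeds the "
            f"{n_receiver_genes} available pseudo-receptor genes"
        )

    sender_means = _bootstrap_means(sender_block, n_iterations, rng)
    if use_external:
        receiver_means = None
    else:
        receiver_means = _bootstrap_means(receiver_block, n_iterations, rng)

    # per-iteration draw of pseudo-receptor genes without replacement:
    # the database_size smallest of one uniform key per gene, in key order
    keys = rng.random((n_iterations, n_receiver_genes))
    pseudo_idx = np.argsort(keys, axis=1, kind="stable")[:, :database_size]
    lig_idx = rng.integers(0, len(pool_rows), size=(n_iterations, database_size))

    iter_cols = np.repeat(np.arange(n_iterations), database_size)
    lig_rows = pool_rows[lig_idx].ravel()
    lig_vals = sender_means[lig_rows, iter_cols]
    if use_external:
        rec_vals = receiver_values[pseudo_idx.ravel()]
    else:
        rec_rows = detected[pseudo_idx].ravel()
        rec_vals = receiver_means[rec_rows, iter_cols]
    scores = lig_vals * rec_vals
    return NullDistribution(scores, n_iterations, database_size, seed)


def empirical_pvalue(null: NullDistribution, score: float) -> float:
    """One-sided upper-tail add-one empirical p: (1 + #{null >= s}) / (1 + N)."""
    n = null._sorted.size
    if n == 0:
        raise ValueError("null distribution is empty")
    n_ge = n - np.searchsorted(null._sorted, score, side="left")
    return float((1 + n_ge) / (1 + n))


def determine_cutoff(
    scores: Iterable[float],
    null: NullDistribution,
    alpha: float = 0.01,
    m: int | None = None,
) -> float:
    """Smallest observed score whose Bonferroni-corrected one-sided
    empirical p falls below ``alpha``; +inf when none qualifies.

    ``m`` defaults to the number of finite observed scores (the
    comparison's family size).
    """
    obs = np.asarray([s for s in scores if s is not None and np.isfinite(s)])
    if m is None:
        m = obs.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    qualifying = [s for s in obs if empirical_pvalue(null, s) * m < alpha]
    return float(min(qualifying)) if qualifying else float("inf")


def score_pairs(
    matrix: CountMatrix | NormalizedMatrix,
    annotation: pd.DataFrame,
    database: LRDatabase,
    comparison: ComparisonSpec,
    alpha: float = 0.01,
    n_iterations: int = 1000,
    seed: int = 0,
    external_profile: pd.Series | None = None,
    fixed_cutoff: float | None = None,
) -> pd.DataFrame:
    """Score every database pair for one comparison and call significance.

    Pipeline: linear average-expression profiles for sender and receiver
    -> product score per pair -> bootstrap null (same seed policy) ->
    add-one empirical p, Bonferroni-corrected over the pairs scored in
    this comparison -> significant iff corrected p < alpha and score > 0.
    ``fixed_cutoff`` bypasses the calibrated threshold and calls any
    score strictly above it significant (the corrected p is still
    reported). Pairs with a gene missing from its profile are reported
    with NaN score and never significant.
    """
    norm_mat = _as_normalized(matrix)
    sender_profile = group_profile(
        norm_mat, annotation, comparison.sender_region, comparison.sender_subtype
    )
    if comparison.receiver_profile_source == "external_profile":
        if external_profile is None:
            raise ValueError("comparison requires an external receiver profile")
        receiver_profile = external_profile
    else:
        receiver_profile = group_profile(
            norm_mat,
            annotation,
            comparison.receiver_region,
            comparison.receiver_subtype,
        )
    profiles = {
        comparison.sender: sender_profile,
        comparison.receiver: receiver_profile,
    }

    raw_scores = [
        interaction_score(profiles, p.ligand, p.receptor, comparison)
        for p in database.pairs
    ]
    m = sum(s is not None for s in raw_scores)
    if m == 0:
        raise ValueError("no database pair could be scored for this comparison")

    # ligands considered for the null: database ligands detected in >= 1
    # sender cell; undetected ligands still appear in the output with
    # score 0 rather than being dropped
    sender_cols = _group_columns(
        annotation, comparison.sender_region, comparison.sender_subtype
    )
    detected_sender = set(
        np.array(norm_mat.gene_ids)[
            np.flatnonzero(
                np.asarray((norm_mat.values[:, sender_cols] > 0).sum(axis=1)).ravel()
            )
        ]
    )
    ligand_pool = [g for g in database.ligands() if g in detected_sender]
    if not ligand_pool:
        ligand_pool = [g for g in database.ligands() if g in set(norm_mat.gene_ids)]

    null = bootstrap_null(
        norm_mat,
        annotation,
        comparison,
        database_size=database.size,
        ligand_pool=ligand_pool,
        n_iterations=n_iterations,
        seed=seed,
        external_profile=external_profile,
    )

    rows = []
    for pair, score in zip(database.pairs, raw_scores):
        if score is None:
            rows.append((pair, np.nan, np.nan, np.nan, False))
            continue
        p_raw = empirical_pvalue(null, score)
        p_bonf = min(1.0, p_raw * m)
        if fixed_cutoff is not None:
            significant = score > fixed_cutoff
        else:
            significant = p_bonf < alpha
        significant = bool(significant and score > 0)
        rows.append((pair, score, p_raw, p_bonf, significant))

    return pd.DataFrame(
        {
            "ligand": [r[0].ligand for r in rows],
            "receptor": [r[0].receptor for r in rows],
            "display_name": [r[0].display_name for r in rows],
            "provenance": [r[0].provenance for r in rows],
            "sender": comparison.sender_subtype,
            "receiver": comparison.receiver_subtype,
            "region": comparison.sender_region,
            "score": [r[1] for r in rows],
            "p_raw": [r[2] for r in rows],
            "p_bonferroni": [r[3] for r in rows],
            "significant": [r[4] for r in rows],
            "excluded_nonspecific": False,
        }
    )


def exclude_nonspecific(
    pericyte_results: pd.DataFrame,
    all_celltype_significance: Mapping[tuple[str, str], set[str]],
    all_subtypes: set[str],
    pericyte_subtype: str = "pericyte",
) -> pd.DataFrame:
    """Flag pericyte pairs significant in every receiver subtype except
    pericytes as methodological artifacts.

    A pair is excluded iff its set of significant receiver subtypes
    equals ``all_subtypes`` minus the pericyte subtype — i.e. it looks
    ubiquitous everywhere else while missing precisely in pericytes.
    Excluded pairs lose their significant flag.
    """
    target = set(all_subtypes) - {pericyte_subtype}
    out = pericyte_results.copy()
    excluded = []
    for row in out.itertuples(index=False):
        sig_set = set(all_celltype_significance.get((row.ligand, row.receptor), set()))
        excluded.append(sig_set == target)
    out["excluded_nonspecific"] = excluded
    out.loc[out["excluded_nonspecific"], "significant"] = False
    return out


def summarize(results: Iterable[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Tidy count table of significant, non-excluded pairs.

    One row per (region, sender, receiver) present in the input, zero
    counts included — the scaffold an alluvial plot is drawn from.
    """
    if isinstance(results, pd.DataFrame):
        combined = results
    else:
        combined = pd.concat(list(results), ignore_index=True)
    keys = ["region", "sender", "receiver"]
    scaffold = combined[keys].drop_duplicates().sort_values(keys)
    hits = combined[combined["significant"] & ~combined["excluded_nonspecific"]]
    counts = hits.groupby(keys).size().rename("n_significant").reset_index()
    out = scaffold.merge(counts, on=keys, how="left").fillna({"n_significant": 0})
    out["n_significant"] = out["n_significant"].astype(int)
    return out.reset_index(drop=True)


def ingest_external_profile(
    profile_table: pd.DataFrame, subtype_label: str
) -> pd.Series:
    """Turn a segment-level average-expression table into a receiver profile.

    The table needs ``gene`` and ``value`` columns; values are used as-is
    as linear average expression for ``subtype_label``. Duplicate genes
    and empty tables are rejected.
    """
    for col in ("gene", "value"):
        if col not in profile_table.columns:
            raise ValueError(f"external profile missing column {col!r}")
    if len(profile_table) == 0:
        raise ValueError("external profile is empty")
    if profile_table["gene"].duplicated().any():
        dup = profile_table.loc[profile_table["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"external profile has duplicate gene {dup!r}")
    values = pd.to_numeric(profile_table["value"], errors="raise")
    return pd.Series(values.to_numpy(dtype=float),
                     index=profile_table["gene"].tolist(),
                     name=subtype_label)
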