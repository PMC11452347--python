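"""Interaction scoring, bootstrap null, cutoff and exclusion logic.

The whole scoring path is checked against a brute-force reference
implemented with plain loops: it consumes the generator's documented
draw order (sender weights, receiver weights, pseudo-receptor keys,
ligand indices) and redoes the normalization, averaging, resampling,
pairing, tail counting and Bonferroni logic independently of the
package's sparse/vectorized code.
"""

import numpy as np
import pandas as pd
import pytest

from vascomm import (
    ComparisonSpec,
    LRDatabase,
    LRPair,
    NullDistribution,
    bootstrap_null,
    determine_cutoff,
    empirical_pvalue,
    exclude_nonspecific,
    ingest_external_profile,
    interaction_score,
    normalize,
    score_pairs,
    summarize,
)

from conftest import make_counts


def make_null(scores, seed=0):
    scores = np.asarray(scores, dtype=float)
    return NullDistribution(scores, n_iterations=1, n_random_genes=scores.size, seed=seed)


class TestInteractionScore:
    def comparison(self):
        return ComparisonSpec("ME", "S", "ME", "R")

    def profiles(self, sender, receiver):
        return {("ME", "S"): sender, ("ME", "R"): receiver}

    def test_product_of_averages(self):
        prof = self.profiles(pd.Series({"L": 8.0}), pd.Series({"R": 5.0}))
        assert interaction_score(prof, "L", "R", self.comparison()) == 40.0

    def test_zero_ligand_is_absorbing(self):
        prof = self.profiles(pd.Series({"L": 0.0}), pd.Series({"R": 7.0}))
        assert interaction_score(prof, "L", "R", self.comparison()) == 0.0

    def test_missing_gene_returns_none(self):
        prof = self.profiles(pd.Series({"L": 1.0}), pd.Series({"R": 1.0}))
        assert interaction_score(prof, "nope", "R", self.comparison()) is None


class TestEmpiricalPvalue:
    def test_direct_tail_count(self):
        assert empirical_pvalue(make_null([1, 2, 3, 4]), 2.5) == pytest.approx(0.6)

    def test_minimum_attainable_p(self):
        null = make_null(np.arange(100, dtype=float))
        assert empirical_pvalue(null, 1e9) == pytest.approx(1 / 101)

    def test_score_zero_has_p_one(self):
        assert empirical_pvalue(make_null([0.0, 0.5, 1.0]), 0.0) == 1.0

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(1)
        null = make_null(rng.exponential(size=500))
        scores = np.sort(rng.exponential(size=50))
        ps = [empirical_pvalue(null, s) for s in scores]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestDetermineCutoff:
    def test_bonferroni_identity_at_m_one(self):
        rng = np.random.default_rng(2)
        null = make_null(rng.uniform(0, 1, 9999))
        scores = np.linspace(0, 1, 201)
        cutoff = determine_cutoff(scores, null, alpha=0.01, m=1)
        # m=1: the raw alpha tail quantile of the null
        assert cutoff == pytest.approx(np.quantile(null.scores, 0.99), abs=0.02)

    def test_uniform_oracle_with_bonferroni_family(self):
        rng = np.random.default_rng(3)
        null = make_null(rng.uniform(0, 1, 10_000))
        scores = rng.uniform(0, 1, 2000)
        cutoff = determine_cutoff(scores, null, alpha=0.01, m=10)
        # p*m < 0.01 -> p < 1e-3 -> the 0.999 quantile of uniform(0,1)
        assert cutoff == pytest.approx(0.999, abs=0.005)

    def test_null_all_zero_makes_any_positive_score_significant(self):
        null = make_null(np.zeros(10_000))
        assert determine_cutoff([0.1], null, alpha=0.01, m=5) == pytest.approx(0.1)

    def test_infinite_sentinel_when_nothing_qualifies(self):
        null = make_null(np.ones(10))
        assert determine_cutoff([0.5], null, alpha=0.01, m=1) == np.inf


class TestBootstrapNull:
    def setup_case(self):
        rng = np.random.default_rng(4)
        counts = make_counts(rng.integers(0, 20, size=(6, 8)))
        cells = pd.DataFrame(
            {
                "barcode": counts.barcodes,
                "region": "ME",
                "subtype": ["S"] * 4 + ["R"] * 4,
                "doublet_score": np.nan,
                "empty_fdr": np.nan,
            }
        )
        return counts, cells, ComparisonSpec("ME", "S", "ME", "R")

    def test_size_contract(self):
        counts, cells, comp = self.setup_case()
        null = bootstrap_null(counts, cells, comp, database_size=3,
                              ligand_pool=["g0", "g1"], n_iterations=2, seed=0)
        assert null.scores.size == 6

    def test_fixed_seed_identical_multiset(self):
        counts, cells, comp = self.setup_case()
        kwargs = dict(database_size=3, ligand_pool=["g0"], n_iterations=5, seed=9)
        a = bootstrap_null(counts, cells, comp, **kwargs)
        b = bootstrap_null(counts, cells, comp, **kwargs)
        assert np.array_equal(a.scores, b.scores)

    def test_all_zero_receiver_gives_zero_null(self):
        dense = np.zeros((4, 8), dtype=int)
        dense[:, :4] = 5  # sender expresses, receiver silent
        counts = make_counts(dense)
        cells = pd.DataFrame(
            {"barcode": counts.barcodes, "region": "ME",
             "subtype": ["S"] * 4 + ["R"] * 4,
             "doublet_score": np.nan, "empty_fdr": np.nan}
        )
        comp = ComparisonSpec("ME", "S", "ME", "R")
        null = bootstrap_null(counts, cells, comp, database_size=2,
                              ligand_pool=["g0"], n_iterations=3, seed=1)
        assert (null.scores == 0).all()

    def test_database_size_exceeding_gene_pool_rejected(self):
        counts, cells, comp = self.setup_case()
        with pytest.raises(ValueError, match="database_size"):
            bootstrap_null(counts, cells, comp, database_size=100,
                           ligand_pool=["g0"], n_iterations=1, seed=0)


# ---------------------------------------------------------------------------
# brute-force reference for the whole scoring path
# ---------------------------------------------------------------------------


def brute_force_score_path(counts, cells, database, comparison, alpha,
                           n_iterations, seed):
    """Plain-loop reimplementation of score_pairs for a tiny instance."""
    genes = counts.gene_ids
    dense = counts.values.toarray().astype(float)
    n_genes, n_cells = dense.shape
    cp10k = np.zeros_like(dense)
    for j in range(n_cells):
        tot = dense[:, j].sum()
        if tot > 0:
            for i in range(n_genes):
                cp10k[i, j] = np.expm1(np.log1p(dense[i, j] * 10_000.0 / tot))

    def group_cols(region, subtype):
        return [
            j
            for j, (r, s) in enumerate(zip(cells["region"], cells["subtype"]))
            if (r, s) == (region, subtype)
        ]

    s_cols = group_cols(comparison.sender_region, comparison.sender_subtype)
    r_cols = group_cols(comparison.receiver_region, comparison.receiver_subtype)
    sender_profile = {g: cp10k[i, s_cols].mean() for i, g in enumerate(genes)}
    receiver_profile = {g: cp10k[i, r_cols].mean() for i, g in enumerate(genes)}
    obs_scores = [
        sender_profile[p.ligand] * receiver_profile[p.receptor]
        for p in database.pairs
    ]
    m = len(obs_scores)

    # ligand pool: database ligands detected in >= 1 sender cell, db order
    pool = []
    for p in database.pairs:
        gi = genes.index(p.ligand)
        if p.ligand not in pool and any(dense[gi, j] > 0 for j in s_cols):
            pool.append(p.ligand)
    detected = [i for i in range(n_genes) if dense[i, :].sum() > 0]
    db_size = database.size

    rng = np.random.default_rng(seed)
    w_s = rng.multinomial(len(s_cols), np.full(len(s_cols), 1 / len(s_cols)),
                          size=n_iterations)
    w_r = rng.multinomial(len(r_cols), np.full(len(r_cols), 1 / len(r_cols)),
                          size=n_iterations)
    keys = rng.random((n_iterations, len(detected)))
    lig_idx = rng.integers(0, len(pool), size=(n_iterations, db_size))

    null = []
    for it in range(n_iterations):
        boot_sender = {
            g: sum(cp10k[i, s_cols[k]] * (w_s[it, k] / len(s_cols))
                   for k in range(len(s_cols)))
            for i, g in enumerate(genes)
        }
        boot_receiver = {
            g: sum(cp10k[i, r_cols[k]] * (w_r[it, k] / len(r_cols))
                   for k in range(len(r_cols)))
            for i, g in enumerate(genes)
        }
        order = np.argsort(keys[it], kind="stable")[:db_size]
        for k, gpos in enumerate(order):
            lig = pool[lig_idx[it, k]]
            rec = genes[detected[gpos]]
            null.append(boot_sender[lig] * boot_receiver[rec])
    null = np.array(null)

    rows = []
    for score in obs_scores:
        p_raw = (1 + int((null >= score).sum())) / (1 + null.size)
        p_bonf = min(1.0, p_raw * m)
        rows.append((score, p_raw, p_bonf, bool(p_bonf < alpha and score > 0)))
    return rows


def test_scoring_path_matches_brute_force_reference():
    """<= 5-gene, 4-cells-per-group instance, 3 iterations, fixed seed:
    the sparse/vectorized path and the loop reference agree exactly."""
    rng = np.random.default_rng(12)
    counts = make_counts(rng.integers(0, 30, size=(5, 8)))
    cells = pd.DataFrame(
        {"barcode": counts.barcodes, "region": "ME",
         "subtype": ["S"] * 4 + ["R"] * 4,
         "doublet_score": np.nan, "empty_fdr": np.nan}
    )
    database = LRDatabase(
        [
            LRPair("g0", "g1", "established", "G0–G1"),
            LRPair("g2", "g3", "candidate", "g2–g3"),
            LRPair("g1", "g4", "candidate", "g1–g4"),
        ]
    )
    comparison = ComparisonSpec("ME", "S", "ME", "R")
    seed = 2024
    results = score_pairs(counts, cells, database, comparison,
                          alpha=0.25, n_iterations=3, seed=seed)
    expected = brute_force_score_path(counts, cells, database, comparison,
                                      alpha=0.25, n_iterations=3, seed=seed)
    for row, (score, p_raw, p_bonf, significant) in zip(
        results.itertuples(index=False), expected
    ):
        assert row.score == pytest.approx(score, rel=1e-12)
        assert row.p_raw == p_raw
        assert row.p_bonferroni == p_bonf
        assert row.significant == significant


def test_score_pairs_deterministic_under_fixed_seed(default_dataset):
    from vascomm import build_database

    ds = default_dataset
    db = build_database(ds.reference_pairs, [], ds.genes, ds.ppi)
    comp = ComparisonSpec("ME", "cEC", "ME", "pericyte")
    norm = normalize(ds.counts)
    a = score_pairs(norm, ds.cells, db, comp, n_iterations=20, seed=5)
    b = score_pairs(norm, ds.cells, db, comp, n_iterations=20, seed=5)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# nonspecific exclusion & summaries
# ---------------------------------------------------------------------------


def peri_results(pairs):
    return pd.DataFrame(
        {
            "ligand": [p[0] for p in pairs],
            "receptor": [p[1] for p in pairs],
            "display_name": [f"{p[0]}–{p[1]}" for p in pairs],
            "provenance": "established",
            "sender": "cEC",
            "receiver": "pericyte",
            "region": "ME",
            "score": 50.0,
            "p_raw": 0.001,
            "p_bonferroni": 0.005,
            "significant": True,
            "excluded_nonspecific": False,
        }
    )


class TestExcludeNonspecific:
    SUBTYPES = {"pericyte", "astrocyte", "fibroblast", "tanycyte"}

    def test_pair_significant_only_in_pericytes_is_retained(self):
        res = exclude_nonspecific(
            peri_results([("L", "R")]), {("L", "R"): {"pericyte"}}, self.SUBTYPES
        )
        assert not res["excluded_nonspecific"].iloc[0]
        assert res["significant"].iloc[0]

    def test_pair_significant_everywhere_except_pericytes_is_excluded(self):
        sig = {("L", "R"): {"astrocyte", "fibroblast", "tanycyte"}}
        res = exclude_nonspecific(peri_results([("L", "R")]), sig, self.SUBTYPES)
        assert res["excluded_nonspecific"].iloc[0]
        assert not res["significant"].iloc[0]

    def test_pair_significant_in_all_subtypes_is_retained(self):
        sig = {("L", "R"): set(self.SUBTYPES)}
        res = exclude_nonspecific(peri_results([("L", "R")]), sig, self.SUBTYPES)
        assert not res["excluded_nonspecific"].iloc[0]


class TestSummarize:
    def test_zero_table_keeps_row_scaffold(self):
        res = peri_results([("L", "R")])
        res["significant"] = False
        out = summarize(res)
        assert len(out) == 1 and out["n_significant"].iloc[0] == 0

    def test_counts_ground_truth_bookkeeping(self):
        res = peri_results([("L1", "R1"), ("L2", "R2"), ("L3", "R3")])
        out = summarize(res)
        row = out.set_index(["region", "sender", "receiver"]).loc[("ME", "cEC", "pericyte")]
        assert row["n_significant"] == 3

    def test_permutation_invariance(self):
        res = peri_results([("L1", "R1"), ("L2", "R2")])
        shuffled = res.iloc[::-1].reset_index(drop=True)
        pd.testing.assert_frame_equal(summarize(res), summarize(shuffled))

    def test_excluded_pairs_not_counted(self):
        res = peri_results([("L1", "R1"), ("L2", "R2")])
        res.loc[0, "excluded_nonspecific"] = True
        res.loc[0, "significant"] = False
        out = summarize(res)
        assert out["n_significant"].iloc[0] == 1


class TestExternalProfile:
    def test_profile_used_as_linear_average(self):
        profile = ingest_external_profile(
            pd.DataFrame({"gene": ["R"], "value": [5.0]}), "pericyte"
        )
        prof = {("ME", "S"): pd.Series({"L": 8.0}), ("ME", "pericyte"): profile}
        comp = ComparisonSpec("ME", "S", "ME", "pericyte",
                              receiver_profile_source="external_profile")
        assert interaction_score(prof, "L", "R", comp) == 40.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ingest_external_profile(pd.DataFrame({"gene": [], "value": []}), "x")

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ingest_external_profile(
                pd.DataFrame({"gene": ["R", "R"], "value": [1.0, 2.0]}), "x"
            )

    def test_profile_genes_absent_from_matrix_are_scoreable(self):
        counts = make_counts(np.array([[3, 4, 0, 0], [1, 2, 5, 6]]))
        cells = pd.DataFrame(
            {"barcode": counts.barcodes, "region": "ME",
             "subtype": ["S", "S", "pericyte", "pericyte"],
             "doublet_score": np.nan, "empty_fdr": np.nan}
        )
        database = LRDatabase([LRPair("g0", "EXT", "candidate", "g0–EXT")])
        profile = ingest_external_profile(
            pd.DataFrame({"gene": ["EXT", "other"], "value": [2.0, 1.0]}), "pericyte"
        )
        comp = ComparisonSpec("ME", "S", "ME", "pericyte",
                              receiver_profile_source="external_profile")
        res = score_pairs(counts, cells, database, comp, n_iterations=5,
                          seed=0, external_profile=profile)
        assert np.isfinite(res["score"].iloc[0]) and res["score"].iloc[0] > 0


class TestComparisonSpec:
    def test_cross_region_disallowed_by_default(self):
        with pytest.raises(ValueError, match="cross-region"):
            ComparisonSpec("ME", "cEC", "cortex", "pericyte")

    def test_cross_region_opt_in(self):
        spec = ComparisonSpec("ME", "cEC", "cortex", "pericyte",
                              allow_cross_region=True)
        assert spec.receiver == ("cortex", "pericyte")
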