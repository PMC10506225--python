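"""Benchmarking statistics against independent oracles and hand-worked cases."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deeplof.evaluation import (
    ESSENTIAL,
    NONESSENTIAL,
    ContingencyTable2x2,
    LabeledScores,
    delong_test,
    deletion_overlap_permutation,
    enrichment_log_or,
    match_genes,
    prior_influence_summary,
    roc_auc,
    threshold_classify,
    tpr_at_fpr,
    venn_partition,
)


def labeled(ess_scores, non_scores):
    ess, non = np.asarray(ess_scores, float), np.asarray(non_scores, float)
    return LabeledScores(
        gene_ids=np.arange(ess.size + non.size).astype(str),
        scores=np.concatenate([ess, non]),
        labels=np.array([ESSENTIAL] * ess.size + [NONESSENTIAL] * non.size),
    )


def brute_force_auc(ess, non):
    """Pair counting with ties worth one half."""
    wins = sum((e > n) + 0.5 * (e == n) for e in ess for n in non)
    return wins / (len(ess) * len(non))


class TestMatchGenes:
    def test_nearest_neighbor(self):
        pairs = match_genes(
            pd.Series({"e1": 5.0}), pd.Series({"p1": 4.9, "p2": 10.0})
        )
        assert pairs == [("e1", "p1")]

    def test_greedy_descending_order(self):
        pairs = match_genes(
            pd.Series({"e1": 5.0, "e2": 6.0}),
            pd.Series({"p1": 5.1, "p2": 5.9, "p3": 100.0}),
        )
        assert dict(pairs) == {"e2": "p2", "e1": "p1"}

    def test_identical_pool_gives_zero_distance(self):
        n = pd.Series({"e1": 2.0, "e2": 7.0, "e3": 11.0})
        pool = pd.Series({"p1": 2.0, "p2": 7.0, "p3": 11.0})
        pairs = match_genes(n, pool)
        total = sum(abs(n[e] - pool[p]) for e, p in pairs)
        assert total == 0.0

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            match_genes(pd.Series({"a": 1.0, "b": 2.0}), pd.Series({"p": 1.0}))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(labeled([3.0, 2.0], [1.0, 0.5])) == 1.0

    def test_all_ties(self):
        assert roc_auc(labeled([1.0, 1.0], [1.0, 1.0])) == 0.5

    def test_hand_worked_example(self):
        assert roc_auc(labeled([0.9, 0.4], [0.5, 0.1])) == 0.75

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(5, 100, size=2)
        # coarse scores force plenty of ties
        ess = rng.integers(0, 10, size=m) / 10.0
        non = rng.integers(0, 10, size=n) / 10.0
        assert roc_auc(labeled(ess, non)) == pytest.approx(
            brute_force_auc(ess, non), abs=1e-12
        )

    def test_single_class_rejected(self):
        data = LabeledScores(
            gene_ids=np.array(["a", "b"]),
            scores=np.array([1.0, 2.0]),
            labels=np.array([ESSENTIAL, ESSENTIAL]),
        )
        with pytest.raises(ValueError):
            roc_auc(data)


def delong_oracle(y, sa, sb):
    """Independent placement-value computation of the DeLong variance of
    AUC_a - AUC_b, written directly from the estimator's definition."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    m, n = pos.size, neg.size
    out = {}
    for name, s in (("a", sa), ("b", sb)):
        psi = np.empty((m, n))
        for i, ip in enumerate(pos):
            for j, jn in enumerate(neg):
                psi[i, j] = 1.0 if s[ip] > s[jn] else (0.5 if s[ip] == s[jn] else 0.0)
        out[name] = psi
    var = 0.0
    cov_terms = {}
    for name, psi in out.items():
        auc = psi.mean()
        v10 = psi.mean(axis=1)
        v01 = psi.mean(axis=0)
        cov_terms[name] = (auc, v10, v01)
    (auc_a, v10a, v01a), (auc_b, v10b, v01b) = cov_terms["a"], cov_terms["b"]
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    return auc_a, auc_b, var


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = np.array([ESSENTIAL] * 10 + [NONESSENTIAL] * 20)
        auc_a, auc_b, p = delong_test(s, s, y)
        assert auc_a == auc_b and p == 1.0

    def test_swapping_arguments_keeps_p(self):
        rng = np.random.default_rng(1)
        y = np.array([ESSENTIAL] * 12 + [NONESSENTIAL] * 18)
        sa, sb = rng.normal(size=30), rng.normal(size=30)
        a1, b1, p1 = delong_test(sa, sb, y)
        a2, b2, p2 = delong_test(sb, sa, y)
        assert (a1, b1) == (b2, a2) and p1 == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_statistic_matches_placement_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = np.zeros(20, dtype=int)
        y[rng.choice(20, size=8, replace=False)] = 1
        sa = rng.normal(size=20) + y
        sb = 0.5 * sa + rng.normal(size=20)
        auc_a, auc_b, p = delong_test(sa, sb, y)
        o_auc_a, o_auc_b, o_var = delong_oracle(y, sa, sb)
        assert auc_a == pytest.approx(o_auc_a, abs=1e-12)
        assert auc_b == pytest.approx(o_auc_b, abs=1e-12)
        z = (o_auc_a - o_auc_b) / np.sqrt(o_var)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)

    def test_null_p_values_roughly_uniform(self):
        # equally informative paired scores: p under label permutation
        # should not concentrate anywhere (KS check at alpha = 0.01)
        rng = np.random.default_rng(7)
        n = 60
        base = rng.normal(size=n)
        y0 = np.array([1] * 20 + [0] * 40)
        ps = []
        for _ in range(500):
            y = rng.permutation(y0)
            sa = base + rng.normal(size=n)
            sb = base + rng.normal(size=n)
            ps.append(delong_test(sa, sb, y)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1.0, 2.0], [1.0], np.array([ESSENTIAL, NONESSENTIAL]))


class TestTprAtFpr:
    def test_perfect_separation(self):
        tpr, se = tpr_at_fpr(labeled([3.0, 2.5], [1.0, 0.5]), 0.05, n_boot=50, seed=0)
        assert tpr == 1.0

    def test_enumerated_threshold_example(self):
        # by hand: any threshold in (1.5, 2] admits one false positive of
        # three (FPR 1/3 <= 0.34) and two true positives; lower thresholds
        # push FPR to 2/3, so the best attainable TPR is 2/3
        data = labeled([3.0, 2.0, 1.0], [2.5, 1.5, 0.1])
        tpr, _ = tpr_at_fpr(data, 0.34, n_boot=10, seed=0)
        assert tpr == pytest.approx(2.0 / 3.0)

    def test_bootstrap_se_reproducible(self):
        data = labeled([3.0, 2.0, 1.0, 0.8], [2.5, 0.9, 0.5, 0.1])
        a = tpr_at_fpr(data, 0.3, n_boot=200, seed=5)
        b = tpr_at_fpr(data, 0.3, n_boot=200, seed=5)
        assert a == b

    def test_invalid_boot_count_rejected(self):
        with pytest.raises(ValueError):
            tpr_at_fpr(labeled([1.0], [0.0]), 0.1, n_boot=0)


class TestThresholdClassify:
    def test_high_direction_inclusive(self):
        s = pd.Series({"a": 0.9, "b": 0.84, "c": 0.8})
        assert threshold_classify(s, 0.835, "high_is_intolerant") == {"a", "b"}

    def test_cutoff_above_max_empty(self):
        s = pd.Series({"a": 0.9})
        assert threshold_classify(s, 0.95, "high_is_intolerant") == set()

    def test_low_direction_loeuf_style(self):
        s = pd.Series({"a": 0.2, "b": 0.35, "c": 0.5})
        assert threshold_classify(s, 0.35, "low_is_intolerant") == {"a", "b"}


class TestVennPartition:
    def test_unique_members(self):
        table = venn_partition({"A": {"g1", "g2"}, "B": {"g2"}})
        assert len(table) == 2
        assert table.loc["g1", "unique_to"] == "A"
        assert table.loc["g2", "n_sets"] == 2

    def test_identical_sets_have_no_unique(self):
        table = venn_partition({"A": {"g1"}, "B": {"g1"}})
        assert (table["unique_to"] == "").all()

    def test_union_matches_brute_force(self):
        rng = np.random.default_rng(3)
        sets = {
            name: {f"g{i}" for i in rng.choice(50, size=rng.integers(5, 20), replace=False)}
            for name in "ABCD"
        }
        table = venn_partition(sets)
        assert set(table.index) == set().union(*sets.values())


class TestEnrichment:
    def test_hand_worked_example(self):
        res = enrichment_log_or(ContingencyTable2x2(20, 10, 10, 20))
        assert res.log_or == pytest.approx(np.log(4.0), abs=1e-10)
        assert res.se == pytest.approx(np.sqrt(0.3), abs=1e-10)
        assert res.ci_low == pytest.approx(1.3863 - 1.96 * 0.5477, abs=1e-3)
        assert res.ci_high == pytest.approx(1.3863 + 1.96 * 0.5477, abs=1e-3)

    def test_symmetric_table_zero(self):
        assert enrichment_log_or(ContingencyTable2x2(10, 10, 10, 10)).log_or == 0.0

    def test_row_swap_negates(self):
        a = enrichment_log_or(ContingencyTable2x2(20, 10, 10, 20))
        b = enrichment_log_or(ContingencyTable2x2(10, 20, 20, 10))
        assert a.log_or == -b.log_or
        assert a.se == pytest.approx(b.se, rel=1e-15)

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            enrichment_log_or(ContingencyTable2x2(0, 10, 10, 10))

    def test_wald_interval_coverage(self):
        # 2x2 tables drawn from known odds: the 95% CI should cover the true
        # log OR ~95% of the time
        rng = np.random.default_rng(11)
        p1, p2 = 0.3, 0.1
        true = np.log((p1 / (1 - p1)) / (p2 / (1 - p2)))
        covered = 0
        reps = 2000
        for _ in range(reps):
            n11 = rng.binomial(200, p1)
            n12 = rng.binomial(800, p2)
            res = enrichment_log_or(
                ContingencyTable2x2(n11, n12, 200 - n11, 800 - n12)
            )
            covered += res.ci_low <= true <= res.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.02)


def toy_intervals():
    genes = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": [0, 100, 200, 300, 400, 500],
            "end": [50, 150, 250, 350, 450, 550],
            "name": [f"g{i}" for i in range(6)],
        }
    )
    deletions = pd.DataFrame(
        {"chrom": "chrS", "start": [10, 120, 410], "end": [30, 140, 430],
         "name": ["d0", "d1", "d2"]}
    )
    return genes, deletions


class TestDeletionOverlapPermutation:
    def test_observed_when_targets_are_deletion_spans(self):
        genes, _ = toy_intervals()
        obs, _, p = deletion_overlap_permutation(
            genes.copy(), set(genes["name"]), genes, B=10, seed=0
        )
        assert obs == 1.0 and p == 1.0

    def test_zero_p_when_targets_never_overlap(self):
        genes, deletions = toy_intervals()
        # g3 and g5 overlap no deletion; most random pairs hit one
        obs, null, p = deletion_overlap_permutation(
            deletions, {"g3", "g5"}, genes, exhaustive=True
        )
        assert obs == 0.0
        assert p == pytest.approx((null <= 0.0).mean())

    def test_exhaustive_matches_manual_enumeration(self):
        genes, deletions = toy_intervals()
        target = {"g0", "g1"}
        obs, null, p = deletion_overlap_permutation(
            deletions, target, genes, exhaustive=True
        )
        overlap_genes = {"g0", "g1", "g4"}  # by construction
        props = []
        for pair in combinations(genes["name"], 2):
            props.append(len(set(pair) & overlap_genes) / 3.0)
        expected_p = np.mean([q <= obs for q in props])
        assert obs == pytest.approx(2.0 / 3.0)
        assert null.size == 15
        assert p == pytest.approx(expected_p)

    def test_sampled_p_approaches_exhaustive(self):
        genes, deletions = toy_intervals()
        _, _, p_ex = deletion_overlap_permutation(
            deletions, {"g0", "g3"}, genes, exhaustive=True
        )
        _, _, p_mc = deletion_overlap_permutation(
            deletions, {"g0", "g3"}, genes, B=4000, seed=1
        )
        assert p_mc == pytest.approx(p_ex, abs=0.05)

    def test_adjacent_intervals_do_not_overlap(self):
        genes = pd.DataFrame(
            {"chrom": "chrS", "start": [10], "end": [20], "name": ["g0"]}
        )
        deletions = pd.DataFrame(
            {"chrom": "chrS", "start": [20], "end": [30], "name": ["d0"]}
        )
        obs, _, _ = deletion_overlap_permutation(deletions, {"g0"}, genes, B=1, seed=0)
        assert obs == 0.0

    def test_pool_smaller_than_target_rejected(self):
        genes, deletions = toy_intervals()
        with pytest.raises(ValueError):
            deletion_overlap_permutation(
                deletions, set(genes["name"]), genes.iloc[:2], B=5
            )


class TestPriorInfluenceSummary:
    def make_tables(self, deltas, n):
        base = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(n))],
             "deeplof_score": 0.5 * np.ones(len(n))}
        )
        shifted = base.copy()
        shifted["deeplof_score"] = base["deeplof_score"] + deltas
        nv = pd.Series(n, index=base["gene_id"])
        return base, shifted, nv

    def test_identical_tables_flat_summary(self):
        base, _, nv = self.make_tables(np.zeros(50), np.linspace(1, 60, 50))
        per_gene, binned, rho = prior_influence_summary(base, base, nv)
        assert (per_gene["abs_delta"] == 0.0).all()
        assert np.isnan(rho)

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(0)
        n = np.exp(rng.normal(1.5, 1.0, size=80))
        a, b, nv = self.make_tables(rng.normal(scale=0.05, size=80), n)
        pg_ab, _, _ = prior_influence_summary(a, b, nv)
        pg_ba, _, _ = prior_influence_summary(b, a, nv)
        assert np.allclose(pg_ab["abs_delta"], pg_ba["abs_delta"])

    def test_detects_decreasing_influence(self):
        rng = np.random.default_rng(4)
        n = np.exp(rng.normal(1.5, 1.2, size=400))
        deltas = 0.5 / (1.0 + n) + rng.normal(scale=1e-3, size=400)
        a, b, nv = self.make_tables(deltas, n)
        _, binned, rho = prior_influence_summary(a, b, nv)
        assert rho < -0.8

    def test_misaligned_genes_rejected(self):
        a, b, nv = self.make_tables(np.zeros(10), np.arange(1.0, 11.0))
        b = b.iloc[:5]
        with pytest.raises(ValueError):
            prior_influence_summary(a, b, nv)
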