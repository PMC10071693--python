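"""Metrics, Fisher exact vs enumeration, correlation, test selection, clustering."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipass import (
    ConfusionMatrix,
    ExpressionMatrix,
    cluster_genes_vs_score,
    confusion,
    fisher_exact_2x2,
    metrics,
    pearson_r,
    two_group_compare,
)
from ipass.errors import IpassError
from ipass.evaluation import round_half_up_percent


def enumerate_fisher(a, b, c, d):
    """Independent oracle: sum hypergeometric probabilities <= P(observed)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestConfusionAndMetrics:
    def test_perfect_and_inverted_predictions(self):
        truth = {f"s{i}": ("pos" if i < 4 else "neg") for i in range(10)}
        cm = confusion(truth, truth, positive="pos")
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (4, 6, 0, 0)
        assert all(v == 1.0 for v in (metrics(cm).sensitivity, metrics(cm).accuracy))
        inverted = {s: ("neg" if t == "pos" else "pos") for s, t in truth.items()}
        cm2 = confusion(inverted, truth, positive="pos")
        assert (cm2.tp, cm2.tn) == (0, 0)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(8)
        truth = {f"s{i}": ("pos" if v < 0.4 else "neg") for i, v in enumerate(rng.uniform(size=50))}
        pred = {f"s{i}": ("pos" if v < 0.6 else "neg") for i, v in enumerate(rng.uniform(size=50))}
        cm = confusion(pred, truth, positive="pos")
        expected = {
            (p, t): sum(1 for s in truth if (pred[s], truth[s]) == (p, t))
            for p in ("pos", "neg")
            for t in ("pos", "neg")
        }
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (
            expected[("pos", "pos")],
            expected[("neg", "pos")],
            expected[("pos", "neg")],
            expected[("neg", "neg")],
        )

    def test_sample_order_invariance(self):
        truth = {"a": "pos", "b": "neg", "c": "pos"}
        pred = {"a": "pos", "b": "pos", "c": "neg"}
        reordered = dict(reversed(list(pred.items())))
        assert confusion(pred, truth, "pos") == confusion(reordered, truth, "pos")

    def test_id_mismatch_rejected(self):
        with pytest.raises(IpassError):
            confusion({"a": "pos"}, {"b": "pos"}, positive="pos")

    def test_published_worked_example(self):
        # the unique integer 2x2 with 25 positives / 52 negatives whose
        # rounded metrics hit 84/88/78/92
        rep = metrics(ConfusionMatrix(tp=21, fn=4, fp=6, tn=46))
        assert round_half_up_percent(rep.sensitivity) == 84
        assert round_half_up_percent(rep.specificity) == 88
        assert round_half_up_percent(rep.ppv) == 78
        assert round_half_up_percent(rep.npv) == 92

    def test_zero_denominator_flagged_not_zeroed(self):
        rep = metrics(ConfusionMatrix(tp=0, fn=3, fp=0, tn=7))
        assert rep.ppv is None
        assert "ppv" in rep.undefined
        assert rep.npv == 0.7


class TestFisherExact:
    def test_no_association_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_three_three(self):
        # support has C(6,3)=20 tables; the two extreme tables each have mass 1/20
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_matches_enumeration_for_all_small_margins(self):
        for a in range(9):
            for b in range(9 - a):
                for c in range(9):
                    for d in range(9 - c):
                        if a + b + c + d == 0 or a + c > 8 or b + d > 8:
                            continue
                        assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                            enumerate_fisher(a, b, c, d), abs=1e-10
                        ), (a, b, c, d)

    def test_all_zero_rejected(self):
        with pytest.raises(IpassError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestPearson:
    def test_self_and_negated_self(self):
        x = [1.0, 2.0, 4.0, 8.0]
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_closed_form_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y)[0] == pytest.approx(num / den, abs=1e-12)

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r0 = pearson_r(x, y)[0]
        assert pearson_r(2.5 * x + 7, y)[0] == pytest.approx(r0, abs=1e-12)
        assert pearson_r(x, 0.1 * y - 3)[0] == pytest.approx(r0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(IpassError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTwoGroupCompare:
    def test_gaussian_equal_variance_mostly_selects_t_test(self):
        chosen = [
            two_group_compare(
                np.random.default_rng(2 * s).normal(0, 1, 30),
                np.random.default_rng(2 * s + 1).normal(0.3, 1, 30),
            )[0]
            for s in range(100)
        ]
        # three alpha=0.05 gatekeeper tests must all pass, so the expected
        # selection rate is ~0.95^3 ~ 0.86
        assert chosen.count("t-test") >= 75

    def test_skewed_group_selects_wilcoxon(self):
        chosen = [
            two_group_compare(
                np.random.default_rng(1000 + s).exponential(1.0, 30),
                np.random.default_rng(2000 + s).normal(1.0, 1.0, 30),
            )[0]
            for s in range(100)
        ]
        assert chosen.count("wilcoxon") >= 90

    def test_identical_groups_give_large_p(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=25)
        _, _, p = two_group_compare(g, g.copy())
        assert p > 0.5

    def test_agrees_with_scipy_on_each_branch(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        name, stat, p = two_group_compare(a, b)
        if name == "t-test":
            assert p == pytest.approx(stats.ttest_ind(a, b).pvalue)
        else:
            assert p == pytest.approx(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )


class TestGeneClustering:
    @staticmethod
    def planted_matrix(seed=0, n=40):
        rng = np.random.default_rng(seed)
        score = rng.normal(0, 1, n)
        track = np.vstack([score + rng.normal(0, 0.2, n) for _ in range(5)])
        anti = np.vstack([-score + rng.normal(0, 0.2, n) for _ in range(5)])
        tpm = np.maximum(np.exp2(3 + np.vstack([track, anti])) - 1, 0)
        genes = [f"T{i}" for i in range(5)] + [f"A{i}" for i in range(5)]
        m = ExpressionMatrix(
            pd.DataFrame(tpm, index=genes, columns=[f"s{i}" for i in range(n)])
        )
        return m, genes, score

    def test_tracking_block_is_top_cluster(self):
        m, genes, score = self.planted_matrix()
        res = cluster_genes_vs_score(m, genes, score, k=2, seed=0)
        top_members = {g for g, c in res.assignments.items() if c == res.top_cluster}
        assert top_members == {f"T{i}" for i in range(5)}
        assert res.cluster_mean_r[res.top_cluster] > 0.8

    def test_singleton_clusters_pick_best_gene(self):
        m, genes, score = self.planted_matrix(seed=5)
        res = cluster_genes_vs_score(m, genes, score, k=len(genes), seed=0)
        best_gene = max(
            genes, key=lambda g: pearson_r(np.log2(m.data.loc[g] + 1), score)[0]
        )
        top_members = [g for g, c in res.assignments.items() if c == res.top_cluster]
        assert top_members == [best_gene]

    def test_deterministic_given_seed(self):
        m, genes, score = self.planted_matrix(seed=2)
        r1 = cluster_genes_vs_score(m, genes, score, k=3, seed=11)
        r2 = cluster_genes_vs_score(m, genes, score, k=3, seed=11)
        assert r1.assignments == r2.assignments

    def test_k_exceeding_gene_count_rejected(self):
        m, genes, score = self.planted_matrix()
        with pytest.raises(IpassError):
            cluster_genes_vs_score(m, genes, score, k=11, seed=0)
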