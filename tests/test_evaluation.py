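from fractions import Fraction

import numpy as np
import pytest

import topknet as tk
from topknet.evaluation import ConfusionCounts

from conftest import random_instance


def roc_auc_oracle(ranks, labels):
    """Exhaustive tie-adjusted pair-ordering probability: P(true ranked
    better than false), ties counted 1/2."""
    pos = [r for r, y in zip(ranks, labels) if y]
    neg = [r for r, y in zip(ranks, labels) if not y]
    score = sum(1.0 if p < n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return score / (len(pos) * len(neg))


def perfect_instance():
    """7 true links ranked 1..7 of T=10."""
    genes = [f"G{i}" for i in range(11)]
    u = tk.build_edge_universe(genes[:1], genes[1:], directed=True)
    gold = tk.GoldStandard(u, frozenset(u.edges[:7]))
    ranks = np.arange(1.0, 11.0)
    return ranks, gold


class TestConfusion:
    def test_perfect_ranking_at_matching_threshold(self):
        ranks, gold = perfect_instance()
        c = tk.confusion_at_threshold(ranks, gold, 7)
        assert (c.tp, c.fp, c.fn, c.tn) == (7, 0, 0, 3)

    def test_threshold_below_everything(self):
        ranks, gold = perfect_instance()
        c = tk.confusion_at_threshold(ranks, gold, 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 0, 7)

    def test_counts_match_hand_enumeration_with_ties(self):
        genes = [f"G{i}" for i in range(11)]
        u = tk.build_edge_universe(genes[:1], genes[1:], directed=True)
        ranks = np.array([1, 2, 3.5, 3.5, 5, 6.5, 6.5, 8, 9, 10])
        gold = tk.GoldStandard(u, frozenset([u.edges[i] for i in (0, 2, 3, 7)]))
        c = tk.confusion_at_threshold(ranks, gold, 3.5)
        # edges ranked <= 3.5: indices 0,1,2,3 -> three true, one false
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 5)
        assert c.total == 10

    def test_universe_mismatch_rejected(self):
        _, gold = perfect_instance()
        other = tk.build_edge_universe(["X"], ["Y"], directed=True)
        rv = tk.RankVector("a", other, np.array([1.0]), 1.0)
        with pytest.raises(tk.ValidationError):
            tk.confusion_at_threshold(rv, gold, 1)


class TestPrecisionRecall:
    def test_worked_example_six_sevenths(self):
        # one missing true link, one mistaken call: p = r = 6/7 exactly
        p, r = tk.precision_recall(ConfusionCounts(tp=6, fp=1, tn=0, fn=1))
        assert Fraction(p).limit_denominator() == Fraction(6, 7)
        assert p == 6 / 7 and r == 6 / 7

    def test_all_calls_wrong(self):
        p, r = tk.precision_recall(ConfusionCounts(tp=0, fp=5, tn=0, fn=3))
        assert p == 0.0 and r == 0.0

    def test_precision_anchor_at_zero_calls(self):
        p, r = tk.precision_recall(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert p == 1.0 and r == 0.0

    def test_half_recall(self):
        p, r = tk.precision_recall(ConfusionCounts(tp=5, fp=0, tn=0, fn=5))
        assert p == 1.0 and r == 0.5

    def test_no_true_edges_rejected(self):
        with pytest.raises(tk.ValidationError):
            tk.precision_recall(ConfusionCounts(tp=0, fp=2, tn=3, fn=0))


class TestCurvesAndAuc:
    def test_perfect_ranking_roc_hits_corner(self):
        ranks, gold = perfect_instance()
        pr, roc = tk.curves(ranks, gold)
        assert [0.0, 1.0] in roc.tolist()
        assert tk.auc(roc) == 1.0
        assert tk.auc(pr) == 1.0

    def test_anti_perfect_ranking_hugs_bottom(self):
        ranks, gold = perfect_instance()
        rev = 11 - ranks  # true links now ranked worst
        _, roc = tk.curves(rev, gold)
        assert tk.auc(roc) == 0.0

    def test_all_tied_gives_diagonal(self):
        ranks, gold = perfect_instance()
        tied = np.full(10, 5.5)
        _, roc = tk.curves(tied, gold)
        assert tk.auc(roc) == pytest.approx(0.5)

    def test_staircase_matches_hand_computation(self):
        # T=6, true = edges ranked 1, 3, 4; thresholds 1..6
        genes = [f"G{i}" for i in range(7)]
        u = tk.build_edge_universe(genes[:1], genes[1:], directed=True)
        gold = tk.GoldStandard(u, frozenset([u.edges[i] for i in (0, 2, 3)]))
        ranks = np.arange(1.0, 7.0)
        pr, roc = tk.curves(ranks, gold)
        expected_recall = [0, 1 / 3, 1 / 3, 2 / 3, 1, 1, 1]
        expected_precision = [1, 1, 1 / 2, 2 / 3, 3 / 4, 3 / 5, 3 / 6]
        assert pr[:, 0].tolist() == pytest.approx(expected_recall)
        assert pr[:, 1].tolist() == pytest.approx(expected_precision)
        assert roc[-1].tolist() == [1.0, 1.0]

    def test_unsorted_curve_rejected(self):
        with pytest.raises(tk.ValidationError):
            tk.auc(np.array([[0.5, 1.0], [0.2, 0.5]]))

    def test_roc_auc_equals_pair_ordering_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(60):
            ensemble, gold = random_instance(rng)
            ranks = ensemble.rank_matrix[0]
            _, roc = tk.curves(ranks, gold)
            assert tk.auc(roc) == pytest.approx(
                roc_auc_oracle(ranks, gold.labels), abs=1e-12
            )

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(11)
        ensemble, gold = random_instance(rng, t_max=12)
        ranks = ensemble.rank_matrix[0]
        # exp(-rank) is a strictly monotone confidence; re-ranking recovers ranks
        from scipy.stats import rankdata

        again = rankdata(-np.exp(-ranks), method="average")
        for curve_a, curve_b in zip(tk.curves(ranks, gold), tk.curves(again, gold)):
            assert tk.auc(curve_a) == pytest.approx(tk.auc(curve_b))

    def test_reversal_maps_roc_auc_to_complement(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            ensemble, gold = random_instance(rng)
            ranks = ensemble.rank_matrix[0]
            t = gold.universe.size
            _, roc = tk.curves(ranks, gold)
            _, roc_rev = tk.curves(t + 1 - ranks, gold)
            assert tk.auc(roc_rev) == pytest.approx(1 - tk.auc(roc), abs=1e-12)


class TestMaxFscore:
    def test_six_sevenths_at_best_threshold(self):
        # 7 true links; top 7 calls contain 6 of them (one mistake at rank 4,
        # one true link missed down at rank 10): p = r = 6/7 at threshold 7,
        # and every other threshold yields a lower f-score
        genes = [f"G{i}" for i in range(11)]
        u = tk.build_edge_universe(genes[:1], genes[1:], directed=True)
        gold = tk.GoldStandard(u, frozenset([u.edges[i] for i in (0, 1, 2, 4, 5, 6, 9)]))
        ranks = np.arange(1.0, 11.0)
        assert tk.max_fscore(ranks, gold) == pytest.approx(6 / 7)

    def test_perfect_ranking_reaches_one(self):
        ranks, gold = perfect_instance()
        assert tk.max_fscore(ranks, gold) == 1.0

    def test_dominates_every_threshold(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            ensemble, gold = random_instance(rng)
            ranks = ensemble.rank_matrix[0]
            best = tk.max_fscore(ranks, gold)
            for thr in np.unique(ranks):
                p, r = tk.precision_recall(tk.confusion_at_threshold(ranks, gold, thr))
                f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
                assert best >= f - 1e-12


class TestEmpiricalPvalue:
    def test_observed_above_all_draws(self):
        _, gold = perfect_instance()
        assert tk.empirical_pvalue(1.01, gold, "ROC", n_draws=99, seed=5) == 0.01

    def test_observed_below_all_draws(self):
        _, gold = perfect_instance()
        assert tk.empirical_pvalue(-0.5, gold, "ROC", n_draws=99, seed=5) == 1.0

    def test_null_is_centered_for_roc(self):
        genes = [f"G{i}" for i in range(21)]
        u = tk.build_edge_universe(genes[:1], genes[1:], directed=True)
        gold = tk.GoldStandard(u, frozenset(u.edges[:10]))
        p = tk.empirical_pvalue(0.5, gold, "ROC", n_draws=2000, seed=6)
        assert 0.4 < p < 0.65  # symmetry of the permutation null around 1/2

    def test_seed_reproducible_and_bounded(self):
        _, gold = perfect_instance()
        draws = [tk.empirical_pvalue(0.7, gold, "PR", n_draws=200, seed=7) for _ in range(2)]
        assert draws[0] == draws[1]
        assert 1 / 201 <= draws[0] <= 1.0

    def test_bad_inputs_rejected(self):
        _, gold = perfect_instance()
        with pytest.raises(tk.ValidationError):
            tk.empirical_pvalue(float("nan"), gold, "ROC")
        with pytest.raises(tk.ValidationError):
            tk.empirical_pvalue(0.5, gold, "XYZ")


class TestOverallScore:
    def test_null_pvalues_give_zero(self):
        reports = [_report(1.0, 1.0) for _ in range(4)]
        assert tk.overall_score(reports).score == 0.0

    def test_strong_pvalues(self):
        reports = [_report(1e-10, 1e-10)]
        assert tk.overall_score(reports).score == pytest.approx(10.0)

    def test_mean_over_networks(self):
        reports = [_report(1e-2, 1e-4) for _ in range(3)]
        os = tk.overall_score(reports)
        assert (os.p1, os.p2, os.score) == (2.0, 4.0, 3.0)

    def test_invalid_pvalue_rejected(self):
        with pytest.raises(tk.ValidationError):
            tk.overall_score([_report(0.0, 0.5)])


def _report(p_pr, p_roc):
    return tk.EvaluationReport(
        auc_pr=0.5, auc_roc=0.5, max_fscore=0.5,
        pr_curve=np.zeros((2, 2)), roc_curve=np.zeros((2, 2)),
        thresholds=np.zeros(1), pvalue_aucpr=p_pr, pvalue_aucroc=p_roc,
    )


class TestSelectOptimalAlgorithms:
    def test_drops_the_weakest(self):
        scored = [(f"a{i:02d}", i / 100) for i in range(12)]
        chosen = tk.select_optimal_algorithms(scored, 10)
        assert set(chosen) == {f"a{i:02d}" for i in range(2, 12)}

    def test_count_equal_to_m_returns_all(self):
        scored = [("x", 0.1), ("y", 0.2)]
        assert set(tk.select_optimal_algorithms(scored, 2)) == {"x", "y"}

    def test_boundary_tie_resolved_lexicographically(self):
        scored = [("c", 0.5), ("a", 0.5), ("b", 0.5), ("d", 0.9)]
        assert tk.select_optimal_algorithms(scored, 2) == ["d", "a"]

    def test_excessive_count_rejected(self):
        with pytest.raises(tk.ValidationError):
            tk.select_optimal_algorithms([("a", 0.5)], 2)


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        _, p = tk.compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_fully_separated_small_groups(self):
        # n=3 vs 3: most extreme split has exact two-sided p = 2/20
        _, p = tk.compare_groups([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)

    def test_single_element_groups(self):
        _, p = tk.compare_groups([1.0], [2.0])
        assert p == 1.0

    def test_one_sided_enumeration(self):
        _, p = tk.compare_groups([10, 11, 12], [1, 2, 3], alternative="greater")
        assert p == pytest.approx(1 / 20)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        _, p = tk.compare_groups(a, b)
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(tk.ValidationError):
            tk.compare_groups([], [1.0])


def test_evaluate_bundles_metrics_and_pvalues():
    # large enough universe that no random permutation reaches AUC 1.0
    genes = [f"G{i}" for i in range(41)]
    u = tk.build_edge_universe(genes[:1], genes[1:], directed=True)
    gold = tk.GoldStandard(u, frozenset(u.edges[:10]))
    ranks = np.arange(1.0, 41.0)
    report = tk.evaluate(ranks, gold, n_null=99, seed=1)
    assert report.auc_roc == pytest.approx(1.0) and report.auc_pr == pytest.approx(1.0)
    assert report.pvalue_aucroc == pytest.approx(0.01)
    assert report.null_spec.n_draws == 99
    d = report.to_dict()
    # both p-values are 1/100, so the single-network OS is -log10(0.01) = 2
    assert d["pvalue_aucpr"] == pytest.approx(0.01)
    assert d["overall_score"] == pytest.approx(2.0)
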