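"""Benchmark-set construction, metrics and the redundancy audit."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import f1_score, matthews_corrcoef

from cueditscan import benchmark as bench, ml, synthetic
from cueditscan.benchmark import (BenchmarkSet, ConfusionCounts, LeakageError,
                                  compute_metrics, counts_from_calls,
                                  make_proportional_set, redundancy_audit,
                                  roc_and_pr_curves, split_train_test)


def _sites(n_pos, n_neg, seed=0):
    params = synthetic.MotifParams()
    bset, _ = synthetic.make_benchmark(n_pos, n_neg // n_pos, params,
                                       seed=seed)
    return list(bset.sites)


class TestSplit:
    def test_stratified_70_30(self):
        sites = _sites(20, 60, seed=1)
        train, test = split_train_test(sites, 0.7, seed=0)
        assert sum(s.label for s in test) == 6
        assert len(test) == 24
        assert not {id(s) for s in train} & {id(s) for s in test}

    def test_same_seed_same_split(self):
        sites = _sites(10, 30)
        t1 = split_train_test(sites, 0.7, seed=5)
        t2 = split_train_test(sites, 0.7, seed=5)
        assert [id(s) for s in t1[0]] == [id(s) for s in t2[0]]

    def test_single_class_raises(self):
        sites = [s for s in _sites(10, 30) if s.label == 1]
        with pytest.raises(ValueError):
            split_train_test(sites)


class TestProportionalSet:
    def test_top_up_arithmetic_and_recall_invariance(self):
        params = synthetic.MotifParams()
        bset, _ = synthetic.make_benchmark(10, 3, params, seed=3)
        pool, _ = synthetic.make_benchmark(1, 400, params, seed=4)
        neg_pool = [s for s in pool.sites if s.label == 0]
        prop = make_proportional_set(BenchmarkSet(bset.sites, 3.0, "testing"),
                                     neg_pool, ratio=40, seed=0)
        assert prop.n_pos == 10
        assert prop.n_neg == 400
        # any fixed classifier keeps its recall: positives are shared
        from cueditscan import rules
        def recall_of(sites):
            labels = np.array([s.label for s in sites], dtype=bool)
            calls = np.array([rules.rules_classify(rules.rules_score(s.window))
                              for s in sites])
            c = counts_from_calls(labels, calls)
            return compute_metrics(c).recall
        assert recall_of(bset.sites) == recall_of(prop.sites)

    def test_leakage_detection(self):
        params = synthetic.MotifParams()
        bset, _ = synthetic.make_benchmark(5, 3, params, seed=5)
        train, test = split_train_test(list(bset.sites), 0.7, seed=0)
        leaky_pool = [s for s in train if s.label == 0]
        with pytest.raises(LeakageError):
            make_proportional_set(BenchmarkSet(tuple(test), 3.0), leaky_pool,
                                  ratio=10, seed=0, train=train)

    def test_ratio_one_is_balanced(self):
        params = synthetic.MotifParams()
        bset, _ = synthetic.make_benchmark(8, 1, params, seed=6)
        assert bset.n_pos == bset.n_neg == 8


class TestPointMetrics:
    def test_hand_derived_example(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=5))
        assert m.recall == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)
        # (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)) = 14/24
        assert m.mcc == pytest.approx((15 - 1) / math.sqrt(4 * 4 * 6 * 6))

    def test_no_information_mcc_zero(self):
        m = compute_metrics(ConfusionCounts(tp=2, fp=2, fn=2, tn=2))
        assert m.mcc == pytest.approx(0.0)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=4, fp=0, fn=0, tn=12))
        assert (m.recall, m.precision, m.f1, m.mcc) == (1, 1, 1, 1)

    def test_zero_denominators_give_nan_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=5))
        assert math.isnan(m.precision)
        assert m.recall == 0.0

    def test_exhaustive_small_tables_match_sklearn(self):
        """Closed forms agree with scikit-learn on every confusion table
        with all counts <= 4 (where the metrics are defined)."""
        for tp, fp, fn, tn in itertools.product(range(5), repeat=4):
            if tp + fn == 0 or fp + tn == 0:
                continue
            labels = [1] * tp + [1] * fn + [0] * fp + [0] * tn
            calls = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            m = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
            if tp + fp > 0:
                assert m.f1 == pytest.approx(
                    f1_score(labels, calls, zero_division=0))
            denom_ok = (tp + fp) and (tn + fn)
            if denom_ok:
                assert m.mcc == pytest.approx(
                    matthews_corrcoef(labels, calls), abs=1e-12)

    def test_mcc_swap_symmetry(self):
        a = compute_metrics(ConfusionCounts(tp=3, fp=2, fn=1, tn=9)).mcc
        b = compute_metrics(ConfusionCounts(tp=9, fp=1, fn=2, tn=3)).mcc
        assert a == pytest.approx(b)


class TestCurves:
    def test_perfect_separation(self):
        auroc, auprc, _, _ = roc_and_pr_curves([0.9, 0.8, 0.2, 0.1],
                                               [1, 1, 0, 0])
        assert auroc == 1.0 and auprc == 1.0

    def test_auroc_equals_mann_whitney(self):
        rng = np.random.default_rng(8)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.3).astype(int)
        if labels.sum() in (0, len(labels)):
            pytest.skip("degenerate draw")
        auroc, _, _, _ = roc_and_pr_curves(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auroc == pytest.approx(u / (len(pos) * len(neg)))

    def test_baseline_auprc_is_prevalence(self):
        rng = np.random.default_rng(9)
        labels = np.array([1] * 5 + [0] * 95)
        _, _, rep, _ = roc_and_pr_curves(rng.random(100), labels)
        assert rep.baseline_auprc == pytest.approx(0.05)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_and_pr_curves([0.1, 0.2], [1, 1])


class TestRedundancyAudit:
    def test_identical_windows_count_at_both_thresholds(self):
        res = redundancy_audit(["A" * 25, "A" * 25])
        assert res["frac_over_75"] == 1.0 and res["frac_over_30"] == 1.0

    def test_19_of_25_exceeds_75_but_18_does_not(self):
        base = "A" * 25
        w19 = "G" * 6 + "A" * 19   # 19/25 matching positions
        w18 = "G" * 7 + "A" * 18   # 18/25
        r19 = redundancy_audit([base, w19])
        r18 = redundancy_audit([base, w18])
        assert r19["frac_over_75"] == 1.0   # 19/25 = 0.76 > 0.75
        assert r18["frac_over_75"] == 0.0   # 18/25 = 0.72
        assert r18["frac_over_30"] == 1.0

    def test_low_identity_counts_at_neither(self):
        base = "A" * 25
        w7 = "A" * 7 + "G" * 18  # 7/25 = 0.28
        res = redundancy_audit([base, w7])
        assert res["frac_over_75"] == 0.0 and res["frac_over_30"] == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            redundancy_audit(["A" * 24, "A" * 24])

    def test_pair_count_across_blocks(self):
        rng = np.random.default_rng(10)
        wins = ["".join(rng.choice(list("ACGU"), size=25)) for _ in range(60)]
        res = redundancy_audit(wins, block=16)
        assert res["n_pairs"] == 60 * 59 // 2


class TestConsensusOrdering:
    def test_recall_ordering_on_synthetic_benchmark(self, motif_benchmark):
        """union recall >= each primary >= intersection recall."""
        from cueditscan import rules
        test = motif_benchmark["test"]
        model = motif_benchmark["model"]
        labels = np.array([s.label for s in test], dtype=bool)
        rules_calls = np.array([
            rules.rules_classify(rules.rules_score(s.window)) for s in test])
        probs = ml.predict_prob_many(model, [s.window for s in test])
        rf_calls = probs > 0.5

        def recall(calls):
            return compute_metrics(counts_from_calls(labels, calls)).recall

        r_union = recall(rules_calls | rf_calls)
        r_inter = recall(rules_calls & rf_calls)
        assert r_union >= max(recall(rules_calls), recall(rf_calls))
        assert min(recall(rules_calls), recall(rf_calls)) >= r_inter
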