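"""Metrics vs brute-force oracles; thresholds, bootstrap, survival, net benefit."""

import numpy as np
import pytest

from foresiin import evaluate
from foresiin.exceptions import UndefinedMetricError


def auroc_bruteforce(scores, labels):
    """All-pairs concordance oracle with 1/2 for ties."""
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    total = 0.0
    for i in pos:
        for j in neg:
            if scores[i] > scores[j]:
                total += 1.0
            elif scores[i] == scores[j]:
                total += 0.5
    return total / (len(pos) * len(neg))


def harrell_bruteforce(scores, times, events):
    conc = comp = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / comp


class TestAuc:
    def test_worked_example(self):
        s = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        assert evaluate.roc_auc(s, y) == pytest.approx(0.75)

    def test_perfect_separation(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        assert evaluate.roc_auc(s, y) == 1.0
        assert evaluate.pr_auc(s, y) == 1.0

    def test_all_tied_scores(self):
        assert evaluate.roc_auc(np.full(10, 0.3), np.r_[np.ones(5), np.zeros(5)]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            evaluate.roc_auc([0.1, 0.2], [1, 1])

    def test_bruteforce_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            s = np.round(rng.random(n), 2)  # rounded to force ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            assert evaluate.roc_auc(s, y) == pytest.approx(auroc_bruteforce(s, y), abs=1e-12)


class TestThreshold:
    def test_fixed_policy(self):
        assert evaluate.select_threshold([0.1], [0], "fixed").threshold == 0.5

    def test_perfect_split_midpoint(self):
        pol = evaluate.select_threshold([0.2, 0.3, 0.7, 0.9], [0, 0, 1, 1], "youden_max")
        assert pol.threshold == pytest.approx(0.5)
        assert pol.selection_split == "validation"

    def test_exhaustive_search_oracle(self):
        """Selected threshold attains the global optimum over all cut-points.

        A uniform grid can only lower-bound the optimum (it may miss the
        boundary between two close scores), so the check is: at least as good
        as a 1001-point grid, and equal to a brute-force loop over every
        distinct cut-point.
        """
        rng = np.random.default_rng(1)
        for mode, key in (("youden_max", "youden"), ("f1_max", "f1")):
            for _ in range(10):
                s = rng.random(60)
                y = rng.integers(0, 2, 60)
                if y.sum() in (0, 60):
                    continue
                pol = evaluate.select_threshold(s, y, mode)
                got = evaluate.confusion_at(s, y, pol.threshold)[key]
                grid_best = max(
                    evaluate.confusion_at(s, y, t)[key]
                    for t in np.linspace(0, 1, 1001)
                )
                su = np.sort(np.unique(s))
                cands = np.r_[0.0, (su[:-1] + su[1:]) / 2, 1.0]
                exact_best = max(evaluate.confusion_at(s, y, t)[key] for t in cands)
                assert got >= grid_best - 1e-12
                assert got == pytest.approx(exact_best, abs=1e-12)


class TestConfusion:
    def test_threshold_zero_all_positive(self):
        c = evaluate.confusion_at([0.1, 0.9], [0, 1], 0.0)
        assert c["sensitivity"] == 1.0 and c["fp"] == 1

    def test_worked_counts(self):
        # TP=2, FP=1, FN=0, TN=1
        c = evaluate.confusion_at([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0], 0.5)
        assert (c["tp"], c["fp"], c["fn"], c["tn"]) == (2, 1, 0, 1)
        assert c["precision"] == pytest.approx(2 / 3)
        assert c["recall"] == 1.0
        assert c["f1"] == pytest.approx(0.8)

    def test_g_mean(self):
        c = evaluate.confusion_at([0.9, 0.9, 0.9, 0.9, 0.1], [1, 0, 0, 0, 0], 0.5)
        assert c["sensitivity"] == 1.0 and c["specificity"] == 0.25
        assert c["g_mean"] == pytest.approx(0.5)

    def test_no_predicted_positive_convention(self):
        c = evaluate.confusion_at([0.1, 0.2], [1, 0], 0.9)
        assert c["precision"] == 0.0 and c["f1"] == 0.0


class TestHarrellC:
    def test_perfect_inverse_ranking(self):
        times = np.array([1.0, 2, 3, 4])
        scores = np.array([4.0, 3, 2, 1])
        assert evaluate.harrell_c(scores, times, [1, 1, 1, 1]) == 1.0

    def test_bruteforce_oracle_50_patients(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.random(50), 2)
        times = rng.integers(1, 400, 50).astype(float)
        events = rng.integers(0, 2, 50)
        assert evaluate.harrell_c(scores, times, events) == pytest.approx(
            harrell_bruteforce(scores, times, events), abs=1e-12
        )

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(3)
        scores = rng.random(80)
        # distinct times: with tied event times lifelines applies extra pair
        # rules beyond the strict earlier-event definition used here
        times = rng.permutation(80).astype(float) + 1
        events = rng.integers(0, 2, 80)
        ours = evaluate.harrell_c(scores, times, events)
        ref = concordance_index(times, -scores, events)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_equals_rank_concordance_without_censoring(self):
        rng = np.random.default_rng(4)
        scores = rng.random(40)
        times = rng.permutation(40).astype(float) + 1
        c = evaluate.harrell_c(scores, times, np.ones(40, int))
        # concordance of scores with -time as a binary-free rank statistic
        ref = harrell_bruteforce(scores, times, np.ones(40, int))
        assert c == pytest.approx(ref)

    def test_no_comparable_pairs(self):
        with pytest.raises(UndefinedMetricError):
            evaluate.harrell_c([0.1, 0.2], [5.0, 5.0], [0, 0])


class TestBootstrap:
    def test_constant_metric_degenerate_ci(self):
        lo, hi = evaluate.bootstrap_ci(lambda s: 0.42, np.arange(30), B=50, seed=0)
        assert lo == hi == 0.42

    def test_seed_deterministic(self):
        rng = np.random.default_rng(5)
        s, y = rng.random(100), rng.integers(0, 2, 100)
        a = evaluate.bootstrap_ci(evaluate.roc_auc, s, y, B=100, seed=7)
        assert a == evaluate.bootstrap_ci(evaluate.roc_auc, s, y, B=100, seed=7)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(6)

        def make(n):
            y = rng.integers(0, 2, n)
            s = y + rng.normal(0, 1, n)
            return s, y

        s1, y1 = make(200)
        s2, y2 = make(2000)
        lo1, hi1 = evaluate.bootstrap_ci(evaluate.roc_auc, s1, y1, B=200, seed=1)
        lo2, hi2 = evaluate.bootstrap_ci(evaluate.roc_auc, s2, y2, B=200, seed=1)
        assert hi2 - lo2 < hi1 - lo1

    def test_report_defaults_to_1000_replicates(self):
        import inspect

        assert inspect.signature(evaluate.bootstrap_ci).parameters["B"].default == 1000
        assert inspect.signature(evaluate.evaluate_scores).parameters["B"].default == 1000


class TestSurvival:
    def test_km_product_limit_hand_calc(self):
        km = evaluate.km_curve([5, 10, 15], [1, 1, 1], ["a", "a", "a"])
        surv = km[km.time > 0].survival.to_numpy()
        np.testing.assert_allclose(surv, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_km_monotone_from_one(self):
        rng = np.random.default_rng(8)
        t = rng.integers(1, 300, 100).astype(float)
        e = rng.integers(0, 2, 100)
        km = evaluate.km_curve(t, e, np.repeat("g", 100))
        s = km.survival.to_numpy()
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()

    def test_km_last_event_equals_empirical_fraction(self):
        t = np.array([3, 6, 9, 12, 15], dtype=float)
        e = np.ones(5, int)
        e[-2:] = 1
        km = evaluate.km_curve(t, e, np.repeat("g", 5))
        assert km.survival.iloc[-1] == pytest.approx(0.0)

    def test_logrank_identical_groups_zero(self):
        t = np.array([2, 4, 6, 2, 4, 6], dtype=float)
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        chi2, p = evaluate.logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_logrank_textbook_toy(self):
        """Group A events at 2 and 4; B event at 6, censored at 8."""
        chi2, p = evaluate.logrank_test(
            [2, 4, 6, 8], [1, 1, 1, 0], ["A", "A", "B", "B"]
        )
        assert chi2 == pytest.approx(2.88235, abs=1e-4)  # hand computation

    def test_logrank_needs_two_groups(self):
        with pytest.raises(ValueError):
            evaluate.logrank_test([1, 2], [1, 1], ["a", "a"])


class TestDecisionCurve:
    def test_reference_lines(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        dca = evaluate.decision_curve(s, y, thresholds=[0.1, 0.2, 0.3])
        prev = y.mean()
        for _, row in dca.iterrows():
            odds = row.threshold / (1 - row.threshold)
            assert row.nb_treat_all == pytest.approx(prev - (1 - prev) * odds)
            assert row.nb_treat_none == 0.0

    def test_worked_example(self):
        # TP=2, FP=1 out of n=10 at p_t = 0.2
        scores = np.r_[[0.9, 0.8, 0.5], np.full(7, 0.05)]
        labels = np.r_[[1, 1, 0], np.ones(2, int), np.zeros(5, int)]
        dca = evaluate.decision_curve(scores, labels, thresholds=[0.2])
        assert dca.nb_model[0] == pytest.approx(0.2 - 0.1 * 0.25)

    def test_pt_one_excluded(self):
        dca = evaluate.decision_curve([0.5], [1], thresholds=[0.5, 1.0])
        assert (dca.threshold < 1).all() and len(dca) == 1
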