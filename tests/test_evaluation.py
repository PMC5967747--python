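"""Metrics, threshold sweeps, strategy curves and the rank-based method test."""

import itertools

import numpy as np
import pytest

from histosample import evaluation, synthetic_wsi
from histosample.evaluation import (
    bootstrap_rank_test,
    confusion_report,
    paired_sign_test,
    roc_auc,
    strategy_comparison,
    subsample_groups,
    threshold_sweep,
)
from histosample.probability_map import ProbabilityMap

from conftest import SMALL, SMALL_TILE


class TestConfusionReport:
    def test_perfect_prediction(self, rng):
        truth = (rng.random((50, 50)) < 0.3).astype(np.uint8)
        rep = confusion_report(truth, truth)
        assert rep.dice == rep.ppv == rep.npv == rep.tpr == rep.tnr == 1.0
        assert rep.fpr == rep.fnr == 0.0

    def test_disjoint_masks_have_zero_dice(self):
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[:3] = 1
        b[7:] = 1
        assert confusion_report(a, b).dice == 0.0

    def test_constructed_counts(self):
        # tp=50, fp=50, fn=50 -> dice = 100/200 = 0.5
        pred = np.zeros(200, np.uint8)
        truth = np.zeros(200, np.uint8)
        pred[:100] = 1
        truth[50:150] = 1
        rep = confusion_report(pred.reshape(10, 20), truth.reshape(10, 20))
        assert (rep.tp, rep.fp, rep.fn) == (50, 50, 50)
        assert rep.dice == 0.5

    def test_metric_identities_on_random_pairs(self, rng):
        for _ in range(200):
            pred = rng.random((12, 12)) < rng.random()
            truth = rng.random((12, 12)) < rng.random()
            rep = confusion_report(pred, truth)
            if "tpr" not in rep.undefined:
                assert rep.tpr + rep.fnr == pytest.approx(1.0)
            if "tnr" not in rep.undefined:
                assert rep.tnr + rep.fpr == pytest.approx(1.0)
            if "dice" not in rep.undefined:
                assert rep.dice == pytest.approx(
                    2 * rep.tp / (2 * rep.tp + rep.fp + rep.fn)
                )

    def test_dice_is_symmetric(self, rng):
        a = rng.random((20, 20)) < 0.4
        b = rng.random((20, 20)) < 0.4
        assert confusion_report(a, b).dice == confusion_report(b, a).dice

    def test_undefined_ratios_are_flagged_not_zeroed(self):
        rep = confusion_report(np.zeros((5, 5)), np.zeros((5, 5)))
        assert "dice" in rep.undefined and np.isnan(rep.dice)
        assert "ppv" in rep.undefined
        assert rep.tnr == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shapes"):
            confusion_report(np.zeros((3, 3)), np.zeros((4, 4)))


def _brute_force_auc(scores, labels):
    """Pair-counting definition: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.02

    def test_four_point_worked_example_and_label_swap(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 1, 0, 1]
        assert roc_auc(scores, labels) == _brute_force_auc(scores, labels) == 1.0
        swapped = [0, 0, 1, 1]  # 0.4 becomes negative, 0.35 positive
        assert roc_auc(scores, swapped) == pytest.approx(
            _brute_force_auc(scores, swapped)
        )

    def test_brute_force_agreement_with_ties(self, rng):
        scores = rng.integers(0, 5, 60) / 4  # many ties
        labels = rng.integers(0, 2, 60)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            _brute_force_auc(scores, labels)
        )

    def test_score_negation_symmetry(self, rng):
        scores = rng.random(100)  # continuous: no ties
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestThresholdSweep:
    def test_exact_map_gives_dice_one_everywhere(self, rng):
        truth = (rng.random((30, 30)) < 0.4).astype(float)
        P = ProbabilityMap(truth)
        for t, dice in threshold_sweep(P, truth.astype(np.uint8),
                                       [0.1, 0.5, 0.9]):
            assert dice == 1.0

    def test_argmax_dominates_grid(self, rng):
        P = ProbabilityMap(rng.random((40, 40)))
        truth = (rng.random((40, 40)) < 0.3).astype(np.uint8)
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
        sweep = threshold_sweep(P, truth, grid)
        dices = [d for _, d in sweep]
        assert max(dices) >= dices[len(dices) // 2]
        # brute-force re-sweep agrees pointwise
        for (t, d) in sweep[::7]:
            rep = confusion_report((P.values > t).astype(np.uint8), truth)
            assert d == rep.dice


class TestStrategyComparison:
    def test_degenerate_grid_reduces_to_single_run(self):
        slide = synthetic_wsi.generate_slide(
            synthetic_wsi.SyntheticSlideSpec(seed=5, **SMALL)
        )
        oracle = synthetic_wsi.make_noisy_oracle(slide)
        curves = strategy_comparison(
            [slide], lambda s: oracle, ["qmc_halton"], budgets=[200],
            n_seeds=1, n_per_iter=100, tile_size_k=SMALL_TILE,
        )
        curve = curves["qmc_halton"]
        assert curve.budgets == [200]
        assert len(curve.runs[200]) == 1
        assert 0.0 <= curve.mean_dice[0] <= 1.0
        assert curve.sd_dice[0] == 0.0

    def test_budget_must_be_multiple_of_iteration_size(self):
        with pytest.raises(ValueError, match="multiples"):
            strategy_comparison([], lambda s: None, ["uniform"], [150],
                                n_per_iter=100)


class TestPairedSignTest:
    def test_consistent_wins_are_significant(self):
        a = np.linspace(0.6, 0.8, 20)
        b = a - 0.05
        assert paired_sign_test(a, b) < 0.001

    def test_symmetric_differences_are_not(self, rng):
        a = rng.random(30)
        assert paired_sign_test(a, a) == 1.0


def _permutation_pvalue(x, y, n_perm=2000, seed=0):
    """Two-sample permutation test on the mean difference (independent check)."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    observed = abs(np.mean(x) - np.mean(y))
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        count += abs(pooled[: len(x)].mean() - pooled[len(x):].mean()) >= observed
    return count / n_perm


class TestBootstrapRankTest:
    def test_identical_methods_show_no_significance(self):
        scores = list(np.linspace(0.5, 0.9, 50))
        res = bootstrap_rank_test({"a": scores, "b": scores, "c": scores})
        assert not res.significant.any()
        assert res.h_statistic == 0.0

    def test_separated_methods_are_significant(self, rng):
        lo = rng.uniform(0.5, 0.6, 100)
        hi = rng.uniform(0.8, 0.9, 100)
        res = bootstrap_rank_test({"weak": lo, "strong": hi})
        i, j = res.methods.index("weak"), res.methods.index("strong")
        assert res.significant[i, j]
        assert res.mean_ranks[j] > res.mean_ranks[i]
        assert res.ranking()[0] == "strong"
        # independent permutation test agrees the gap is real
        assert _permutation_pvalue(lo, hi) < 0.05

    def test_h_statistic_matches_hand_computation(self):
        # three methods totally ordered in every one of 3 groups:
        # rank columns (1,1,1), (2,2,2), (3,3,3); pooled ranks with ties
        # give H = 7.2 / (1 - 72/720) = 8.0
        res = bootstrap_rank_test({
            "a": [0.1, 0.2, 0.3],
            "b": [0.4, 0.5, 0.6],
            "c": [0.7, 0.8, 0.9],
        })
        assert res.h_statistic == pytest.approx(8.0)

    def test_too_few_groups_or_methods_raise(self):
        with pytest.raises(ValueError, match="two methods"):
            bootstrap_rank_test({"only": [1, 2, 3]})
        with pytest.raises(ValueError, match="B >= 2"):
            bootstrap_rank_test({"a": [1.0], "b": [2.0]})


def test_subsample_groups_shape_and_determinism():
    groups = subsample_groups(50, n_groups=10, fraction=0.6, seed=3)
    again = subsample_groups(50, n_groups=10, fraction=0.6, seed=3)
    assert len(groups) == 10
    for g, h in zip(groups, again):
        assert len(g) == 30
        assert len(np.unique(g)) == 30  # without replacement within a group
        assert np.array_equal(g, h)
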