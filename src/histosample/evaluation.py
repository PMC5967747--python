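"""Segmentation metrics, threshold sweeps, strategy curves and method ranking.

A thresholded probability map is scored against ground truth pixelwise:
Dice = 2TP/(2TP+FP+FN) plus the confusion-derived rates (PPV, NPV, TPR,
TNR, FPR, FNR). Tile classifiers are ranked by ROC AUC. Sampling strategies
are compared by mean Dice at matched sample budgets over slides and seeds,
and methods are ranked by the repeated-subsample procedure: many groups of
60% of the instances, per-group performance ranks, a Kruskal-Wallis test on
the rank data and Tukey-HSD pairwise comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import adaptive, samplers
from .adaptive import AdaptiveConfig
from .probability_map import ProbabilityMap, threshold_map
from .samplers import SamplerConfig
from .synthetic_wsi import Slide


@dataclass
class EvalReport:
    """Pixel-level confusion counts and derived rates.

    Rates whose denominator is zero are NaN and listed in ``undefined``
    rather than silently reported as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    dice: float
    ppv: float
    npv: float
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "dice": self.dice, "ppv": self.ppv, "npv": self.npv,
            "tpr": self.tpr, "tnr": self.tnr, "fpr": self.fpr, "fnr": self.fnr,
            "undefined": list(self.undefined),
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_report(pred_mask: np.ndarray, truth_mask: np.ndarray) -> EvalReport:
    """Score a binary prediction against a binary ground truth."""
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask shapes differ: {pred.shape} vs {truth.shape}"
        )
    tp = int(np.logical_and(pred, truth).sum())
    fp = int(np.logical_and(pred, ~truth).sum())
    fn = int(np.logical_and(~pred, truth).sum())
    tn = pred.size - tp - fp - fn
    metrics = {
        "dice": _ratio(2 * tp, 2 * tp + fp + fn),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "tpr": _ratio(tp, tp + fn),
        "tnr": _ratio(tn, tn + fp),
        "fpr": _ratio(fp, fp + tn),
        "fnr": _ratio(fn, fn + tp),
    }
    undefined = tuple(k for k, v in metrics.items() if math.isnan(v))
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, undefined=undefined, **metrics)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (tie-aware Mann-Whitney formulation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def threshold_sweep(
    P: ProbabilityMap,
    truth_mask: np.ndarray,
    thresholds: Sequence[float],
) -> list[tuple[float, float]]:
    """Dice of the thresholded map at each threshold."""
    out = []
    for t in thresholds:
        if not (0.0 <= t <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")
        rep = confusion_report(threshold_map(P, t), truth_mask)
        out.append((float(t), rep.dice))
    return out


@dataclass
class StrategyCurve:
    """Mean +/- sd Dice per sample budget for one sampling strategy."""

    strategy: str
    budgets: list[int]
    mean_dice: list[float]
    sd_dice: list[float]
    #: per-budget Dice for every (slide, seed) run, for paired comparisons
    runs: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.budgets, self.budgets[1:])):
            raise ValueError("budgets must be strictly increasing")


def _closest_regular_step(domain: samplers.Domain, budget: int) -> int:
    """Step size whose inclusive grid count is closest to the budget."""
    span_r = domain.r_max - domain.r_min
    span_c = domain.c_max - domain.c_min
    best_s, best_err = 1, float("inf")
    for s in range(1, max(span_r, span_c) + 1):
        count = (span_r // s + 1) * (span_c // s + 1)
        err = abs(count - budget)
        if err < best_err:
            best_s, best_err = s, err
        if count < budget and err > best_err:
            break
    return best_s


def strategy_comparison(
    slides: Sequence[Slide],
    classifier_for: Callable[[Slide], object],
    strategies: Sequence[str],
    budgets: Sequence[int],
    n_seeds: int = 20,
    n_per_iter: int = 100,
    tile_size_k: int = 101,
    threshold_t: float = 0.5,
    map_grid_step: int = 1,
    base_seed: int = 0,
) -> dict[str, StrategyCurve]:
    """Mean Dice versus sample budget for each sampling strategy.

    Iterative strategies run ``max(budgets)/n_per_iter`` iterations once
    per (slide, seed) and read Dice at each requested budget from the
    per-iteration log. ``regular`` is swept by the step size whose grid
    count is closest to each budget; ``dense`` classifies every centre
    (both deterministic, evaluated once per slide). ``classifier_for``
    maps a slide to its tile classifier, so ground-truth oracles can be
    slide-specific.
    """
    budgets = sorted(int(b) for b in budgets)
    for b in budgets:
        if b % n_per_iter:
            raise ValueError("budgets must be multiples of n_per_iter")
    curves: dict[str, StrategyCurve] = {}
    for strategy in strategies:
        per_budget: dict[int, list[float]] = {b: [] for b in budgets}
        if strategy == "dense":
            for slide in slides:
                P = adaptive.run_dense(slide, classifier_for(slide), tile_size_k)
                d = confusion_report(threshold_map(P, threshold_t), slide.mask).dice
                for b in budgets:
                    per_budget[b].append(d)
        elif strategy == "regular":
            for slide in slides:
                domain = samplers.valid_center_domain(slide.shape, tile_size_k)
                clf = classifier_for(slide)
                for b in budgets:
                    step = _closest_regular_step(domain, b)
                    P, _ = adaptive.run_regular(
                        slide, clf, step, tile_size_k, map_grid_step
                    )
                    per_budget[b].append(
                        confusion_report(threshold_map(P, threshold_t), slide.mask).dice
                    )
        else:
            t_max = budgets[-1] // n_per_iter
            dice_iters = tuple(b // n_per_iter for b in budgets)
            for s_idx, slide in enumerate(slides):
                clf = classifier_for(slide)
                for seed in range(n_seeds):
                    config = AdaptiveConfig(
                        t_iterations=t_max,
                        n_per_iter=n_per_iter,
                        sampler=SamplerConfig(kind=strategy, n_per_iter=n_per_iter),
                        tile_size_k=tile_size_k,
                        threshold_t=threshold_t,
                        seed=base_seed + 1000 * s_idx + seed,
                        map_grid_step=map_grid_step,
                        dice_iterations=dice_iters,
                    )
                    result = adaptive.run_adaptive(slide, clf, config)
                    by_iter = {
                        rec["iteration"]: rec.get("dice")
                        for rec in result.per_iteration
                    }
                    for b in budgets:
                        per_budget[b].append(by_iter[b // n_per_iter])
        curves[strategy] = StrategyCurve(
            strategy=strategy,
            budgets=budgets,
            mean_dice=[float(np.mean(per_budget[b])) for b in budgets],
            sd_dice=[float(np.std(per_budget[b])) for b in budgets],
            runs={b: np.asarray(per_budget[b]) for b in budgets},
        )
    return curves


def paired_sign_test(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided sign-test p-value for median(a - b) > 0 (ties dropped)."""
    diff = np.asarray(a) - np.asarray(b)
    diff = diff[diff != 0]
    if len(diff) == 0:
        return 1.0
    wins = int((diff > 0).sum())
    return float(stats.binomtest(wins, len(diff), 0.5, alternative="greater").pvalue)


@dataclass
class RankTestResult:
    methods: list[str]
    mean_ranks: np.ndarray  # higher = better
    h_statistic: float
    p_value: float
    significant: np.ndarray  # k x k boolean, pairwise at alpha

    def ranking(self) -> list[str]:
        order = np.argsort(-self.mean_ranks)
        return [self.methods[i] for i in order]


def bootstrap_rank_test(
    per_method_scores: dict[str, Sequence[float]],
    alpha: float = 0.05,
) -> RankTestResult:
    """Rank methods over repeated resamples and test pairwise differences.

    Input: per method, one score per resample group (equal count B >= 2).
    Methods are ranked within each group (average ranks on ties, larger
    score = larger rank), the Kruskal-Wallis H statistic is computed on the
    per-method rank samples, and Tukey's honestly-significant-difference
    criterion applied to the rank data gives the pairwise significance
    matrix at ``alpha``.
    """
    methods = list(per_method_scores)
    if len(methods) < 2:
        raise ValueError("need at least two methods to rank")
    scores = np.column_stack(
        [np.asarray(per_method_scores[m], dtype=np.float64) for m in methods]
    )
    b = scores.shape[0]
    if b < 2:
        raise ValueError("need at least two resample groups (B >= 2)")
    ranks = np.apply_along_axis(stats.rankdata, 1, scores)  # B x k
    rank_groups = [ranks[:, j] for j in range(len(methods))]
    if all(np.ptp(g) == 0 and np.allclose(g, rank_groups[0]) for g in rank_groups):
        # identical rank profiles: H is 0/undefined, nothing is significant
        h, p = 0.0, 1.0
        sig = np.zeros((len(methods), len(methods)), dtype=bool)
    else:
        h, p = stats.kruskal(*rank_groups)
        with np.errstate(divide="ignore", invalid="ignore"):
            # zero-variance rank columns (a method always ranked the same)
            # give infinite studentised statistics; the comparison is valid
            tukey = stats.tukey_hsd(*rank_groups)
        sig = np.asarray(tukey.pvalue) < alpha
        np.fill_diagonal(sig, False)
    return RankTestResult(
        methods=methods,
        mean_ranks=ranks.mean(axis=0),
        h_statistic=float(h),
        p_value=float(p),
        significant=sig,
    )


def subsample_groups(
    n_instances: int, n_groups: int = 100, fraction: float = 0.6, seed: int = 0
) -> list[np.ndarray]:
    """Index sets for the repeated-subsample protocol: ``n_groups`` draws of
    ``fraction`` of the instances, without replacement within a group."""
    rng = np.random.default_rng(seed)
    size = max(1, int(round(fraction * n_instances)))
    return [
        rng.choice(n_instances, size=size, replace=False) for _ in range(n_groups)
    ]


def plot_strategy_curves(curves: dict[str, StrategyCurve], path: str) -> None:
    """Dice-versus-budget plot (log-x), one line per strategy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, curve in curves.items():
        ax.errorbar(
            curve.budgets, curve.mean_dice, yerr=curve.sd_dice, label=name,
            marker="o", capsize=2,
        )
    ax.set_xscale("log")
    ax.set_xlabel("number of tile samples")
    ax.set_ylabel("mean Dice")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_threshold_sweep(
    sweep: list[tuple[float, float]], path: str, label: str = ""
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, d = zip(*sweep)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(t, d, marker=".", label=label or None)
    ax.set_xlabel("probability threshold")
    ax.set_ylabel("Dice")
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
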