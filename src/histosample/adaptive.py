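"""The adaptive sampling loop: classify, interpolate, rank by gradient.

One run alternates exploration and exploitation against a fixed budget of
T iterations times N tiles:

1. iteration 1 classifies N centres drawn from the configured base sampler
   (uniform or a low-discrepancy sequence);
2. every later iteration interpolates a probability map from ALL samples
   classified so far, computes its gradient magnitude, draws 2N fresh
   candidates from the base sampler and classifies the N with the largest
   magnitude — concentrating effort on class boundaries, where the map is
   most uncertain.

Previously classified centres are cached and never re-classified;
replacement candidates come from continuing the same sampler stream, so the
total classified count is exactly T*N. The map is cumulative across
iterations: the sample set only grows, which is what makes each iteration's
estimate strictly better informed than the last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import probability_map as pmap
from . import samplers, tile_ops
from .probability_map import GradientMap, ProbabilityMap, TileSampleSet
from .samplers import Domain, SamplerConfig
from .synthetic_wsi import Slide

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdaptiveConfig:
    """Run parameters for the adaptive loop.

    ``seed`` is the master seed of the run and overrides the sampler
    config's own seed. ``map_grid_step`` > 1 evaluates intermediate maps on
    a coarse lattice (see probability_map) — a cost option for large
    images, off by default. ``dice_iterations`` limits which iterations
    record a Dice diagnostic (None = every iteration when the slide has a
    mask; empty = none).
    """

    t_iterations: int = 20
    n_per_iter: int = 100
    sampler: SamplerConfig = field(
        default_factory=lambda: SamplerConfig(kind="grad_qmc_halton")
    )
    tile_size_k: int = tile_ops.DEFAULT_TILE_SIZE
    classify_non_tissue: bool = True
    threshold_t: float = 0.5
    seed: int = 0
    map_grid_step: int = 1
    dice_iterations: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.t_iterations < 1:
            raise ValueError("t_iterations must be >= 1")
        if self.n_per_iter < 1:
            raise ValueError("n_per_iter must be >= 1")
        if not (0.0 <= self.threshold_t <= 1.0):
            raise ValueError("threshold_t must lie in [0, 1]")
        if self.map_grid_step < 1:
            raise ValueError("map_grid_step must be >= 1")

    @property
    def total_budget(self) -> int:
        return self.t_iterations * self.n_per_iter


@dataclass
class AdaptiveResult:
    final_map: ProbabilityMap
    samples: TileSampleSet
    per_iteration: list[dict]
    classifier_calls: int


def _dice(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = float(np.logical_and(pred, truth).sum())
    denom = float(pred.sum()) + float(truth.sum())
    return 2.0 * tp / denom if denom > 0 else float("nan")


def _classify(
    slide: Slide,
    classifier,
    centers: np.ndarray,
    config: AdaptiveConfig,
) -> tuple[np.ndarray, int]:
    """Probabilities for a batch of centres, honouring the tissue gate.

    With ``classify_non_tissue`` off, blank-glass tiles get probability 0
    without a classifier call (the call count is returned separately so the
    budget ledger stays exact).
    """
    try:
        if config.classify_non_tissue:
            probs = classifier.predict_proba_at(slide, centers, config.tile_size_k)
            return np.clip(np.asarray(probs, dtype=np.float64), 0.0, 1.0), len(centers)
        tissue = tile_ops.is_tissue_at(slide, centers, config.tile_size_k)
        probs = np.zeros(len(centers))
        if tissue.any():
            probs[tissue] = classifier.predict_proba_at(
                slide, centers[tissue], config.tile_size_k
            )
        return np.clip(probs, 0.0, 1.0), int(tissue.sum())
    except Exception as exc:
        first = tuple(int(v) for v in centers[0]) if len(centers) else None
        raise RuntimeError(
            f"classifier failed on batch starting at centre {first}: {exc}"
        ) from exc


def run_adaptive(slide: Slide, classifier, config: AdaptiveConfig) -> AdaptiveResult:
    """Run the full adaptive loop and return the final probability map.

    Deterministic given ``config.seed``. Raises if the slide cannot host
    T*N distinct tile centres, or if the sampler kind is non-iterative
    (``regular``/``dense`` — see :func:`run_regular` / :func:`run_dense`).
    """
    kind = config.sampler.kind
    if samplers.base_kind(kind) == "regular":
        raise ValueError(
            f"sampler kind {kind!r} is not iterative; use run_regular/run_dense"
        )
    h, w = slide.shape
    domain = samplers.valid_center_domain(slide.shape, config.tile_size_k)
    if domain.size < config.total_budget:
        raise ValueError(
            f"slide hosts {domain.size} distinct centres < budget "
            f"{config.total_budget}"
        )
    gradient_mode = config.sampler.is_gradient
    if config.dice_iterations is None:
        dice_at = (
            set(range(1, config.t_iterations + 1)) if slide.mask is not None else set()
        )
    else:
        dice_at = set(config.dice_iterations)
    step = config.map_grid_step

    state = samplers.make_state(kind, config.seed, domain)
    samples = TileSampleSet.empty()
    classified: set[tuple[int, int]] = set()
    per_iteration: list[dict] = []
    calls = 0
    final_full: Optional[ProbabilityMap] = None

    pending, state = samplers.draw_unique(domain, config.n_per_iter, state)
    for i in range(1, config.t_iterations + 1):
        probs, n_calls = _classify(slide, classifier, pending, config)
        calls += n_calls
        samples = samples.extend(pending, probs, i)
        classified.update((int(r), int(c)) for r, c in pending)

        need_full = (i == config.t_iterations) or (i in dice_at)
        need_grad = gradient_mode and i < config.t_iterations

        full_map: Optional[ProbabilityMap] = None
        grad_mag: Optional[np.ndarray] = None
        grad_spacing = 1
        if step == 1:
            if need_full or need_grad:
                full_map = pmap.interpolate_map(samples, h, w)
            if need_grad:
                grad_mag = pmap.gradient(full_map).magnitude
        else:
            if need_full or need_grad:
                coarse, rows, cols = pmap._coarse_lattice(samples, h, w, step)
            if need_grad:
                d_dy, d_dx = np.gradient(coarse, float(step))
                grad_mag = np.hypot(d_dx, d_dy)
                grad_spacing = step
            if need_full:
                from scipy.interpolate import RegularGridInterpolator

                rgi = RegularGridInterpolator(
                    (rows, cols), coarse, method="linear"
                )
                rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
                full_map = ProbabilityMap(
                    np.clip(
                        rgi(np.column_stack([rr.ravel(), cc.ravel()]).astype(float))
                        .reshape(h, w),
                        0.0,
                        1.0,
                    )
                )

        record = {"iteration": i, "n_classified_cum": len(samples),
                  "classifier_calls_cum": calls}
        if i in dice_at and slide.mask is not None and full_map is not None:
            record["dice"] = _dice(
                pmap.threshold_map(full_map, config.threshold_t), slide.mask
            )
        per_iteration.append(record)
        if full_map is not None:
            final_full = full_map

        if i < config.t_iterations:
            if gradient_mode:
                pending, state = samplers.gradient_ranked_sample(
                    grad_mag, domain, config.n_per_iter, state,
                    exclude=classified, grid_step=grad_spacing,
                )
            else:
                pending, state = samplers.draw_unique(
                    domain, config.n_per_iter, state, exclude=classified
                )

    assert final_full is not None
    assert len(samples) == config.total_budget
    return AdaptiveResult(
        final_map=final_full,
        samples=samples,
        per_iteration=per_iteration,
        classifier_calls=calls,
    )


def run_dense(
    slide: Slide,
    classifier,
    tile_size_k: int = tile_ops.DEFAULT_TILE_SIZE,
) -> ProbabilityMap:
    """Classify every valid tile centre (step-1 regular sampling).

    The per-pixel map needs no interpolation where a centre was classified;
    the half-tile margin is filled by edge replication. This is the
    accuracy ceiling the adaptive loop approximates, and is intended for
    modest image sizes or classifiers with a vectorised coordinate path.
    """
    h, w = slide.shape
    domain = samplers.valid_center_domain(slide.shape, tile_size_k)
    centers = samplers.regular_grid(domain, 1)
    probs = np.clip(
        np.asarray(
            classifier.predict_proba_at(slide, centers, tile_size_k), dtype=np.float64
        ),
        0.0,
        1.0,
    )
    nr = domain.r_max - domain.r_min + 1
    nc = domain.c_max - domain.c_min + 1
    inner = probs.reshape(nr, nc)
    half = tile_size_k // 2
    values = np.pad(inner, ((half, h - half - nr), (half, w - half - nc)), mode="edge")
    return ProbabilityMap(values)


def run_regular(
    slide: Slide,
    classifier,
    step_s: int,
    tile_size_k: int = tile_ops.DEFAULT_TILE_SIZE,
    map_grid_step: int = 1,
) -> tuple[ProbabilityMap, TileSampleSet]:
    """Classify a regular grid of centres and interpolate the map."""
    h, w = slide.shape
    domain = samplers.valid_center_domain(slide.shape, tile_size_k)
    centers = samplers.regular_grid(domain, step_s)
    if len(centers) == 0:
        raise ValueError("empty sampling domain")
    probs = np.clip(
        np.asarray(
            classifier.predict_proba_at(slide, centers, tile_size_k), dtype=np.float64
        ),
        0.0,
        1.0,
    )
    samples = TileSampleSet.empty().extend(centers, probs, 1)
    return pmap.interpolate_map(samples, h, w, grid_step=map_grid_step), samples
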