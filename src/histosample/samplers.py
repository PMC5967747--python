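"""Tile-centre sampling strategies.

Seven strategies are supported: ``regular`` grids (``dense`` is the step-1
extreme), ``uniform`` random, the two quasi-Monte-Carlo low-discrepancy
sequences ``qmc_sobol`` and ``qmc_halton``, and the gradient-ranked variants
``grad_uniform`` / ``grad_qmc_sobol`` / ``grad_qmc_halton`` which draw twice
the requested candidates from their base sampler and keep the half with the
largest probability-gradient magnitude.

QMC conventions, fixed for reproducibility: unscrambled sequences, no leap,
index 0 (the origin point) skipped. Continuing a sequence from a saved state
reproduces exactly the points a single longer run would emit, which is what
lets the adaptive loop add samples incrementally without discarding earlier
ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.stats import qmc

SAMPLER_KINDS = (
    "regular",
    "dense",
    "uniform",
    "qmc_sobol",
    "qmc_halton",
    "grad_uniform",
    "grad_qmc_sobol",
    "grad_qmc_halton",
)


@dataclass(frozen=True)
class Domain:
    """Inclusive rectangle of valid tile centres."""

    r_min: int
    r_max: int
    c_min: int
    c_max: int

    @property
    def size(self) -> int:
        if self.r_max < self.r_min or self.c_max < self.c_min:
            return 0
        return (self.r_max - self.r_min + 1) * (self.c_max - self.c_min + 1)

    def contains(self, centers: np.ndarray) -> np.ndarray:
        r, c = centers[:, 0], centers[:, 1]
        return (
            (r >= self.r_min) & (r <= self.r_max)
            & (c >= self.c_min) & (c <= self.c_max)
        )


def valid_center_domain(shape: tuple[int, int], size_k: int) -> Domain:
    """Centres at which a k x k tile fits fully inside an HxW slide."""
    half = size_k // 2
    h, w = shape
    return Domain(half, h - 1 - half, half, w - 1 - half)


@dataclass(frozen=True)
class SamplerConfig:
    kind: str = "grad_qmc_halton"
    step_s: int = 101  # regular sampling only
    n_per_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SAMPLER_KINDS:
            raise ValueError(f"unknown sampler kind {self.kind!r}")
        if self.step_s < 1:
            raise ValueError("step_s must be >= 1")
        if self.n_per_iter < 1:
            raise ValueError("n_per_iter must be >= 1")

    @property
    def base_kind(self) -> str:
        return base_kind(self.kind)

    @property
    def is_gradient(self) -> bool:
        return self.kind.startswith("grad_")


def base_kind(kind: str) -> str:
    """The underlying point source of a (possibly gradient-ranked) sampler."""
    if kind.startswith("grad_"):
        kind = kind[len("grad_"):]
    if kind == "dense":
        return "regular"
    return kind


@dataclass
class SamplerState:
    """Resumable sampling position.

    ``sequence_index`` counts low-discrepancy points already emitted (QMC
    kinds); ``rng`` carries the pseudorandom stream (uniform kind). The
    prefix property holds: drawing n then m points from a state yields the
    same set as drawing n+m at once.
    """

    kind: str
    seed: int
    domain: Domain
    sequence_index: int = 0
    rng: Optional[np.random.Generator] = None

    def __post_init__(self) -> None:
        if self.kind == "uniform" and self.rng is None:
            self.rng = np.random.default_rng(self.seed)


def make_state(kind: str, seed: int, domain: Domain) -> SamplerState:
    return SamplerState(kind=base_kind(kind), seed=seed, domain=domain)


def regular_grid(domain: Domain, step_s: int) -> np.ndarray:
    """Row-major centres at r_min + i*s, c_min + j*s inside the domain.

    The inclusive-endpoint count is (floor((r_max-r_min)/s)+1) *
    (floor((c_max-c_min)/s)+1); step 1 enumerates every valid centre once.
    """
    if step_s < 1:
        raise ValueError("step_s must be >= 1")
    if domain.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    rows = np.arange(domain.r_min, domain.r_max + 1, step_s)
    cols = np.arange(domain.c_min, domain.c_max + 1, step_s)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(np.int64)


def uniform_random(
    domain: Domain, n: int, state: SamplerState
) -> tuple[np.ndarray, SamplerState]:
    """n i.i.d. integer centres, uniform over the domain."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = state.rng
    r = rng.integers(domain.r_min, domain.r_max + 1, size=n)
    c = rng.integers(domain.c_min, domain.c_max + 1, size=n)
    centers = np.column_stack([r, c]).astype(np.int64)
    return centers, state


def _make_engine(kind: str, start_index: int) -> qmc.QMCEngine:
    if kind == "qmc_sobol":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            engine = qmc.Sobol(d=2, scramble=False)
    elif kind == "qmc_halton":
        engine = qmc.Halton(d=2, scramble=False)
    else:
        raise ValueError(f"not a QMC kind: {kind!r}")
    engine.fast_forward(1 + start_index)  # skip the degenerate origin point
    return engine


def qmc_unit_points(kind: str, n: int, start_index: int = 0) -> np.ndarray:
    """Raw unit-square sequence points (after the skipped origin)."""
    engine = _make_engine(kind, start_index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return engine.random(n)


def qmc_sequence(
    kind: str, domain: Domain, n: int, state: SamplerState
) -> tuple[np.ndarray, SamplerState]:
    """Next n points of the sequence, mapped onto the domain's integer grid.

    Unit-square coordinates map affinely onto [r_min, r_max] x [c_min, c_max]
    by flooring u * span, so every integer centre is reachable and points
    stay inside the inclusive rectangle.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = qmc_unit_points(kind, n, state.sequence_index)
    nr = domain.r_max - domain.r_min + 1
    nc = domain.c_max - domain.c_min + 1
    r = domain.r_min + np.minimum((u[:, 0] * nr).astype(np.int64), nr - 1)
    c = domain.c_min + np.minimum((u[:, 1] * nc).astype(np.int64), nc - 1)
    centers = np.column_stack([r, c])
    new_state = replace(state, sequence_index=state.sequence_index + n)
    new_state.rng = state.rng
    return centers, new_state


def _draw(kind: str, domain: Domain, n: int, state: SamplerState):
    if kind == "uniform":
        return uniform_random(domain, n, state)
    if kind in ("qmc_sobol", "qmc_halton"):
        return qmc_sequence(kind, domain, n, state)
    raise ValueError(f"kind {kind!r} is not an incremental sampler")


def draw_unique(
    domain: Domain,
    n: int,
    state: SamplerState,
    exclude: Optional[set[tuple[int, int]]] = None,
    max_rounds: int = 200,
) -> tuple[np.ndarray, SamplerState]:
    """Draw n distinct centres not in ``exclude`` by continuing the sequence.

    Duplicates (within the draw or against ``exclude``) are replaced by
    further points from the same stream, keeping the per-iteration budget
    exact. Raises if the domain cannot supply n fresh centres.
    """
    exclude = exclude or set()
    if domain.size - len(exclude) < n:
        raise ValueError(
            f"domain has only {domain.size - len(exclude)} unclassified "
            f"centres; cannot draw {n}"
        )
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    for _ in range(max_rounds):
        need = n - len(out)
        if need == 0:
            break
        batch, state = _draw(state.kind, domain, max(need, 1), state)
        for r, c in batch:
            key = (int(r), int(c))
            if key in seen or key in exclude:
                continue
            seen.add(key)
            out.append(key)
            if len(out) == n:
                break
    if len(out) < n:
        raise RuntimeError("sampler failed to produce enough fresh centres")
    return np.array(out, dtype=np.int64), state


def gradient_ranked_sample(
    gradient_magnitude: np.ndarray,
    domain: Domain,
    n: int,
    state: SamplerState,
    exclude: Optional[set[tuple[int, int]]] = None,
    grid_step: int = 1,
) -> tuple[np.ndarray, SamplerState]:
    """Top-n of 2n base-sampler candidates, ranked by |grad P|.

    The gradient is looked up at the nearest stored pixel (``grid_step`` > 1
    means the magnitude image is a coarse lattice with that spacing; lookup
    rounds to the nearest node). Sorting is stable and descending, so ties
    are broken by candidate emission order.
    """
    if n == 0:
        return np.empty((0, 2), dtype=np.int64), state
    candidates, state = draw_unique(domain, 2 * n, state, exclude)
    r = np.clip(
        np.rint(candidates[:, 0] / grid_step).astype(np.int64),
        0, gradient_magnitude.shape[0] - 1,
    )
    c = np.clip(
        np.rint(candidates[:, 1] / grid_step).astype(np.int64),
        0, gradient_magnitude.shape[1] - 1,
    )
    values = gradient_magnitude[r, c]
    order = np.argsort(-values, kind="stable")
    return candidates[order[:n]], state
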