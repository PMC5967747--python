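"""Dense probability maps from scattered tile predictions.

Scattered tile probabilities are extended to every pixel by piecewise-cubic
Clough-Tocher interpolation over a Delaunay triangulation of the sample
centres; pixels outside the convex hull take the nearest sample's value
(constant extrapolation — unbounded cubic extrapolation is never used), and
the result is clipped to [0, 1]. The map's spatial gradient (central
differences inside, one-sided at the borders) and its magnitude mark the
transition zones between tissue classes that drive adaptive acquisition.

Axis convention: x is the column direction, y the row direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import (
    CloughTocher2DInterpolator,
    NearestNDInterpolator,
    RegularGridInterpolator,
)
from scipy.spatial import QhullError

logger = logging.getLogger(__name__)


@dataclass
class TileSampleSet:
    """Accumulated tile centres with classifier probabilities."""

    centers: np.ndarray  # n x 2 int (row, col)
    probabilities: np.ndarray  # n floats in [0, 1]
    iteration_of: np.ndarray  # n ints

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.int64).reshape(-1, 2)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64).ravel()
        self.iteration_of = np.asarray(self.iteration_of, dtype=np.int64).ravel()
        n = len(self.centers)
        if len(self.probabilities) != n or len(self.iteration_of) != n:
            raise ValueError("centers, probabilities and iterations must align")
        if n and (self.probabilities.min() < 0 or self.probabilities.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if n and len(np.unique(self.centers, axis=0)) != n:
            raise ValueError("sample centres must be unique")

    def __len__(self) -> int:
        return len(self.centers)

    @classmethod
    def empty(cls) -> "TileSampleSet":
        return cls(np.empty((0, 2), np.int64), np.empty(0), np.empty(0, np.int64))

    def extend(
        self, centers: np.ndarray, probabilities: np.ndarray, iteration: int
    ) -> "TileSampleSet":
        """New set with the given samples appended (validates uniqueness)."""
        centers = np.asarray(centers, dtype=np.int64).reshape(-1, 2)
        return TileSampleSet(
            np.vstack([self.centers, centers]),
            np.concatenate([self.probabilities, probabilities]),
            np.concatenate(
                [self.iteration_of, np.full(len(centers), iteration, np.int64)]
            ),
        )


@dataclass
class ProbabilityMap:
    values: np.ndarray  # H x W in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("probability map must be a 2-D grid")
        if not np.isfinite(self.values).all():
            raise ValueError("probability map must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GradientMap:
    d_dx: np.ndarray  # dP/d(col)
    d_dy: np.ndarray  # dP/d(row)
    magnitude: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.magnitude is None:
            self.magnitude = np.hypot(self.d_dx, self.d_dy)


def _interpolate_on_points(
    samples: TileSampleSet, points: np.ndarray
) -> np.ndarray:
    """Clough-Tocher values at query points, nearest-fill outside the hull
    (and everywhere when the triangulation is degenerate)."""
    pts = samples.centers.astype(np.float64)
    vals = samples.probabilities
    nearest = NearestNDInterpolator(pts, vals)
    if len(samples) >= 4:
        try:
            ct = CloughTocher2DInterpolator(pts, vals)
            out = ct(points)
            hole = np.isnan(out)
            if hole.any():
                out[hole] = nearest(points[hole])
            return out
        except QhullError:
            pass
    logger.warning(
        "scattered cubic interpolation needs >= 4 non-collinear centres "
        "(got %d); falling back to nearest-neighbour fill", len(samples)
    )
    return nearest(points)


def interpolate_map(
    samples: TileSampleSet,
    height: int,
    width: int,
    grid_step: int = 1,
) -> ProbabilityMap:
    """Dense H x W probability map from scattered samples.

    With ``grid_step`` > 1 the scattered interpolant is evaluated on a
    coarser lattice and bilinearly upsampled — a cost-saving option for
    large images, off (step 1) by default. The map is exact at sample
    centres (to interpolation tolerance) and clipped to [0, 1].
    """
    if len(samples) == 0:
        raise ValueError("cannot interpolate an empty sample set")
    if grid_step == 1:
        rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
        q = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
        values = _interpolate_on_points(samples, q).reshape(height, width)
    else:
        coarse, rows, cols = _coarse_lattice(samples, height, width, grid_step)
        rgi = RegularGridInterpolator(
            (rows, cols), coarse, method="linear", bounds_error=False, fill_value=None
        )
        rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
        values = rgi(
            np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
        ).reshape(height, width)
    return ProbabilityMap(np.clip(values, 0.0, 1.0))


def _coarse_lattice(
    samples: TileSampleSet, height: int, width: int, grid_step: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the scattered interpolant on a step-spaced lattice covering
    the image (last row/column always included)."""
    rows = np.arange(0, height, grid_step)
    if rows[-1] != height - 1:
        rows = np.append(rows, height - 1)
    cols = np.arange(0, width, grid_step)
    if cols[-1] != width - 1:
        cols = np.append(cols, width - 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    q = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    coarse = np.clip(
        _interpolate_on_points(samples, q).reshape(len(rows), len(cols)), 0.0, 1.0
    )
    return coarse, rows.astype(np.float64), cols.astype(np.float64)


def gradient(P: ProbabilityMap, spacing: float = 1.0) -> GradientMap:
    """Spatial derivatives of the map: central differences in the interior,
    one-sided at the edges; magnitude is the elementwise Euclidean norm."""
    if P.values.shape[0] < 2 or P.values.shape[1] < 2:
        raise ValueError("gradient needs at least a 2x2 map")
    d_dy, d_dx = np.gradient(P.values, spacing)
    return GradientMap(d_dx=d_dx, d_dy=d_dy)


def threshold_map(P: ProbabilityMap, t: float) -> np.ndarray:
    """Binary mask: 1 where P > t (strict), else 0."""
    return (P.values > t).astype(np.uint8)
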