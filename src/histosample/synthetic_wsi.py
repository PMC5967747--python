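"""Synthetic H&E-like slides with ground-truth invasive masks.

Real whole-slide cohorts (scanned at 40x, downsampled 32:1) are large and
access-restricted, so every downstream stage of the pipeline is exercised on
generated slides containing the three pixel populations the method assumes:

* a near-white glass background (rejected by the tissue filter),
* a benign-tissue texture (eosin-pink, Gaussian intensity jitter),
* irregular "invasive" blobs with a distinct colour signature
  (hematoxylin-purple by default) whose union is the ground-truth mask.

Blobs are radially perturbed ellipses: real tumour outlines are free-form
pathologist annotations with no canonical shape statistics, and perturbed
ellipses produce the boundary heterogeneity the gradient-guided sampler is
designed to exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of a generated slide; the seed fully determines the output.

    ``target_invasive_fraction`` is the fraction of *tissue* (not image) area
    covered by invasive blobs, met to within about +/-20% by analytic radius
    choice plus one corrective rescale. Colour means are 8-bit RGB triples;
    the benign and invasive means must differ by at least ``texture_noise_sd``
    in some channel, otherwise the two classes are unlearnable by
    construction and the spec is rejected.
    """

    height: int = 1024
    width: int = 1024
    n_invasive_blobs: int = 2
    target_invasive_fraction: float = 0.25
    tissue_fraction: float = 0.6
    benign_color_mean: tuple[float, float, float] = (226.0, 176.0, 204.0)
    invasive_color_mean: tuple[float, float, float] = (148.0, 112.0, 170.0)
    texture_noise_sd: float = 12.0
    blob_irregularity: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.height < 256 or self.width < 256:
            raise ValueError("slide must be at least 256x256 pixels")
        if self.n_invasive_blobs < 0:
            raise ValueError("n_invasive_blobs must be >= 0")
        if not (0.0 <= self.target_invasive_fraction < 1.0):
            raise ValueError("target_invasive_fraction must lie in [0, 1)")
        if not (0.0 < self.tissue_fraction <= 1.0):
            raise ValueError("tissue_fraction must lie in (0, 1]")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")
        if self.blob_irregularity < 0:
            raise ValueError("blob_irregularity must be >= 0")
        for name in ("benign_color_mean", "invasive_color_mean"):
            col = getattr(self, name)
            if len(col) != 3 or not all(0 <= v <= 255 for v in col):
                raise ValueError(f"{name} must be an RGB triple in [0, 255]")
        diff = max(
            abs(b - i)
            for b, i in zip(self.benign_color_mean, self.invasive_color_mean)
        )
        if diff < max(self.texture_noise_sd, 1.0):
            raise ValueError(
                "benign and invasive colour means must differ by at least "
                "texture_noise_sd in one channel; classes would be unlearnable"
            )


@dataclass
class Slide:
    """An RGB pixel grid standing in for a 32:1-downsampled WSI.

    ``pixel_spacing`` is metadata only (micrometres per pixel at the working
    resolution). ``mask`` marks invasive pixels with 1 and is present for
    synthetic slides.
    """

    pixels: np.ndarray  # H x W x 3, uint8
    pixel_spacing: float = 7.86  # 0.2456 um/px at 40x, downsampled 32:1
    mask: Optional[np.ndarray] = None  # H x W, values in {0, 1}

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an HxWx3 array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        if self.mask is not None:
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError("mask shape must match pixel grid")
            vals = np.unique(self.mask)
            if not np.isin(vals, [0, 1]).all():
                raise ValueError("mask values must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _perturbed_ellipse(
    center: tuple[float, float],
    semi_r: float,
    semi_c: float,
    irregularity: float,
    rng: np.random.Generator,
    n_vertices: int = 360,
    n_harmonics: int = 6,
) -> tuple[np.ndarray, np.ndarray]:
    """Polygon vertices of an ellipse whose radius is modulated by a random
    low-frequency Fourier series of relative amplitude ``irregularity``."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    mod = np.zeros_like(theta)
    if irregularity > 0:
        amps = rng.normal(size=n_harmonics)
        phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
        for h, (a, p) in enumerate(zip(amps, phases), start=2):
            mod += a * np.cos(h * theta + p)
        peak = np.abs(mod).max()
        if peak > 0:
            mod = mod / peak * irregularity
    radius = 1.0 + mod
    rows = center[0] + semi_r * radius * np.sin(theta)
    cols = center[1] + semi_c * radius * np.cos(theta)
    return rows, cols


def _rasterize(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(rows, cols, shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def _tissue_region(spec: SyntheticSlideSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    if spec.tissue_fraction >= 0.999:
        return np.ones((h, w), dtype=bool)
    # Semi-axes chosen so the ellipse area matches the requested fraction,
    # clipped so the region stays inside the frame.
    a0, b0 = h / 2.0, w / 2.0
    scale = np.sqrt(spec.tissue_fraction * h * w / (np.pi * a0 * b0))
    a = min(a0 * scale, h / 2.0 - 2)
    b = min(b0 * scale, w / 2.0 - 2)
    rows, cols = _perturbed_ellipse((h / 2.0, w / 2.0), a, b, 0.06, rng)
    region = _rasterize(rows, cols, (h, w))
    if not region.any():
        raise ValueError("degenerate spec: tissue region has zero area")
    return region


def generate_slide(spec: SyntheticSlideSpec) -> Slide:
    """Generate a synthetic slide with its ground-truth invasive mask.

    Pure function of ``spec``: identical specs give bit-identical output.
    Raises ``ValueError`` naming the failed constraint for degenerate specs
    (zero tissue area, blobs that cannot be placed inside the tissue).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    tissue = _tissue_region(spec, rng)
    tissue_area = int(tissue.sum())

    mask = np.zeros((h, w), dtype=bool)
    if spec.n_invasive_blobs > 0:
        if spec.target_invasive_fraction <= 0:
            raise ValueError(
                "degenerate spec: n_invasive_blobs > 0 requires "
                "target_invasive_fraction > 0"
            )
        target_area = spec.target_invasive_fraction * tissue_area
        blobs, geoms = _place_blobs(spec, rng, tissue, target_area)
        mask = np.logical_or.reduce(blobs) if blobs else mask
        # One corrective rescale if the union area drifted beyond ~10%.
        actual = mask.sum()
        if actual > 0 and abs(actual / target_area - 1.0) > 0.10:
            factor = np.sqrt(target_area / actual)
            rescaled = [
                _rasterize(b_r * factor + (1 - factor) * cr,
                           b_c * factor + (1 - factor) * cc, (h, w))
                for (b_r, b_c, cr, cc) in geoms
            ]
            candidate = np.logical_or.reduce(rescaled)
            if not candidate[~tissue].any():
                mask = candidate

    pixels = np.empty((h, w, 3), dtype=np.float64)
    # Near-white glass background: mean >= 245 with tiny jitter so the
    # sd/mean tissue filter rejects it.
    pixels[:] = 252.0 + rng.normal(0.0, 1.5, size=(h, w, 3))
    benign = tissue & ~mask
    noise = rng.normal(0.0, spec.texture_noise_sd, size=(h, w, 3))
    for ch in range(3):
        plane = pixels[..., ch]
        plane[benign] = spec.benign_color_mean[ch] + noise[..., ch][benign]
        plane[mask] = spec.invasive_color_mean[ch] + noise[..., ch][mask]
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)

    return Slide(pixels=pixels, mask=mask.astype(np.uint8))


def _place_blobs(
    spec: SyntheticSlideSpec,
    rng: np.random.Generator,
    tissue: np.ndarray,
    target_area: float,
) -> tuple[list[np.ndarray], list[tuple[np.ndarray, np.ndarray, float, float]]]:
    """Place non-overlapping perturbed-ellipse blobs fully inside the tissue."""
    geoms: list[tuple[np.ndarray, np.ndarray, float, float]] = []
    h, w = tissue.shape
    n = spec.n_invasive_blobs
    per_blob = target_area / n
    base_radius = np.sqrt(per_blob / np.pi)
    if base_radius < 2:
        raise ValueError(
            "degenerate spec: per-blob area below the raster resolution"
        )
    tissue_rows, tissue_cols = np.nonzero(tissue)
    occupied = np.zeros_like(tissue)
    blobs: list[np.ndarray] = []
    for _ in range(n):
        placed = False
        for _attempt in range(300):
            idx = rng.integers(0, tissue_rows.size)
            cr, cc = float(tissue_rows[idx]), float(tissue_cols[idx])
            # mild eccentricity for visual variety
            ecc = rng.uniform(0.8, 1.25)
            rows, cols = _perturbed_ellipse(
                (cr, cc), base_radius * ecc, base_radius / ecc,
                spec.blob_irregularity, rng,
            )
            if rows.min() < 0 or cols.min() < 0 or rows.max() >= h or cols.max() >= w:
                continue
            blob = _rasterize(rows, cols, (h, w))
            if not blob.any():
                continue
            if blob[~tissue].any() or (blob & occupied).any():
                continue
            blobs.append(blob)
            occupied |= blob
            geoms.append((rows, cols, cr, cc))
            placed = True
            break
        if not placed:
            raise ValueError(
                "degenerate spec: could not fit an invasive blob of radius "
                f"~{base_radius:.0f}px inside the tissue region"
            )
    return blobs, geoms


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorised splitmix64 finaliser; uint64 in, uint64 out."""
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x = (x * np.uint64(0xBF58476D1CE4E5B9)).astype(np.uint64)
    x ^= x >> np.uint64(27)
    x = (x * np.uint64(0x94D049BB133111EB)).astype(np.uint64)
    x ^= x >> np.uint64(31)
    return x


class NoisyOracleClassifier:
    """Tile classifier that reads the ground-truth mask.

    The probability for a tile is the fraction of mask-positive pixels under
    its footprint, computed from an integral image. With probability
    ``label_noise`` the value is flipped to ``1 - fraction``; the flip
    decision is a deterministic counter-hash of ``(flip_seed, row, col)``,
    so predictions depend only on the seed and the tile coordinates.

    Stands in for a trained tile model wherever ground truth is known,
    letting sampling strategies be compared without any training step.
    """

    def __init__(self, slide: Slide, label_noise: float = 0.0, flip_seed: int = 0):
        if slide.mask is None:
            raise ValueError("noisy oracle requires a slide with a ground-truth mask")
        if not (0.0 <= label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        self.label_noise = float(label_noise)
        self.flip_seed = int(flip_seed)
        self._shape = slide.shape
        m = slide.mask.astype(np.float64)
        # integral image with a zero top row/left column
        self._integral = np.pad(m.cumsum(0).cumsum(1), ((1, 0), (1, 0)))

    def _fractions(self, centers: np.ndarray, size_k: int) -> np.ndarray:
        half = size_k // 2
        r0 = centers[:, 0] - half
        c0 = centers[:, 1] - half
        r1, c1 = r0 + size_k, c0 + size_k
        if (r0 < 0).any() or (c0 < 0).any() or (r1 > self._shape[0]).any() or (
            c1 > self._shape[1]
        ).any():
            raise ValueError("tile footprint falls outside the slide")
        s = self._integral
        total = s[r1, c1] - s[r0, c1] - s[r1, c0] + s[r0, c0]
        return total / float(size_k * size_k)

    def _flip_mask(self, centers: np.ndarray) -> np.ndarray:
        key = (
            centers[:, 0].astype(np.uint64) * np.uint64(0x100000000)
            + centers[:, 1].astype(np.uint64)
            + _splitmix64(np.full(len(centers), self.flip_seed, dtype=np.uint64))
        )
        u = _splitmix64(key).astype(np.float64) / float(2**64)
        return u < self.label_noise

    def predict_proba_at(
        self, slide: Slide, centers: Sequence[tuple[int, int]] | np.ndarray, size_k: int
    ) -> np.ndarray:
        centers = np.asarray(centers, dtype=np.int64).reshape(-1, 2)
        frac = self._fractions(centers, size_k)
        if self.label_noise > 0 and len(centers):
            flip = self._flip_mask(centers)
            frac = np.where(flip, 1.0 - frac, frac)
        return frac

    def predict_proba(self, tiles) -> np.ndarray:
        centers = np.array(
            [(t.center_row, t.center_col) for t in tiles], dtype=np.int64
        ).reshape(-1, 2)
        size_k = tiles[0].size_k if tiles else 101
        return self.predict_proba_at(None, centers, size_k)


def make_noisy_oracle(
    slide: Slide, label_noise: float = 0.0, flip_seed: int = 0
) -> NoisyOracleClassifier:
    """Build the ground-truth-reading test classifier for a synthetic slide."""
    return NoisyOracleClassifier(slide, label_noise=label_noise, flip_seed=flip_seed)


def save_slide(slide: Slide, spec: Optional[SyntheticSlideSpec], out_dir: str | Path) -> None:
    """Write slide.png (8-bit RGB), mask.png (0/255) and spec.json sidecar."""
    from . import io_utils

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_utils.write_image(slide, out / "slide.png")
    if slide.mask is not None:
        io_utils.write_mask(slide.mask, out / "mask.png")
    if spec is not None:
        (out / "spec.json").write_text(json.dumps(asdict(spec), indent=2))
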