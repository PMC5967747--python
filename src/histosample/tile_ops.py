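"""Tile extraction, the tissue filter, overlap labeling and preprocessing.

A tile is a k x k square patch (k odd, default 101) addressed by its centre
pixel in 0-based (row, col) coordinates; every sampling coordinate in this
package is a tile centre. Non-tissue patches — homogeneous near-white glass —
are detected by the grayscale sd/mean rule; tiles are labelled positive when
at least a configurable fraction of their area overlaps the annotated mask.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .synthetic_wsi import Slide

DEFAULT_TILE_SIZE = 101
DEFAULT_SD_THRESHOLD = 10.0
DEFAULT_MEAN_THRESHOLD = 240.0
DEFAULT_POSITIVE_FRACTION = 0.5

# BT.601 full-range RGB -> YUV (analog Y'UV form)
_YUV_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.14713, -0.28886, 0.436],
        [0.615, -0.51499, -0.10001],
    ]
)


@dataclass
class Tile:
    center_row: int
    center_col: int
    size_k: int
    pixels: np.ndarray  # k x k x 3, uint8

    def __post_init__(self) -> None:
        if self.size_k % 2 == 0:
            raise ValueError("tile size_k must be odd so the centre pixel is unique")
        if self.pixels.shape != (self.size_k, self.size_k, 3):
            raise ValueError("tile pixel block must be k x k x 3")


def extract_tile(slide: Slide, center_row: int, center_col: int,
                 size_k: int = DEFAULT_TILE_SIZE) -> Tile:
    """Cut the k x k x 3 sub-grid centred at (center_row, center_col).

    The centre must lie at least floor(k/2) pixels from every edge; an
    out-of-margin centre raises rather than silently padding.
    """
    if size_k % 2 == 0 or size_k < 1:
        raise ValueError("size_k must be a positive odd integer")
    h, w = slide.shape
    half = size_k // 2
    if not (half <= center_row <= h - 1 - half and half <= center_col <= w - 1 - half):
        raise ValueError(
            f"tile centre ({center_row}, {center_col}) with k={size_k} "
            f"overhangs the {h}x{w} slide"
        )
    block = slide.pixels[
        center_row - half : center_row + half + 1,
        center_col - half : center_col + half + 1,
    ]
    return Tile(center_row, center_col, size_k, block)


def grayscale(pixels: np.ndarray) -> np.ndarray:
    """Channel-mean grayscale used by the tissue filter."""
    return pixels.astype(np.float64).mean(axis=-1)


def is_tissue(
    tile: Tile,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD,
) -> bool:
    """False iff the tile looks like blank glass.

    A tile is non-tissue when its grayscale standard deviation is below
    ``sd_threshold`` (homogeneous) AND its grayscale mean is above
    ``mean_threshold`` (near white). Both comparisons are strict, so a tile
    sitting exactly at either threshold counts as tissue.
    """
    g = grayscale(tile.pixels)
    return not (g.std() < sd_threshold and g.mean() > mean_threshold)


def is_tissue_at(
    slide: Slide,
    centers: np.ndarray,
    size_k: int = DEFAULT_TILE_SIZE,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD,
) -> np.ndarray:
    """Vectorised ``is_tissue`` for a batch of tile centres.

    Uses integral images of the grayscale slide and its square, so the cost
    is independent of the tile size; agrees with the per-tile rule.
    """
    centers = np.asarray(centers, dtype=np.int64).reshape(-1, 2)
    g = grayscale(slide.pixels)
    s1 = np.pad(g.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    s2 = np.pad((g * g).cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    half = size_k // 2
    r0, c0 = centers[:, 0] - half, centers[:, 1] - half
    r1, c1 = r0 + size_k, c0 + size_k
    area = float(size_k * size_k)
    tot = s1[r1, c1] - s1[r0, c1] - s1[r1, c0] + s1[r0, c0]
    tot2 = s2[r1, c1] - s2[r0, c1] - s2[r1, c0] + s2[r0, c0]
    mean = tot / area
    var = np.maximum(tot2 / area - mean * mean, 0.0)
    sd = np.sqrt(var)
    return ~((sd < sd_threshold) & (mean > mean_threshold))


def label_tile(
    tile: Tile,
    mask: np.ndarray,
    positive_fraction_threshold: float = DEFAULT_POSITIVE_FRACTION,
) -> int:
    """1 (positive) iff the masked fraction of the tile's area reaches the
    threshold; the comparison is >= so a tile exactly at the threshold is
    positive."""
    half = tile.size_k // 2
    window = mask[
        tile.center_row - half : tile.center_row + half + 1,
        tile.center_col - half : tile.center_col + half + 1,
    ]
    frac = float(window.sum()) / float(tile.size_k * tile.size_k)
    return int(frac >= positive_fraction_threshold)


def preprocess_tile(tile: Tile) -> np.ndarray:
    """RGB -> YUV (BT.601 full range), then per-channel standardisation.

    Each output channel has mean 0 and variance 1 over the tile's pixels;
    a constant (zero-variance) channel maps to all zeros. Decorrelating
    luma from chroma and removing per-tile intensity scale makes tiles
    comparable across staining variation.
    """
    rgb = tile.pixels.astype(np.float64)
    yuv = np.einsum("ij,rcj->rci", _YUV_MATRIX, rgb)
    out = np.empty_like(yuv)
    for ch in range(3):
        plane = yuv[..., ch]
        sd = plane.std()
        if sd < 1e-12:
            out[..., ch] = 0.0
        else:
            out[..., ch] = (plane - plane.mean()) / sd
    return out


def rgb_to_yuv(rgb: np.ndarray) -> np.ndarray:
    """Apply the BT.601 full-range YUV transform to an (..., 3) RGB array."""
    return np.einsum("ij,...j->...i", _YUV_MATRIX, rgb.astype(np.float64))


@dataclass
class LabeledTileSet:
    """Tiles plus binary labels; every tile has passed the tissue filter."""

    tiles: list[Tile]
    labels: np.ndarray  # int {0, 1}
    positive_fraction_threshold: float = DEFAULT_POSITIVE_FRACTION

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.tiles) != len(self.labels):
            raise ValueError("tiles and labels must have equal length")

    def __len__(self) -> int:
        return len(self.tiles)

    def save(self, out_dir: str | Path) -> None:
        """Directory of PNG tiles plus a CSV manifest; bit-exact round trip."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (tile, label) in enumerate(zip(self.tiles, self.labels)):
            name = f"tile_{i:06d}.png"
            Image.fromarray(tile.pixels).save(out / name)
            rows.append((name, tile.center_row, tile.center_col, tile.size_k, int(label)))
        with open(out / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["filename", "center_row", "center_col", "size_k", "label"]
            )
            writer.writerows(rows)
            fh.write(f"# positive_fraction_threshold={self.positive_fraction_threshold}\n")

    @classmethod
    def load(cls, in_dir: str | Path) -> "LabeledTileSet":
        src = Path(in_dir)
        tiles, labels = [], []
        threshold = DEFAULT_POSITIVE_FRACTION
        with open(src / "manifest.csv", newline="") as fh:
            lines = [ln for ln in fh if ln.strip()]
        for ln in lines:
            if ln.startswith("#"):
                threshold = float(ln.split("=", 1)[1])
        reader = csv.DictReader(ln for ln in lines if not ln.startswith("#"))
        for rec in reader:
            px = np.asarray(Image.open(src / rec["filename"]).convert("RGB"))
            tiles.append(
                Tile(int(rec["center_row"]), int(rec["center_col"]),
                     int(rec["size_k"]), px)
            )
            labels.append(int(rec["label"]))
        return cls(tiles, np.array(labels), threshold)


def build_training_set(
    slide: Slide,
    mask: Optional[np.ndarray] = None,
    stride: int = DEFAULT_TILE_SIZE,
    size_k: int = DEFAULT_TILE_SIZE,
    positive_fraction_threshold: float = DEFAULT_POSITIVE_FRACTION,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    mean_threshold: float = DEFAULT_MEAN_THRESHOLD,
) -> LabeledTileSet:
    """Regular-grid tiles, tissue-filtered and overlap-labelled.

    ``mask`` defaults to the slide's own ground-truth mask. Raises if the
    grid yields no tissue tile (e.g. an entirely blank slide).
    """
    from . import samplers  # local import to avoid a cycle at module load

    if stride < 1:
        raise ValueError("stride must be >= 1")
    if mask is None:
        mask = slide.mask
    if mask is None:
        raise ValueError("labeling requires a mask (none on slide, none given)")
    domain = samplers.valid_center_domain(slide.shape, size_k)
    centers = samplers.regular_grid(domain, stride)
    tiles, labels = [], []
    for r, c in centers:
        tile = extract_tile(slide, int(r), int(c), size_k)
        if not is_tissue(tile, sd_threshold, mean_threshold):
            continue
        tiles.append(tile)
        labels.append(label_tile(tile, mask, positive_fraction_threshold))
    if not tiles:
        raise ValueError("no tissue tiles found on the slide at this grid")
    return LabeledTileSet(tiles, np.array(labels), positive_fraction_threshold)
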