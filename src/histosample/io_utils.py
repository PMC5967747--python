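"""Raster readers/writers and run configuration.

The working images are plain 8-bit RGB PNG or TIFF (the pipeline operates
on heavily downsampled slides, so no pyramid/scanner formats are needed);
masks are single-channel 0/255 images binarised at 128 on read. Probability
maps are written both as 32-bit float TIFF (exact) and as an 8-bit heatmap
PNG (value x 255, for eyeballing).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml
from PIL import Image

from .adaptive import AdaptiveConfig
from .probability_map import ProbabilityMap, TileSampleSet
from .samplers import SamplerConfig
from .synthetic_wsi import Slide, SyntheticSlideSpec

logger = logging.getLogger(__name__)


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(str(path))
    with Image.open(path) as img:
        if img.mode in ("I", "I;16", "I;16B", "F"):
            raise ValueError(
                f"{path}: unsupported bit depth (mode {img.mode}); "
                "8-bit images required"
            )
        return np.asarray(img)


def read_image(path: str | Path) -> Slide:
    """Read an 8-bit RGB PNG/TIFF as a Slide (no mask attached)."""
    path = Path(path)
    arr = _load_array(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported bit depth {arr.dtype}; need uint8")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return Slide(pixels=np.ascontiguousarray(arr[..., :3]))


def write_image(slide: Slide, path: str | Path) -> None:
    """Lossless write of the slide pixels as PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), slide.pixels)
    else:
        Image.fromarray(slide.pixels).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask, binarising at 128.

    Logs a warning if the file holds values other than {0, 255}.
    """
    path = Path(path)
    arr = _load_array(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported mask bit depth {arr.dtype}")
    if arr.ndim == 3:
        arr = arr[..., 0]
    vals = np.unique(arr)
    if not np.isin(vals, [0, 255]).all():
        logger.warning("%s: non-binary mask values found; binarising at 128", path)
    return (arr >= 128).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a 0/1 mask as a 0/255 single-channel image."""
    out = (np.asarray(mask) > 0).astype(np.uint8) * 255
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), out)
    else:
        Image.fromarray(out).save(path)


def write_probability_map(P: ProbabilityMap, out_dir: str | Path, stem: str = "map") -> None:
    """Float TIFF (exact values) plus an 8-bit heatmap PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(out / f"{stem}.tif"), P.values.astype(np.float32))
    heat = np.clip(np.rint(P.values * 255), 0, 255).astype(np.uint8)
    Image.fromarray(heat).save(out / f"{stem}_heatmap.png")


def read_probability_map(path: str | Path) -> ProbabilityMap:
    arr = tifffile.imread(str(path))
    return ProbabilityMap(arr.astype(np.float64))


def write_samples_csv(samples: TileSampleSet, path: str | Path) -> None:
    """Sample log: iteration, center_row, center_col, probability."""
    with open(path, "w") as fh:
        fh.write("iteration,center_row,center_col,probability\n")
        for (r, c), p, it in zip(
            samples.centers, samples.probabilities, samples.iteration_of
        ):
            fh.write(f"{it},{r},{c},{float(p)!r}\n")


def read_samples_csv(path: str | Path) -> TileSampleSet:
    its, rows, cols, probs = [], [], [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            it, r, c, p = line.strip().split(",")
            its.append(int(it)); rows.append(int(r)); cols.append(int(c))
            probs.append(float(p))
    return TileSampleSet(
        np.column_stack([rows, cols]) if rows else np.empty((0, 2), np.int64),
        np.array(probs),
        np.array(its, dtype=np.int64),
    )


@dataclass
class RunConfig:
    """Aggregate configuration for a reproducible end-to-end run.

    Every random operation derives its stream from ``seed`` plus a fixed
    per-component offset: slide generation uses ``seed``, oracle label
    flips ``seed + 1``, classifier training ``seed + 2``, the adaptive
    loop ``seed + 3``.
    """

    seed: int = 0
    output_dir: str = "runs/out"
    slide_spec: SyntheticSlideSpec = field(default_factory=SyntheticSlideSpec)
    adaptive: AdaptiveConfig = field(default_factory=AdaptiveConfig)
    sd_threshold: float = 10.0
    mean_threshold: float = 240.0
    positive_fraction_threshold: float = 0.5
    training_stride: int = 101
    feature_kind: str = "CF"
    lambda_reg: float = 1e-4
    learning_rate: float = 0.01
    epochs: int = 50
    minibatch_size: int = 32
    eval_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))

    SEED_OFFSETS = {"slide": 0, "oracle": 1, "training": 2, "loop": 3}

    def component_seed(self, component: str) -> int:
        return self.seed + self.SEED_OFFSETS[component]

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        spec = d.pop("slide_spec", {})
        if isinstance(spec, dict):
            for key in ("benign_color_mean", "invasive_color_mean"):
                if key in spec:
                    spec[key] = tuple(spec[key])
            spec = SyntheticSlideSpec(**spec)
        ad = d.pop("adaptive", {})
        if isinstance(ad, dict):
            sampler = ad.pop("sampler", {})
            if isinstance(sampler, dict):
                sampler = SamplerConfig(**sampler)
            if ad.get("dice_iterations") is not None:
                ad["dice_iterations"] = tuple(ad["dice_iterations"])
            ad = AdaptiveConfig(sampler=sampler, **ad)
        if "eval_thresholds" in d:
            d["eval_thresholds"] = tuple(d["eval_thresholds"])
        return cls(slide_spec=spec, adaptive=ad, **d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
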