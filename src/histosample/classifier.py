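"""Tile classifiers: the contract, hand-crafted features and a softmax model.

The adaptive loop is classifier-agnostic — anything exposing
``predict_proba`` over tiles can drive it. Shipped here are two concrete
feature extractors (colour/intensity first-order statistics, CF, 56-d; and
per-channel 8-bin colour histograms, CH, 24-d) feeding a two-class softmax
(multinomial logistic) model with L2 weight decay, trained by minibatch
stochastic gradient descent:

    L(W) = -(1/m) sum_i sum_c 1{y_i = c} log softmax_c(W s_i)
           + (lambda/2) ||W||_F^2

Convolutional backends are deliberately out of scope; they plug in through
the same contract.
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import kurtosis, skew
from skimage import color as skcolor

from . import tile_ops
from .synthetic_wsi import Slide
from .tile_ops import Tile

#: the 14 colour channels behind the CF extractor, in output order
CF_CHANNELS = (
    "R", "G", "B",
    "H", "S", "V",
    "L*", "a*", "b*",
    "Y", "Cb", "Cr",
    "gray", "od",
)
#: the 4 first-order statistics per channel, in output order
CF_STATISTICS = ("mean", "sd", "skewness", "kurtosis")

CF_LENGTH = len(CF_CHANNELS) * len(CF_STATISTICS)  # 56
CH_BINS = 8
CH_LENGTH = CH_BINS * 3  # 24


class TileClassifier(abc.ABC):
    """Anything that maps tiles to invasive-class probabilities in [0, 1]."""

    @abc.abstractmethod
    def predict_proba(self, tiles: Sequence[Tile]) -> np.ndarray:
        """Probability of the invasive class for each tile."""

    def predict_proba_at(
        self, slide: Slide, centers: np.ndarray, size_k: int
    ) -> np.ndarray:
        """Batch prediction at tile centres; default extracts the tiles.

        Subclasses that can predict from coordinates alone (e.g. the
        ground-truth oracle) override this with a vectorised fast path.
        """
        centers = np.asarray(centers, dtype=np.int64).reshape(-1, 2)
        tiles = [
            tile_ops.extract_tile(slide, int(r), int(c), size_k)
            for r, c in centers
        ]
        return self.predict_proba(tiles)


@dataclass
class TrainingBatch:
    features: np.ndarray  # m x n
    labels: np.ndarray  # m, values in {0, 1}

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty m x n matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must align with feature rows")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary {0, 1}")
        if not np.isfinite(self.features).all():
            raise ValueError("non-finite feature values")


@dataclass
class ClassifierModel:
    """Softmax weights plus the preprocessing frozen at training time.

    ``weights`` is C x n with C = 2 (row 0: non-invasive, row 1: invasive).
    ``feature_mean``/``feature_scale`` standardise inputs exactly as during
    training; hand-crafted statistics span several orders of magnitude and
    SGD is only stable on the standardised design.
    """

    weights: np.ndarray  # 2 x n
    lambda_reg: float = 0.0
    feature_kind: str = "external"  # CF | CH | concatenated | external
    training_log: list[float] = field(default_factory=list)
    feature_mean: Optional[np.ndarray] = None
    feature_scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2 or self.weights.shape[0] != 2:
            raise ValueError("weights must be a 2 x n matrix")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def standardize(self, features: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return features
        return (features - self.feature_mean) / self.feature_scale

    # -- serialisation (round-trip exact) ---------------------------------
    def to_json(self) -> str:
        payload = {
            "format_version": 1,
            "weights": self.weights.tolist(),
            "lambda_reg": self.lambda_reg,
            "feature_kind": self.feature_kind,
            "training_log": list(self.training_log),
            "feature_mean": None if self.feature_mean is None else self.feature_mean.tolist(),
            "feature_scale": None if self.feature_scale is None else self.feature_scale.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            weights=np.array(d["weights"], dtype=np.float64),
            lambda_reg=d["lambda_reg"],
            feature_kind=d["feature_kind"],
            training_log=list(d["training_log"]),
            feature_mean=None if d["feature_mean"] is None else np.array(d["feature_mean"]),
            feature_scale=None if d["feature_scale"] is None else np.array(d["feature_scale"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return cls.from_json(Path(path).read_text())


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def softmax_loss(model: ClassifierModel, batch: TrainingBatch) -> float:
    """Average negative log-likelihood of the softmax model plus the L2 term
    (lambda/2)||W||_F^2, with the max-subtraction guard."""
    s = batch.features
    if s.shape[1] != model.n_features:
        raise ValueError("feature dimensionality does not match the model")
    logp = _log_softmax(s @ model.weights.T)  # m x 2
    nll = -logp[np.arange(len(batch.labels)), batch.labels].mean()
    return float(nll + 0.5 * model.lambda_reg * (model.weights ** 2).sum())


def softmax_loss_gradient(model: ClassifierModel, batch: TrainingBatch) -> np.ndarray:
    """Analytic d loss / d W, a 2 x n matrix."""
    s = batch.features
    m = s.shape[0]
    p = np.exp(_log_softmax(s @ model.weights.T))  # m x 2
    onehot = np.zeros_like(p)
    onehot[np.arange(m), batch.labels] = 1.0
    return (p - onehot).T @ s / m + model.lambda_reg * model.weights


def train_sgd(
    batch: TrainingBatch,
    lambda_reg: float = 1e-4,
    learning_rate: float = 0.01,
    epochs: int = 50,
    minibatch_size: int = 32,
    seed: int = 0,
    feature_kind: str = "external",
    standardize: bool = True,
) -> ClassifierModel:
    """Minibatch SGD on the softmax loss from a zero initialisation.

    Shuffling is driven by ``seed`` so training is deterministic. The
    per-epoch full-batch loss is recorded in ``model.training_log``.
    Raises if the batch contains a single class only.
    """
    classes = np.unique(batch.labels)
    if len(classes) < 2:
        raise ValueError("training requires at least one example of each class")
    rng = np.random.default_rng(seed)
    features = batch.features
    mean = scale = None
    if standardize:
        mean = features.mean(axis=0)
        scale = features.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        features = (features - mean) / scale
    work = TrainingBatch(features, batch.labels)
    m, n = features.shape
    model = ClassifierModel(
        weights=np.zeros((2, n)),
        lambda_reg=lambda_reg,
        feature_kind=feature_kind,
        feature_mean=mean,
        feature_scale=scale,
    )
    for _ in range(epochs):
        order = rng.permutation(m)
        for start in range(0, m, minibatch_size):
            idx = order[start : start + minibatch_size]
            mini = TrainingBatch(features[idx], batch.labels[idx])
            model.weights -= learning_rate * softmax_loss_gradient(model, mini)
        model.training_log.append(softmax_loss(model, work))
    return model


# -- hand-crafted feature extractors --------------------------------------

def _cf_channels(rgb: np.ndarray) -> np.ndarray:
    """Stack the 14 CF colour channels of a k x k x 3 uint8 tile."""
    rgb01 = rgb.astype(np.float64) / 255.0
    hsv = skcolor.rgb2hsv(rgb01)
    lab = skcolor.rgb2lab(rgb01)
    ycbcr = skcolor.rgb2ycbcr(rgb)
    gray = rgb.astype(np.float64).mean(axis=-1)
    od = -np.log((gray + 1.0) / 256.0)  # optical-density-like channel
    planes = [rgb[..., i].astype(np.float64) for i in range(3)]
    planes += [hsv[..., i] for i in range(3)]
    planes += [lab[..., i] for i in range(3)]
    planes += [ycbcr[..., i] for i in range(3)]
    planes += [gray, od]
    return np.stack(planes)


def extract_cf_features(tile: Tile) -> np.ndarray:
    """Colour/intensity first-order statistics: 14 channels x 4 stats = 56.

    Per channel: mean, standard deviation, skewness, excess kurtosis, in
    that order, channel-major. Zero-variance channels report 0 for skewness
    and kurtosis.
    """
    out = np.empty(CF_LENGTH)
    for i, plane in enumerate(_cf_channels(tile.pixels)):
        flat = plane.ravel()
        mean = flat.mean()
        sd = flat.std()
        if sd < 1e-9 * (1.0 + abs(mean)):
            sd = 0.0  # constant channel up to colour-conversion round-off
        out[4 * i] = mean
        out[4 * i + 1] = sd
        if sd == 0.0:
            out[4 * i + 2] = 0.0
            out[4 * i + 3] = 0.0
        else:
            out[4 * i + 2] = skew(flat)
            out[4 * i + 3] = kurtosis(flat)
    return out


def extract_ch_features(tile: Tile) -> np.ndarray:
    """Colour histograms: 8 equal-width bins on [0, 255] per RGB channel,
    each normalised to sum 1, concatenated R, G, B (24 values)."""
    k2 = tile.size_k * tile.size_k
    parts = []
    for ch in range(3):
        counts, _ = np.histogram(tile.pixels[..., ch], bins=CH_BINS, range=(0, 256))
        parts.append(counts / k2)
    return np.concatenate(parts)


FEATURE_EXTRACTORS: dict[str, Callable[[Tile], np.ndarray]] = {
    "CF": extract_cf_features,
    "CH": extract_ch_features,
}
FEATURE_LENGTHS = {"CF": CF_LENGTH, "CH": CH_LENGTH, "concatenated": CF_LENGTH + CH_LENGTH}


def extract_concatenated_features(tile: Tile) -> np.ndarray:
    return np.concatenate([extract_cf_features(tile), extract_ch_features(tile)])


FEATURE_EXTRACTORS["concatenated"] = extract_concatenated_features


def build_training_batch(
    tile_set: tile_ops.LabeledTileSet, feature_kind: str = "CF"
) -> TrainingBatch:
    extractor = FEATURE_EXTRACTORS[feature_kind]
    features = np.stack([extractor(t) for t in tile_set.tiles])
    return TrainingBatch(features, tile_set.labels)


class FeatureTileClassifier(TileClassifier):
    """Softmax model over a named hand-crafted feature extractor."""

    def __init__(self, model: ClassifierModel, extractor: Callable[[Tile], np.ndarray]):
        self.model = model
        self.extractor = extractor

    def predict_proba(self, tiles: Sequence[Tile]) -> np.ndarray:
        if not len(tiles):
            return np.empty(0)
        features = np.stack([self.extractor(t) for t in tiles])
        if features.shape[1] != self.model.n_features:
            raise ValueError(
                f"extractor emits {features.shape[1]}-d features but the "
                f"model expects {self.model.n_features}-d"
            )
        z = self.model.standardize(features)
        logp = _log_softmax(z @ self.model.weights.T)
        return np.exp(logp[:, 1])


def feature_classifier(
    model: ClassifierModel,
    extractor: Optional[Callable[[Tile], np.ndarray]] = None,
) -> FeatureTileClassifier:
    """Wrap a trained model (+ its extractor) as a TileClassifier.

    The extractor defaults to the one named by ``model.feature_kind``; a
    dimensionality mismatch raises at prediction time.
    """
    if extractor is None:
        if model.feature_kind not in FEATURE_EXTRACTORS:
            raise ValueError(
                f"model feature_kind {model.feature_kind!r} has no built-in "
                "extractor; pass one explicitly"
            )
        extractor = FEATURE_EXTRACTORS[model.feature_kind]
    expected = FEATURE_LENGTHS.get(model.feature_kind)
    if expected is not None and expected != model.n_features:
        raise ValueError(
            f"model of kind {model.feature_kind!r} should have {expected} "
            f"features, found {model.n_features}"
        )
    return FeatureTileClassifier(model, extractor)
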