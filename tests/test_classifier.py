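"""Softmax model, SGD training and hand-crafted feature extractors."""

import numpy as np
import pytest

from histosample import classifier as clf
from histosample import evaluation, synthetic_wsi, tile_ops
from histosample.classifier import (
    ClassifierModel,
    TrainingBatch,
    extract_cf_features,
    extract_ch_features,
    feature_classifier,
    softmax_loss,
    softmax_loss_gradient,
    train_sgd,
)
from histosample.tile_ops import Tile

from conftest import SMALL, SMALL_TILE


def _tile_from(arr):
    arr = np.asarray(arr, dtype=np.uint8)
    k = arr.shape[0]
    return Tile(k // 2, k // 2, k, arr)


def _toy_batch(rng, m=40, separated=True):
    x0 = rng.normal([-2, 0], 0.5, (m // 2, 2))
    x1 = rng.normal([2, 0], 0.5, (m - m // 2, 2))
    features = np.vstack([x0, x1])
    labels = np.array([0] * (m // 2) + [1] * (m - m // 2))
    return TrainingBatch(features, labels)


class TestSoftmaxLoss:
    def test_zero_weights_give_ln2(self, rng):
        batch = _toy_batch(rng)
        model = ClassifierModel(weights=np.zeros((2, 2)))
        assert softmax_loss(model, batch) == pytest.approx(np.log(2), rel=1e-12)

    def test_single_example_matches_hand_softmax(self):
        # W rows w0=(1,-1), w1=(0.5,2); s=(2,1); y=1
        W = np.array([[1.0, -1.0], [0.5, 2.0]])
        s = np.array([[2.0, 1.0]])
        z = W @ s[0]  # logits (1.0, 3.0)
        p1 = np.exp(z[1]) / np.exp(z).sum()
        lam = 0.3
        expected = -np.log(p1) + 0.5 * lam * (W ** 2).sum()
        model = ClassifierModel(weights=W, lambda_reg=lam)
        got = softmax_loss(model, TrainingBatch(s, np.array([1])))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        batch = _toy_batch(rng, m=30)
        W = rng.normal(size=(2, 2))
        model = ClassifierModel(weights=W.copy(), lambda_reg=0.1)
        analytic = softmax_loss_gradient(model, batch)
        eps = 1e-6
        for i in range(2):
            for j in range(2):
                w_hi, w_lo = W.copy(), W.copy()
                w_hi[i, j] += eps
                w_lo[i, j] -= eps
                num = (
                    softmax_loss(ClassifierModel(w_hi, 0.1), batch)
                    - softmax_loss(ClassifierModel(w_lo, 0.1), batch)
                ) / (2 * eps)
                rel = abs(analytic[i, j] - num) / max(abs(num), 1e-8)
                assert rel < 1e-5

    def test_convex_in_weights(self, rng):
        batch = _toy_batch(rng)
        for _ in range(20):
            wa, wb = rng.normal(size=(2, 2, 2))
            mid = ClassifierModel((wa + wb) / 2, 0.05)
            la = softmax_loss(ClassifierModel(wa, 0.05), batch)
            lb = softmax_loss(ClassifierModel(wb, 0.05), batch)
            assert softmax_loss(mid, batch) <= (la + lb) / 2 + 1e-12

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError):
            TrainingBatch(np.array([[np.inf, 0.0]]), np.array([1]))


class TestTrainSgd:
    def test_separable_data_reaches_perfect_accuracy(self, rng):
        batch = _toy_batch(rng, m=60)
        model = train_sgd(batch, lambda_reg=0.0, epochs=80, seed=1)
        z = model.standardize(batch.features) @ model.weights.T
        pred = z.argmax(axis=1)
        assert (pred == batch.labels).mean() == 1.0

    def test_loss_sequence_non_increasing_at_small_rate(self, rng):
        batch = _toy_batch(rng, m=60)
        model = train_sgd(batch, lambda_reg=0.0, learning_rate=0.005,
                          epochs=40, seed=0)
        log = np.array(model.training_log)
        assert len(log) == 40
        assert np.all(np.diff(log) <= 1e-10)

    def test_heavy_regularization_shrinks_weights(self, rng):
        batch = _toy_batch(rng)
        # rate must satisfy lr * lambda < 1 for the decay step to contract
        model = train_sgd(batch, lambda_reg=1e6, learning_rate=1e-7,
                          epochs=20, seed=0)
        assert np.linalg.norm(model.weights) < 1e-3
        probs = feature_classifier_probs(model, batch.features)
        assert np.allclose(probs, 0.5, atol=1e-3)

    def test_single_class_raises(self):
        batch = TrainingBatch(np.eye(3), np.array([1, 1, 1]))
        with pytest.raises(ValueError, match="each class"):
            train_sgd(batch)

    def test_deterministic_given_seed(self, rng):
        batch = _toy_batch(rng)
        a = train_sgd(batch, seed=5)
        b = train_sgd(batch, seed=5)
        assert np.array_equal(a.weights, b.weights)
        assert a.training_log == b.training_log


def feature_classifier_probs(model, features):
    z = model.standardize(features) @ model.weights.T
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / e.sum(axis=1)


class TestFeatureExtractors:
    def test_cf_length_is_56(self, rng):
        tile = _tile_from(rng.integers(0, 256, (21, 21, 3)))
        assert extract_cf_features(tile).shape == (56,)
        assert clf.CF_LENGTH == 14 * 4 == 56

    def test_cf_constant_tile_zero_variance_guard(self):
        feats = extract_cf_features(_tile_from(np.full((21, 21, 3), 120)))
        per_channel = feats.reshape(14, 4)
        assert np.all(per_channel[:, 1] == 0)  # sd
        assert np.all(per_channel[:, 2] == 0)  # skewness
        assert np.all(per_channel[:, 3] == 0)  # kurtosis

    def test_cf_red_mean_entry(self, rng):
        arr = rng.integers(0, 256, (21, 21, 3), dtype=np.uint8)
        feats = extract_cf_features(_tile_from(arr))
        assert feats[0] == pytest.approx(arr[..., 0].mean())

    def test_ch_length_and_black_tile(self):
        feats = extract_ch_features(_tile_from(np.zeros((21, 21, 3))))
        assert feats.shape == (24,)
        for ch in range(3):
            hist = feats[8 * ch : 8 * ch + 8]
            assert hist[0] == 1.0 and np.all(hist[1:] == 0)

    def test_ch_two_value_histogram(self):
        arr = np.zeros((20, 20, 3), dtype=np.uint8)  # even count is fine here
        arr = np.full((21, 21, 3), 10, dtype=np.uint8)
        flat = arr.reshape(-1, 3)
        flat[: flat.shape[0] // 2, 1] = 250  # half of green channel high
        tile = _tile_from(flat.reshape(21, 21, 3))
        feats = extract_ch_features(tile)
        green = feats[8:16]
        n = 21 * 21
        assert green[7] == pytest.approx((n // 2) / n)
        assert green[0] == pytest.approx((n - n // 2) / n)
        assert np.all(green[1:7] == 0)

    def test_extractors_permutation_invariant(self, rng):
        arr = rng.integers(0, 256, (9, 9, 3), dtype=np.uint8)
        perm = rng.permutation(81)
        shuffled = arr.reshape(81, 3)[perm].reshape(9, 9, 3)
        assert np.allclose(
            extract_cf_features(_tile_from(arr)),
            extract_cf_features(_tile_from(shuffled)),
        )
        assert np.array_equal(
            extract_ch_features(_tile_from(arr)),
            extract_ch_features(_tile_from(shuffled)),
        )


class TestFeatureClassifier:
    def test_probabilities_in_unit_interval_and_row_swap_symmetry(self, rng):
        model = ClassifierModel(weights=rng.normal(size=(2, 56)),
                                feature_kind="CF")
        tiles = [_tile_from(rng.integers(0, 256, (21, 21, 3))) for _ in range(5)]
        p = feature_classifier(model).predict_proba(tiles)
        assert np.all((p >= 0) & (p <= 1))
        swapped = ClassifierModel(weights=model.weights[::-1].copy(),
                                  feature_kind="CF")
        q = feature_classifier(swapped).predict_proba(tiles)
        assert np.allclose(p + q, 1.0)

    def test_dimension_mismatch_raises(self, rng):
        model = ClassifierModel(weights=rng.normal(size=(2, 24)),
                                feature_kind="CH")
        with pytest.raises(ValueError, match="features"):
            feature_classifier(model, clf.extract_cf_features).predict_proba(
                [_tile_from(rng.integers(0, 256, (9, 9, 3)))]
            )
        with pytest.raises(ValueError, match="56"):
            feature_classifier(
                ClassifierModel(weights=np.zeros((2, 10)), feature_kind="CF")
            )

    def test_cf_model_separates_synthetic_tissue(self, small_slide):
        """Held-out AUC > 0.9 for CF features + softmax on fresh slides."""
        train_set = tile_ops.build_training_set(small_slide, stride=20, size_k=SMALL_TILE)
        batch = clf.build_training_batch(train_set, "CF")
        model = train_sgd(batch, lambda_reg=1e-4, epochs=40, seed=0,
                          feature_kind="CF")
        test_slide = synthetic_wsi.generate_slide(
            synthetic_wsi.SyntheticSlideSpec(seed=99, **SMALL)
        )
        test_set = tile_ops.build_training_set(test_slide, stride=20, size_k=SMALL_TILE)
        scores = feature_classifier(model).predict_proba(test_set.tiles)
        auc = evaluation.roc_auc(scores, test_set.labels)
        assert auc > 0.9
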