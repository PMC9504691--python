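import numpy as np
import pytest

from fcamseg import (
    SuperpixelPartition,
    build_palette,
    elm_predict,
    elm_train,
    load_model,
    mosaic3,
    patch_halfwidth,
    refine,
    sample_prototypes,
    save_model,
    segment,
)
from fcamseg.errors import InvalidParameterError, TrainingError
from fcamseg.segmenter import SegmentationResult, elm_raw_output


def separable_toy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal((0, 0), 0.3, size=(n // 2, 2))
    b = rng.normal((5, 5), 0.3, size=(n // 2, 2))
    X = np.vstack([a, b])
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


class TestPatchHalfwidth:
    @pytest.mark.parametrize(
        "N, P, W",
        [
            (512 * 512, 400, 13),  # 27x27 patch
            (100 * 100, 100, 5),  # area 100 -> side 11
            (10, 10, 0),  # area 1 -> side 1
            (81 * 4, 4, 4),  # exact odd square: side 9
        ],
    )
    def test_smallest_odd_side(self, N, P, W):
        assert patch_halfwidth(N, P) == W

    def test_invalid(self):
        with pytest.raises(InvalidParameterError):
            patch_halfwidth(10, 20)


class TestSamplePrototypes:
    def test_deterministic_given_seed(self):
        pal = build_palette((2, 2, 2), "gaussian")
        rng = np.random.default_rng(0)
        imgs = {
            "a": rng.integers(0, 256, (20, 20, 3), dtype=np.uint8),
            "b": rng.integers(0, 256, (20, 20, 3), dtype=np.uint8),
        }
        f1, l1 = sample_prototypes(imgs, T=5, W=3, palette=pal, seed=9)
        f2, l2 = sample_prototypes(imgs, T=5, W=3, palette=pal, seed=9)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(l1, l2)
        assert f1.shape == (10, 64)

    def test_constant_image_gives_identical_features(self):
        pal = build_palette((2, 2, 2), "gaussian")
        img = np.full((15, 15, 3), 77, dtype=np.uint8)
        feats, _ = sample_prototypes({"x": img, "y": img}, T=4, W=2, palette=pal)
        np.testing.assert_allclose(
            feats, np.broadcast_to(feats[0], feats.shape), atol=1e-12
        )

    def test_image_smaller_than_patch_rejected(self):
        pal = build_palette((2, 2, 2), "gaussian")
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        with pytest.raises(InvalidParameterError):
            sample_prototypes({"x": img}, T=1, W=3, palette=pal)


class TestELM:
    def test_perfect_training_accuracy_on_separable_toy(self):
        X, y = separable_toy()
        model = elm_train(X, y, seed=0)
        assert model.hidden_count == 200
        preds = elm_predict(model, X)
        assert np.mean(preds == y) == 1.0

    def test_output_weights_match_least_squares_oracle(self):
        # hidden=16 keeps the hidden-feature matrix well conditioned so
        # the minimum-norm solution is numerically well defined
        X, y = separable_toy(80, seed=3)
        model = elm_train(X, y, hidden=16, seed=1)
        z = X @ model.input_weights.T + model.biases
        hmat = 1.0 / (1.0 + np.exp(-z))
        targets = np.zeros((X.shape[0], 2))
        targets[np.arange(X.shape[0]), y] = 1.0
        oracle, *_ = np.linalg.lstsq(hmat, targets, rcond=None)
        np.testing.assert_allclose(model.output_weights, oracle, atol=1e-6)

    def test_bit_identical_given_seed(self):
        X, y = separable_toy(60)
        m1 = elm_train(X, y, seed=5)
        m2 = elm_train(X, y, seed=5)
        assert np.array_equal(m1.input_weights, m2.input_weights)
        assert np.array_equal(m1.output_weights, m2.output_weights)

    def test_batch_equals_per_item(self):
        X, y = separable_toy(40)
        model = elm_train(X, y, seed=2)
        batch = elm_predict(model, X[:7])
        singles = [elm_predict(model, x) for x in X[:7]]
        assert batch.tolist() == singles

    def test_prediction_invariant_to_output_rescaling(self):
        X, y = separable_toy(40)
        model = elm_train(X, y, seed=2)
        before = elm_predict(model, X)
        model.output_weights *= 3.5
        np.testing.assert_array_equal(elm_predict(model, X), before)

    def test_tie_breaks_to_lowest_class(self):
        X, y = separable_toy(40)
        model = elm_train(X, y, seed=2)
        model.output_weights[:, 1] = model.output_weights[:, 0]
        assert np.all(elm_predict(model, X) == 0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(TrainingError):
            elm_train(np.zeros((10, 4)), [0] * 5 + [1] * 5)
        X, y = separable_toy(20)
        with pytest.raises(TrainingError):
            elm_train(X, y, K=3)
        with pytest.raises(TrainingError):
            elm_train(X, np.zeros(20, dtype=int))

    def test_feature_length_mismatch(self):
        X, y = separable_toy(20)
        model = elm_train(X, y)
        with pytest.raises(InvalidParameterError):
            elm_predict(model, np.zeros(5))


class TestRefine:
    def _result(self, labels, classes):
        part = SuperpixelPartition(labels=labels, count=int(labels.max()))
        classes = np.asarray(classes)
        return (
            SegmentationResult(
                labels=classes[labels - 1],
                superpixel_classes=classes,
                partition=part,
            ),
            part,
        )

    def test_small_superpixel_inherits_largest_neighbor(self):
        labels = np.ones((20, 20), dtype=np.int64)
        labels[:, 10:] = 2
        labels[0, 0] = 3  # 1 site < 0.5% of 400
        res, part = self._result(labels, ["a", "b", "c"])
        out = refine(res, part)
        assert out.superpixel_classes[2] == "a"
        assert set(np.unique(out.labels)) == {"a", "b"}

    def test_no_change_when_all_large(self):
        labels = np.ones((10, 10), dtype=np.int64)
        labels[:, 5:] = 2
        res, part = self._result(labels, ["a", "b"])
        out = refine(res, part)
        np.testing.assert_array_equal(out.labels, res.labels)

    def test_threshold_arithmetic(self):
        # 100-site region in a 128x128 image: below 0.5% (81.92)? No —
        # 100 > 81.92 stays; a 50-site region is relabeled.
        labels = np.ones((128, 128), dtype=np.int64)
        labels[:10, :10] = 2  # 100 sites, above threshold
        labels[-5:, -10:] = 3  # 50 sites, below threshold
        res, part = self._result(labels, ["a", "b", "c"])
        out = refine(res, part)
        assert out.superpixel_classes[1] == "b"
        assert out.superpixel_classes[2] == "a"


@pytest.fixture(scope="module")
def small_setup():
    sample = mosaic3(96, seed=0)
    pal = build_palette((2, 2, 2), "gaussian")
    train = {i + 1: t for i, t in enumerate(sample.tiles)}
    feats, labs = sample_prototypes(train, T=10, W=4, palette=pal, seed=1)
    model = elm_train(feats, labs, seed=1)
    return sample, pal, model


class TestSegment:
    def test_every_site_gets_a_model_class(self, small_setup):
        sample, pal, model = small_setup
        res = segment(sample.image, model, pal, P=20)
        assert set(np.unique(res.labels)) <= set(model.classes)

    def test_labels_constant_per_superpixel_without_refinement(self, small_setup):
        sample, pal, model = small_setup
        res = segment(sample.image, model, pal, P=20, refine_flag=False)
        for lab in range(1, res.partition.count + 1):
            vals = np.unique(res.labels[res.partition.labels == lab])
            assert vals.size == 1

    def test_deterministic(self, small_setup):
        sample, pal, model = small_setup
        r1 = segment(sample.image, model, pal, P=20)
        r2 = segment(sample.image, model, pal, P=20)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_model_palette_mismatch_rejected(self, small_setup):
        sample, _, model = small_setup
        wrong = build_palette((2, 4, 2), "gaussian")
        with pytest.raises(InvalidParameterError):
            segment(sample.image, model, wrong)


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        X, y = separable_toy(60)
        model = elm_train(X, y, seed=4)
        pal = build_palette((2, 2, 2), "gaussian")
        save_model(model, pal, tmp_path / "model")
        loaded, pal2, manifest = load_model(tmp_path / "model")
        assert manifest["K"] == 2
        assert pal2.counts == pal.counts
        np.testing.assert_array_equal(
            elm_raw_output(loaded, X), elm_raw_output(model, X)
        )
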