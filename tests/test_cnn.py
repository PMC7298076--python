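"""Patch classifier: sampling, training, heat-map inference."""

import numpy as np
import pytest

import standcount as sc
from standcount.cnn import _CLASS_INDEX, PatchSample, UndersamplingError
from standcount.indices import LEAF, SOIL, WEED


def _synthetic_patch(cls, s, rng):
    """Well-separated three-class patches built from the color model."""
    img = np.full((s, s, 3), (140.0, 120.0, 90.0))
    if cls == LEAF:
        img[:] = (55.0, 135.0, 45.0)
    elif cls == WEED:
        r, c = np.ogrid[:s, :s]
        blob = (r - s // 2) ** 2 + (c - s // 2) ** 2 <= 9
        img[blob] = (85.0, 130.0, 35.0)
    img += rng.normal(0, 5, img.shape)
    return np.clip(img, 0, 255).astype(np.float32) / 255.0


def _make_samples(n_per_class, s, seed):
    rng = np.random.default_rng(seed)
    out = []
    for cls in (LEAF, WEED, SOIL):
        for i in range(n_per_class):
            out.append(
                PatchSample(pixels=_synthetic_patch(cls, s, rng), label=cls,
                            source=("synthetic", 0, 0))
            )
    return out


def _accuracy(model, samples):
    x = np.stack([p.pixels for p in samples])
    y = np.array([_CLASS_INDEX[p.label] for p in samples])
    return float((model.forward(x).argmax(1) == y).mean())


class TestCnnSpec:
    def test_architecture_sizes(self):
        spec = sc.CnnSpec(patch_size=24)
        assert (spec.conv1_out, spec.pool1_out, spec.conv2_out, spec.pool2_out) == (
            20, 10, 6, 3,
        )

    @pytest.mark.parametrize("bad", [8, 12, 18, 15])
    def test_invalid_patch_sizes_rejected(self, bad):
        with pytest.raises(ValueError):
            sc.CnnSpec(patch_size=bad)

    def test_default_hyperparameters(self):
        spec = sc.CnnSpec()
        assert spec.kernel == 5 and spec.feature_maps == 12
        assert spec.learning_rate == pytest.approx(0.0005)


class TestSamplePatches:
    def test_exact_class_histogram(self, train_scenes, train_maps):
        counts = {LEAF: 200, WEED: 100, SOIL: 100}
        samples = sc.sample_patches(train_scenes, train_maps, 16, counts, seed=0)
        assert len(samples) == 400
        hist = {c: sum(1 for p in samples if p.label == c) for c in counts}
        assert hist == counts
        for p in samples[:20]:
            assert p.pixels.shape == (16, 16, 3)
            assert 0.0 <= p.pixels.min() and p.pixels.max() <= 1.0

    def test_label_is_center_pixel_class(self, train_scenes, train_maps):
        samples = sc.sample_patches(
            train_scenes, train_maps, 16, {LEAF: 50, SOIL: 50}, seed=3
        )
        lookup = {s.plot_id: m.labels for s, m in zip(train_scenes, train_maps)}
        for p in samples:
            plot, r, c = p.source
            assert lookup[plot][r, c] == p.label

    def test_zero_counts_give_empty_list(self, train_scenes, train_maps):
        assert sc.sample_patches(
            train_scenes, train_maps, 16, {LEAF: 0, WEED: 0, SOIL: 0}, seed=0
        ) == []

    def test_undersampling_error_names_class(self, train_scenes, train_maps):
        with pytest.raises(UndersamplingError, match="weed"):
            sc.sample_patches(
                train_scenes, train_maps, 16, {WEED: 10**6}, seed=0
            )

    def test_deterministic_under_seed(self, train_scenes, train_maps):
        a = sc.sample_patches(train_scenes, train_maps, 16, {LEAF: 30}, seed=8)
        b = sc.sample_patches(train_scenes, train_maps, 16, {LEAF: 30}, seed=8)
        assert [p.source for p in a] == [p.source for p in b]


class TestTraining:
    def test_separable_classes_reach_high_holdout_accuracy(self):
        train = _make_samples(134, 16, seed=0)  # ~400 patches
        hold = _make_samples(40, 16, seed=1)
        spec = sc.CnnSpec(patch_size=16, epochs=10, optimizer="adam", seed=0)
        model = sc.train(spec, train)
        assert _accuracy(model, hold) >= 0.95

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(2)
        train = _make_samples(134, 16, seed=0)
        labels = [p.label for p in train]
        rng.shuffle(labels)
        train = [
            PatchSample(pixels=p.pixels, label=l, source=p.source)
            for p, l in zip(train, labels)
        ]
        hold = _make_samples(40, 16, seed=1)
        spec = sc.CnnSpec(patch_size=16, epochs=10, optimizer="adam", seed=0)
        model = sc.train(spec, train)
        # with labels shuffled, the classifier collapses to an arbitrary
        # class-to-class mapping: held-out accuracy is chance-level at best
        assert _accuracy(model, hold) <= 0.6

    def test_same_seed_reproduces_loss_trajectory(self):
        train = _make_samples(40, 16, seed=0)
        spec = sc.CnnSpec(patch_size=16, epochs=3, seed=4)
        h1 = sc.train(spec, train).history
        h2 = sc.train(spec, train).history
        assert [e["loss"] for e in h1] == [e["loss"] for e in h2]

    def test_single_class_sample_set_rejected(self):
        train = [p for p in _make_samples(20, 16, seed=0) if p.label == LEAF]
        with pytest.raises(ValueError):
            sc.train(sc.CnnSpec(patch_size=16, epochs=1), train)

    def test_probabilities_sum_to_one(self, trained_model):
        x = np.stack([p.pixels for p in _make_samples(5, 16, seed=3)])
        probs = trained_model.forward(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()


class TestHeatMap:
    def test_shape_contract_and_range(self, trained_model, test_scene):
        s = trained_model.spec.patch_size
        heat = sc.heat_map(trained_model, test_scene)
        h, w = test_scene.shape
        assert heat.values.shape == (h - s + 1, w - s + 1)
        assert heat.offset == (s // 2, s // 2)
        assert heat.values.min() >= 0.0 and heat.values.max() <= 1.0

    def test_dense_equals_sliding_window(self, trained_model, test_scene):
        s = trained_model.spec.patch_size
        crop = test_scene.image[:64, :64]
        heat = sc.heat_map(trained_model, crop)
        n = 64 - s + 1
        patches = np.stack(
            [
                crop[i : i + s, j : j + s].astype(np.float32) / 255.0
                for i in range(n)
                for j in range(n)
            ]
        )
        direct = trained_model.forward(patches)[:, _CLASS_INDEX[LEAF]].reshape(n, n)
        assert np.abs(direct - heat.values).max() <= 1e-5

    def test_all_soil_image_scores_low(self, trained_model):
        rng = np.random.default_rng(0)
        img = np.clip(
            np.full((48, 48, 3), (140.0, 120.0, 90.0)) + rng.normal(0, 5, (48, 48, 3)),
            0, 255,
        ).astype(np.uint8)
        heat = sc.heat_map(trained_model, img)
        assert heat.values.max() <= 0.5

    def test_tiled_leaf_texture_scores_high(self, trained_model):
        rng = np.random.default_rng(1)
        img = np.clip(
            np.full((48, 48, 3), (55.0, 135.0, 45.0)) + rng.normal(0, 5, (48, 48, 3)),
            0, 255,
        ).astype(np.uint8)
        heat = sc.heat_map(trained_model, img)
        assert np.median(heat.values) >= 0.5

    def test_image_smaller_than_patch_rejected(self, trained_model):
        with pytest.raises(ValueError):
            sc.heat_map(trained_model, np.zeros((8, 8, 3), dtype=np.uint8))


def test_model_save_load_roundtrip(tmp_path, trained_model, test_scene):
    path = tmp_path / "model.npz"
    trained_model.save(path)
    back = sc.PatchCNN.load(path)
    crop = test_scene.image[:32, :32]
    np.testing.assert_array_equal(
        sc.heat_map(trained_model, crop).values, sc.heat_map(back, crop).values
    )
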