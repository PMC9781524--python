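"""1D-CNN architecture contract, training behavior, determinism."""

import numpy as np
import pytest

from oxyradiomics.cnn import (CNN1D, CNNSpec, TrainingConfig, infer_shapes,
                              predict, train)


def _separable(n=40, length=74, gap=2.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(-gap / 2, 1.0, (n // 2, length)),
                   rng.normal(gap / 2, 1.0, (n // 2, length))])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    return x, y


class TestShapeContract:
    def test_input_74_flattens_to_296(self):
        shapes = dict((name, (l, c)) for name, l, c in infer_shapes(CNNSpec(74)))
        assert shapes["pool3(s2)"] == (37, 8)
        assert shapes["flatten"] == (296, 1)
        assert shapes["dense1"] == (296, 1)
        assert shapes["dense2(sigmoid)"] == (1, 1)

    def test_input_296_flattens_to_1184(self):
        shapes = dict((name, (l, c)) for name, l, c in infer_shapes(CNNSpec(296)))
        assert shapes["pool3(s2)"] == (148, 8)
        assert shapes["flatten"] == (1184, 1)

    def test_stride_one_layers_preserve_length(self):
        for length in (10, 74, 296, 57):
            shapes = infer_shapes(CNNSpec(length))
            for name, l, _ in shapes:
                if name.startswith(("conv", "pool1", "pool2")):
                    assert l == length

    def test_forward_shapes_match_contract(self):
        """The actual forward pass realizes the declared layer sizes."""
        model = CNN1D(CNNSpec(74), seed=0)
        h = model._check_input(np.zeros((3, 74)))
        for layer in model.layers:
            h = layer.forward(h, training=False)
        assert h.shape == (3, 1)
        # flatten input recorded by the Flatten layer
        assert model.layers[8]._shape == (3, 8, 37)

    def test_nonpositive_input_length_rejected(self):
        with pytest.raises(ValueError):
            CNNSpec(0)

    def test_batch_size_derivation(self):
        assert TrainingConfig().batch_size(134) == 27
        assert TrainingConfig().batch_size(40) == 8


class TestTraining:
    def test_initial_loss_near_analytic_random_guess(self):
        """At near-zero output init the first-batch BCE is ~ln 2 = 0.693."""
        x, y = _separable()
        _, hist = train(x, y, CNNSpec(74), TrainingConfig(max_epochs=1, seed=1))
        assert hist["loss"].iloc[0] == pytest.approx(np.log(2.0), abs=0.05)

    def test_loss_decreases_after_one_epoch(self):
        x, y = _separable()
        _, hist = train(x, y, CNNSpec(74), TrainingConfig(max_epochs=2, seed=1))
        first_epoch = hist[hist["epoch"] == 0]["loss"].iloc[0]
        second_epoch = hist[hist["epoch"] == 1]["loss"].iloc[0]
        assert second_epoch < first_epoch

    def test_overfits_separable_fixture(self):
        x, y = _separable()
        model, hist = train(x, y, CNNSpec(74),
                            TrainingConfig(max_epochs=60, seed=3))
        p = model.predict_proba(x)
        assert np.mean((p > 0.5) == (y > 0.5)) == 1.0
        assert (hist["train_accuracy"] == 1.0).any()

    def test_trained_model_ranks_positives_first(self):
        x, y = _separable()
        model, _ = train(x, y, CNNSpec(74), TrainingConfig(max_epochs=60, seed=3))
        p = model.predict_proba(x)
        assert p[y == 1].min() > p[y == 0].max()

    def test_permuted_labels_give_chance_holdout_accuracy(self):
        """With random labels the held-out accuracy must sit inside the 95%
        binomial band around 0.5."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(120, 74))
        y = rng.integers(0, 2, 120).astype(float)
        model, _ = train(x[:80], y[:80], CNNSpec(74),
                         TrainingConfig(max_epochs=40, seed=5))
        acc = float(np.mean((model.predict_proba(x[80:]) > 0.5) == (y[80:] > 0.5)))
        half_width = 1.96 * np.sqrt(0.25 / 40)
        assert abs(acc - 0.5) <= half_width

    def test_single_class_rejected(self):
        x, _ = _separable()
        with pytest.raises(ValueError, match="single class"):
            train(x, np.zeros(len(x)), CNNSpec(74), TrainingConfig(max_epochs=1))

    def test_seeded_training_bit_identical(self):
        x, y = _separable()
        cfg = TrainingConfig(max_epochs=5, seed=13)
        m1, h1 = train(x, y, CNNSpec(74), cfg)
        m2, h2 = train(x, y, CNNSpec(74), cfg)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1, p2)
        assert h1.equals(h2)

    def test_best_validation_checkpoint_restored(self):
        x, y = _separable(n=60)
        xv, yv = _separable(n=20, seed=9)
        model, hist = train(x, y, CNNSpec(74),
                            TrainingConfig(max_epochs=20, seed=4),
                            val_features=xv, val_labels=yv)
        best = hist["val_accuracy"].dropna().max()
        zv = model.forward_logits(xv, training=False)
        final_acc = float(np.mean((zv > 0) == (yv > 0.5)))
        assert final_acc == pytest.approx(best)


class TestPrediction:
    def test_probabilities_strictly_inside_unit_interval(self):
        model = CNN1D(CNNSpec(74), seed=2)
        p = model.predict_proba(np.random.default_rng(0).normal(size=(10, 74)))
        assert np.all((p > 0.0) & (p < 1.0))

    def test_duplicated_rows_identical_probabilities(self):
        model = CNN1D(CNNSpec(74), seed=2)
        row = np.random.default_rng(1).normal(size=74)
        p = model.predict_proba(np.vstack([row, row]))
        assert p[0] == p[1]

    def test_inference_bit_identical_across_calls(self):
        """Dropout must be inactive at inference."""
        x, y = _separable()
        model, _ = train(x, y, CNNSpec(74), TrainingConfig(max_epochs=3, seed=0))
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_length_mismatch_rejected(self):
        model = CNN1D(CNNSpec(74), seed=0)
        with pytest.raises(ValueError, match="length"):
            predict(model, np.zeros((2, 80)))


def test_save_load_roundtrip(tmp_path):
    x, y = _separable()
    cfg = TrainingConfig(max_epochs=3, seed=6)
    model, _ = train(x, y, CNNSpec(74), cfg)
    path = tmp_path / "model.npz"
    model.save(path, training_config=cfg)
    restored = CNN1D.load(path)
    assert np.array_equal(model.predict_proba(x), restored.predict_proba(x))
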