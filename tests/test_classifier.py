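"""1-D CNN tests: architecture shapes, gradients, training, evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import algascan.nn as nn
from algascan.classifier import (
    ModelSpec,
    PredictionResult,
    TrainConfig,
    build_model,
    evaluate_segmentation,
    load_model,
    predict_cube,
    save_model,
    split_train_val,
    train_model,
)
from algascan.hypercube import Hypercube
from algascan.library import Annotation, SpectralLibrary


def _library(x, y, seed=0):
    pixels = pd.DataFrame({"cube_id": "c", "row": np.arange(len(y)), "col": 0})
    return SpectralLibrary(
        np.asarray(x, dtype=np.float32),
        np.asarray(y),
        pixels,
        np.arange(np.asarray(x).shape[1], dtype=float),
    )


def _separable_library(n_per_class=120, n_bands=45, seed=0):
    rng = np.random.default_rng(seed)
    x_up = np.linspace(0, 1, n_bands) + rng.normal(0, 0.02, (n_per_class, n_bands))
    x_down = np.linspace(1, 0, n_bands) + rng.normal(0, 0.02, (n_per_class, n_bands))
    x = np.vstack([x_up, x_down])
    y = np.array(["up"] * n_per_class + ["down"] * n_per_class)
    return _library(x, y, seed)


class TestArchitecture:
    def test_default_flatten_length_is_704(self):
        spec = ModelSpec()
        # shape propagation oracle: 45 -> pool -> 22 -> pool -> 11, 64 ch
        assert spec.flatten_length == 64 * ((45 // 2) // 2) == 704

    def test_flatten_length_small_input(self):
        assert ModelSpec(n_bands=8, n_classes=2).flatten_length == 64 * 2

    @settings(max_examples=30, derandomize=True)
    @given(n_bands=st.integers(4, 200))
    def test_flatten_formula_holds_for_any_band_count(self, n_bands):
        spec = ModelSpec(n_bands=n_bands)
        model = build_model(spec, seed=0)
        x = np.zeros((2, n_bands), dtype=np.float32)
        logits = model.logits(x)
        assert logits.shape == (2, spec.n_classes)
        # the first dense layer's weight matrix encodes the flatten length
        assert model.net.layers[9].params["W"].shape[1] == spec.flatten_length

    def test_parameter_shapes_match_spec(self):
        model = build_model(ModelSpec(), seed=0)
        conv1, conv2 = model.net.layers[0], model.net.layers[4]
        assert conv1.params["W"].shape == (32, 1, 3)
        assert conv2.params["W"].shape == (64, 32, 3)
        dense1, dense2, head = (
            model.net.layers[9], model.net.layers[11], model.net.layers[13]
        )
        assert dense1.params["W"].shape == (128, 704)
        assert dense2.params["W"].shape == (128, 128)
        assert head.params["W"].shape == (5, 128)

    def test_too_few_bands_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelSpec(n_bands=3, n_classes=2))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        # independent oracle: central finite differences on the loss
        spec = ModelSpec(
            n_bands=8, n_classes=3, conv1_filters=4, conv2_filters=5,
            dense_units=6, dropout=0.0,
        )
        model = build_model(spec, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((5, 8)).astype(np.float32)
        y = np.array([0, 1, 2, 1, 0])

        def loss_fn():
            logits = model.logits(x, train=True)
            return nn.cross_entropy(logits, y)[0]

        logits = model.logits(x, train=True)
        _, grad = nn.cross_entropy(logits, y)
        model.net.backward(grad)

        eps = 1e-3
        checked = 0
        for layer in model.net.layers:
            for name, w in layer.params.items():
                flat_idx = [0, w.size // 2, w.size - 1]
                for i in set(flat_idx):
                    orig = w.flat[i]
                    w.flat[i] = orig + eps
                    up = loss_fn()
                    w.flat[i] = orig - eps
                    down = loss_fn()
                    w.flat[i] = orig
                    numeric = (up - down) / (2 * eps)
                    analytic = layer.grads[name].flat[i]
                    assert numeric == pytest.approx(analytic, abs=2e-3)
                    checked += 1
        assert checked >= 15


class TestSplit:
    def test_fraction_arithmetic(self):
        lib = _library(np.zeros((1000, 4)), np.array(["a", "b"] * 500))
        tr, va = split_train_val(lib, 0.9, seed=0)
        assert (len(tr), len(va)) == (900, 100)

    def test_same_seed_identical_split(self):
        lib = _separable_library()
        a_tr, _ = split_train_val(lib, 0.9, seed=5)
        b_tr, _ = split_train_val(lib, 0.9, seed=5)
        assert a_tr.pixels.equals(b_tr.pixels)

    def test_stratified_within_one_record(self):
        lib = _library(np.zeros((300, 4)), np.array(["a"] * 100 + ["b"] * 200))
        tr, va = split_train_val(lib, 0.9, seed=0)
        for cls, total in (("a", 100), ("b", 200)):
            n_tr = int((tr.labels == cls).sum())
            assert abs(n_tr - 0.9 * total) <= 1

    def test_too_small_library_rejected(self):
        lib = _library(np.zeros((5, 4)), np.array(["a", "b", "a", "b", "a"]))
        with pytest.raises(ValueError):
            split_train_val(lib)


class TestTraining:
    def _spec(self):
        return ModelSpec(n_bands=45, n_classes=2)

    def test_separable_classes_reach_perfect_validation_accuracy(self):
        lib = _separable_library()
        model = build_model(self._spec(), class_names=["down", "up"], seed=0)
        result = train_model(
            model, lib, TrainConfig(epochs=20, batch_size=64, seed=0)
        )
        _, val = split_train_val(lib, 0.9, seed=0)
        pred = result.model.predict(val.spectra)
        truth = np.array([result.model.class_names.index(l) for l in val.labels])
        assert np.mean(pred == truth) == 1.0

    def test_loss_trend_decreases_on_separable_data(self):
        lib = _separable_library()
        model = build_model(self._spec(), class_names=["down", "up"], seed=1)
        result = train_model(
            model, lib, TrainConfig(epochs=12, batch_size=64, seed=1)
        )
        losses = np.array(result.train_losses)
        assert losses[-3:].mean() < losses[:3].mean()
        assert len(result.val_losses) == 12

    def test_fixed_seed_reproduces_final_weights(self):
        lib = _separable_library()
        runs = []
        for _ in range(2):
            model = build_model(self._spec(), class_names=["down", "up"], seed=4)
            train_model(model, lib, TrainConfig(epochs=3, batch_size=64, seed=4))
            runs.append(model.state_arrays())
        for key in runs[0]:
            assert np.array_equal(runs[0][key], runs[1][key]), key

    def test_unknown_library_class_rejected(self):
        lib = _separable_library()
        model = build_model(self._spec(), class_names=["down", "other"], seed=0)
        with pytest.raises(ValueError, match="up"):
            train_model(model, lib, TrainConfig(epochs=1))


class TestPredictCube:
    def _trained(self):
        lib = _separable_library(n_bands=45)
        model = build_model(
            ModelSpec(n_bands=45, n_classes=2), class_names=["down", "up"], seed=0
        )
        train_model(model, lib, TrainConfig(epochs=10, batch_size=64, seed=0))
        return model

    def test_coverage_sums_to_one_and_unknowns_masked(self):
        model = self._trained()
        vals = np.tile(np.linspace(0, 1, 45, dtype=np.float32), (4, 4, 1))
        cube = Hypercube(vals, np.arange(45.0))
        cube.valid_mask[0, 0] = False
        cube.values[0, 0] = np.nan
        pred = predict_cube(model, cube)
        assert pred.label_map[0, 0] == -1
        assert sum(pred.coverage.values()) == pytest.approx(1.0)
        assert pred.coverage["up"] == pytest.approx(1.0)

    def test_band_mismatch_rejected(self):
        model = self._trained()
        cube = Hypercube(np.zeros((2, 2, 10), dtype=np.float32), np.arange(10.0))
        with pytest.raises(ValueError, match="bands"):
            predict_cube(model, cube)

    def test_model_save_load_round_trip(self, tmp_path):
        model = self._trained()
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        x = np.random.default_rng(0).random((10, 45)).astype(np.float32)
        assert np.allclose(back.logits(x), model.logits(x), atol=1e-6)


class TestEvaluation:
    def _prediction(self, label_map, names=("grey", "a", "b")):
        return PredictionResult(
            label_map=np.asarray(label_map),
            class_names=list(names),
            coverage={},
        )

    def test_perfect_prediction_scores_one(self):
        labels = np.array([[1, 1], [2, 2]])
        pred = self._prediction(labels)
        anns = [
            Annotation("c", "a", (0, 0, 2, 1)),
            Annotation("c", "b", (0, 1, 2, 2)),
        ]
        m = evaluate_segmentation(pred, anns, "c")
        assert m.macro_f1 == 1.0 and m.macro_precision == 1.0

    def test_confusion_arithmetic(self):
        # TP=9, FP=1, FN=3 for class "a"
        label_map = np.full((1, 13), 2)
        label_map[0, :9] = 1  # 9 true positives
        label_map[0, 12] = 1  # 1 false positive (truth is b)
        pred = self._prediction(label_map)
        anns = [
            Annotation("c", "a", (0, 0, 12, 1)),  # 12 truth-a pixels
            Annotation("c", "b", (12, 0, 13, 1)),
        ]
        m = evaluate_segmentation(pred, anns, "c")
        row = m.per_class.loc["a"]
        assert row["precision"] == pytest.approx(0.9)
        assert row["recall"] == pytest.approx(0.75)
        assert row["f1"] == pytest.approx(0.81818181, abs=1e-6)

    def test_class_absent_from_truth_is_nan(self):
        labels = np.array([[1, 1]])
        pred = self._prediction(labels)
        m = evaluate_segmentation(
            pred, [Annotation("c", "a", (0, 0, 2, 1))], "c"
        )
        assert np.isnan(m.per_class.loc["b", "f1"])
        assert m.macro_f1 == 1.0  # nan-classes excluded from the average

    def test_macro_excludes_background(self):
        labels = np.array([[0, 1, 2, 2]])
        pred = self._prediction(labels)
        anns = [
            Annotation("c", "grey", (0, 0, 1, 1)),
            Annotation("c", "a", (1, 0, 2, 1)),
            Annotation("c", "b", (2, 0, 4, 1)),
        ]
        m = evaluate_segmentation(pred, anns, "c")
        algae = m.per_class.drop(index="grey")
        assert m.macro_f1 == pytest.approx(float(algae["f1"].mean()))

    @settings(max_examples=40, derandomize=True)
    @given(tp=st.integers(0, 20), fp=st.integers(0, 20), fn=st.integers(0, 20))
    def test_f1_between_precision_and_recall(self, tp, fp, fn):
        from algascan.classifier import _prf

        p, r, f1 = _prf(tp, fp, fn)
        if not (np.isnan(p) or np.isnan(r) or np.isnan(f1)):
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12
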