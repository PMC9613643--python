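"""Classifier structure, label encoding, training behaviour and scoring."""

import numpy as np
import pytest

from ncctscreen.cnnmodel import (HyperParams, ModelSpec, PretrainedWeightsUnavailable,
                                 SliceClassifier, build_model, decode_labels,
                                 encode_labels, predict_slices, train)


class TestStructure:
    def test_customized_head_has_exactly_two_batchnorm_layers(self):
        model = build_model(ModelSpec(backbone="vgg16", input_size=32), HyperParams())
        assert model.n_batchnorm_layers() == 2
        manifest = model.manifest()
        assert manifest["output_units"] == 2
        assert manifest["output_activation"] == "sigmoid"
        assert manifest["loss"] == "categorical_crossentropy"
        assert manifest["optimizer"] == "adam"

    def test_vgg16_backbone_has_13_conv_layers(self):
        model = build_model(ModelSpec(backbone="vgg16", input_size=32), HyperParams())
        convs = [d for d in model.net.manifest() if d["type"] == "Conv2D"]
        assert len(convs) == 13
        assert [c["out_channels"] for c in convs] == [
            64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512
        ]

    def test_head_layout_dense_bn_dropout_twice_then_sigmoid(self):
        model = build_model(ModelSpec(backbone="small_cnn", input_size=32),
                            HyperParams(dense_units=16))
        types = [d["type"] for d in model.net.manifest()]
        i = types.index("Flatten")
        assert types[i + 1 :] == ["Dense", "BatchNorm", "Dropout",
                                  "Dense", "BatchNorm", "Dropout",
                                  "Dense", "Sigmoid"]

    def test_first_dense_parameter_count_closed_form(self):
        hp = HyperParams(dense_units=1049)
        model = build_model(ModelSpec(backbone="small_cnn", input_size=32), hp)
        dense = [d for d in model.net.manifest() if d["type"] == "Dense"]
        flat = model._flat_features
        assert dense[0]["n_params"] == (flat + 1) * 1049

    def test_small_cnn_outputs_probabilities(self):
        model = build_model(ModelSpec(backbone="small_cnn", input_size=32),
                            HyperParams(dense_units=8))
        x = np.random.default_rng(0).random((4, 32, 32)).astype(np.float32)
        s = model.scores(x)
        assert s.shape == (4,)
        assert np.all((s >= 0) & (s <= 1))

    def test_pretrained_without_fallback_raises(self):
        with pytest.raises(PretrainedWeightsUnavailable):
            SliceClassifier(ModelSpec(backbone="vgg16", input_size=32,
                                      pretrained=True, allow_random_init=False))

    def test_hyperparams_defaults_are_the_tuned_optimum(self):
        hp = HyperParams()
        assert (hp.learning_rate, hp.batch_size, hp.epochs, hp.steps_per_epoch) == \
            (0.001, 8, 4, 1000)
        assert (hp.dropout, hp.decay, hp.epsilon, hp.momentum, hp.dense_units) == \
            (0.5, 0.01, 1e-7, 0.9, 1049)


class TestLabelEncoding:
    def test_one_hot_convention(self):
        assert encode_labels(["ischemic"]).tolist() == [[1.0, 0.0]]
        assert encode_labels(["normal"]).tolist() == [[0.0, 1.0]]

    def test_empty_input(self):
        out = encode_labels([])
        assert out.shape == (0, 2)

    def test_rows_sum_to_one_and_round_trip(self):
        labels = ["ischemic", "normal", "normal", "ischemic"]
        onehot = encode_labels(labels)
        assert np.all(onehot.sum(axis=1) == 1)
        assert decode_labels(onehot) == labels

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            encode_labels(["hemorrhagic"])


class TestTraining:
    def _toy(self, n=32, size=32, seed=0):
        """Separable toy data: ischemic slices carry a dark square."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.4, 0.6, (n, size, size)).astype(np.float32)
        labels = []
        for i in range(n):
            if i % 2 == 0:
                x[i, 8:20, 8:20] -= 0.3
                labels.append("ischemic")
            else:
                labels.append("normal")
        return x, encode_labels(labels), labels

    def _model(self, epochs=3, seed=0):
        return SliceClassifier(ModelSpec(backbone="small_cnn", input_size=32),
                               HyperParams(epochs=epochs, dense_units=16), seed=seed)

    def test_zero_epochs_is_a_no_op(self):
        x, y, _ = self._toy()
        model = self._model(epochs=0)
        before = [p.copy() for p in model.net.params]
        res = model.fit(x, y, x, y)
        assert res.history == []
        assert all(np.array_equal(a, b) for a, b in zip(before, model.net.params))

    def test_empty_training_set_rejected(self):
        model = self._model()
        with pytest.raises(ValueError, match="empty"):
            model.fit(np.empty((0, 32, 32)), np.empty((0, 2)))

    def test_single_class_warns(self):
        x, y, _ = self._toy()
        keep = y[:, 0] == 1
        model = self._model(epochs=1)
        with pytest.warns(UserWarning, match="single-class"):
            model.fit(x[keep], y[keep], x[keep], y[keep])

    def test_training_is_deterministic_for_fixed_seed(self):
        x, y, _ = self._toy()
        r1 = self._model(seed=5).fit(x[:24], y[:24], x[24:], y[24:])
        r2 = self._model(seed=5).fit(x[:24], y[:24], x[24:], y[24:])
        assert r1.final_val_loss == r2.final_val_loss
        assert [h["train_loss"] for h in r1.history] == [h["train_loss"] for h in r2.history]

    def test_loss_decreases_on_separable_task(self):
        x, y, _ = self._toy(n=64)
        model = self._model(epochs=3)
        res = model.fit(x[:48], y[:48], x[48:], y[48:])
        # validation loss is the dropout-free signal; it must trend down
        val = [h["val_loss"] for h in res.history]
        assert val[-1] < val[0]
        assert min(h["train_loss"] for h in res.history) <= res.history[0]["train_loss"]

    def test_functional_train_wrapper(self):
        x, y, _ = self._toy()
        model = self._model(epochs=1)
        model2, res = train(model, (x[:24], y[:24]), (x[24:], y[24:]))
        assert model2 is model and len(res.history) >= 1


class TestPrediction:
    def test_threshold_boundary_inclusive(self):
        class Stub:
            def scores(self, x, batch=32):
                return np.array([0.49, 0.50, 0.51])

        preds = SliceClassifier.predict(Stub(), np.zeros((3, 1, 1)))
        assert [p.predicted_label for p in preds] == ["normal", "ischemic", "ischemic"]

    def test_order_and_metadata_preserved(self):
        model = SliceClassifier(ModelSpec(backbone="small_cnn", input_size=32),
                                HyperParams(dense_units=8))
        x = np.random.default_rng(1).random((3, 32, 32)).astype(np.float32)
        preds = predict_slices(model, x, subject_ids=["a", "a", "b"],
                               slice_indices=[2, 0, 1])
        assert [p.subject_id for p in preds] == ["a", "a", "b"]
        assert [p.slice_index for p in preds] == [2, 0, 1]

    def test_easy_phantom_model_accuracy(self, trained_easy_model, easy_dataset):
        """Held-out slice accuracy on the easy-contrast cohort exceeds 0.9."""
        model, splits, _ = trained_easy_model
        ds = easy_dataset
        test = splits["test"]
        s = model.scores(ds.x[test])
        truth = np.array([ds.labels[i] == "ischemic" for i in test])
        assert ((s >= 0.5) == truth).mean() > 0.9

    def test_easy_phantom_model_finds_lesion_slices(self, trained_easy_model, easy_dataset):
        """≥18 of 20 lesion-bearing slices are predicted ischemic."""
        model, splits, _ = trained_easy_model
        ds = easy_dataset
        lesion_idx = [i for i in range(len(ds)) if ds.labels[i] == "ischemic"][:20]
        s = model.scores(ds.x[lesion_idx])
        assert (s >= 0.5).sum() >= 18
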