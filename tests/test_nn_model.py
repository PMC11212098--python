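"""Neural-network engine and the fusion classifier."""

import numpy as np
import pytest

from gliofusion import nn
from gliofusion.errors import StateError, ValidationError
from gliofusion.model import (CLASS_ORDER, FeatureScaler, FeaturesOnlyModel,
                              FusionModel, TrainConfig, build_backbone,
                              predict_slices, small_backbone, train_model,
                              train_features_only)

from conftest import build_samples


class TestBackprop:
    def test_gradients_match_numerical_differentiation(self):
        """Central-difference check of every layer type in one small net."""
        rng = np.random.default_rng(0)
        net = nn.Sequential(
            nn.Conv2d(2, 3, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(3), nn.ReLU(), nn.MaxPool2d(2, 2),
            nn.GlobalAvgPool(), nn.Linear(3, 2, rng=rng))

        def promote(layer):
            for key in list(layer.params):
                layer.params[key] = layer.params[key].astype(np.float64)
            for sub in getattr(layer, "layers", []):
                promote(sub)
        promote(net)

        x = rng.normal(size=(4, 2, 8, 8))
        y = np.array([0, 1, 0, 1])

        def loss_value():
            probs = nn.softmax(net.forward(x))
            return -np.log(probs[np.arange(4), y]).mean()

        probs = nn.softmax(net.forward(x))
        _, dlogits = nn.cross_entropy(probs, y)
        net.backward(dlogits)
        grads = dict(net.named_grads())
        eps = 1e-6
        for name, p in net.named_params():
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up = loss_value()
            p[idx] = orig - eps
            down = loss_value()
            p[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)

    def test_residual_block_gradient_flow(self):
        rng = np.random.default_rng(1)
        block = nn.Residual(nn.Sequential(
            nn.Conv2d(3, 3, 3, padding=1, rng=rng), nn.BatchNorm2d(3)))
        x = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
        out = block.forward(x)
        dx = block.backward(np.ones_like(out))
        assert dx.shape == x.shape
        assert np.isfinite(dx).all()


class TestFeatureScaler:
    def test_training_matrix_standardized(self):
        rng = np.random.default_rng(0)
        m = rng.normal(5.0, 3.0, size=(20, 14))
        scaler = FeatureScaler().fit(m)
        z = scaler.transform(m)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)
        assert np.allclose(scaler.transform(scaler.mean), 0.0)

    def test_unfitted_scaler_raises(self):
        with pytest.raises(StateError):
            FeatureScaler().transform(np.zeros(14))

    def test_validation_transform_leaves_scaler_untouched(self):
        rng = np.random.default_rng(1)
        scaler = FeatureScaler().fit(rng.normal(size=(10, 14)))
        before = scaler.state_hash()
        scaler.transform(rng.normal(size=(5, 14)))
        assert scaler.state_hash() == before


@pytest.fixture(scope="module")
def model():
    return FusionModel(small_backbone(width=4, seed=0), seed=0)


class TestForwardContract:

    def test_probabilities_sum_to_one(self, model):
        rng = np.random.default_rng(0)
        probs = model.forward(rng.normal(size=(3, 4, 160, 160)),
                              rng.normal(size=(3, 14)))
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_fused_vector_has_length_28(self, model):
        rng = np.random.default_rng(0)
        model.forward(rng.normal(size=(2, 4, 160, 160)), rng.normal(size=(2, 14)))
        assert model._fused.shape == (2, 28)

    def test_zero_classifier_gives_uniform_output(self, model):
        model.classifier.params["W"][:] = 0.0
        model.classifier.params["b"][:] = 0.0
        rng = np.random.default_rng(0)
        probs = model.forward(rng.normal(size=(1, 4, 160, 160)),
                              rng.normal(size=(1, 14)))
        assert np.allclose(probs, 0.5)

    def test_wrong_channel_count_raises_shape_error(self, model):
        with pytest.raises(ValidationError):
            model.forward(np.zeros((1, 3, 160, 160)), np.zeros((1, 14)))

    def test_wrong_feature_length_raises(self, model):
        with pytest.raises(ValidationError):
            model.forward(np.zeros((1, 4, 160, 160)), np.zeros((1, 13)))


class TestTraining:
    def test_loss_decreases_over_epochs(self, trained_bundle):
        losses = trained_bundle["train_log"]["epoch_losses"]
        assert len(losses) == trained_bundle["config"].epochs
        assert losses[-1] < losses[0]

    def test_single_class_training_set_rejected(self, trained_bundle):
        hgg_only = [s for s in trained_bundle["train_samples"] if s.grade == "HGG"]
        with pytest.raises(ValidationError):
            train_model(hgg_only, TrainConfig(epochs=1))
        with pytest.raises(ValidationError):
            train_model([], TrainConfig(epochs=1))

    def test_training_deterministic_given_seed(self, small_cohort):
        _, patients, _ = small_cohort
        samples = build_samples(patients[:4] + patients[-4:])
        cfg = TrainConfig(epochs=1, batch_size=16, seed=12)
        _, log_a = train_model(samples, cfg, backbone_kwargs={"width": 4})
        _, log_b = train_model(samples, cfg, backbone_kwargs={"width": 4})
        assert log_a["epoch_losses"] == log_b["epoch_losses"]

    def test_predict_slices_shapes_and_normalization(self, trained_bundle):
        preds = predict_slices(trained_bundle["model"],
                               trained_bundle["val_samples"][:10])
        assert len(preds) == 10
        for p in preds:
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_duplicate_slices_get_identical_predictions(self, trained_bundle):
        s = trained_bundle["val_samples"][0]
        a, b = predict_slices(trained_bundle["model"], [s, s])
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_save_load_round_trip(self, trained_bundle, tmp_path):
        model = trained_bundle["model"]
        model.save(tmp_path / "m")
        loaded = FusionModel.load(tmp_path / "m")
        samples = trained_bundle["val_samples"][:6]
        orig = predict_slices(model, samples)
        back = predict_slices(loaded, samples)
        for a, b in zip(orig, back):
            assert np.allclose(a.probabilities, b.probabilities, atol=1e-6)


class TestFeaturesOnly:
    def test_features_only_model_ignores_images(self, trained_bundle):
        fm, _ = train_features_only(trained_bundle["train_samples"],
                                    TrainConfig(epochs=5, seed=0))
        preds = predict_slices(fm, trained_bundle["val_samples"][:4])
        assert all(p.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
                   for p in preds)

    def test_class_order_is_lgg_then_hgg(self):
        assert CLASS_ORDER == ("LGG", "HGG")


def test_resnet50_backbone_forward_shape():
    """The 50-layer bottleneck builder produces 2048 pooled features from a
    4-channel image (forward only; training it is out of CI scope)."""
    backbone = build_backbone("resnet50", in_channels=4, seed=0)
    x = np.random.default_rng(0).normal(size=(1, 4, 64, 64)).astype(np.float32)
    feats = backbone.forward(x)
    assert feats.shape == (1, 2048)
    n_conv = sum(1 for name, _ in backbone.named_params() if name.endswith("W"))
    assert n_conv >= 53  # 53 conv/linear weight tensors incl. shortcuts
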