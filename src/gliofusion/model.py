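"""CNN-radiomics fusion classifier for LGG/HGG grading.

A 4-channel 2D convolutional backbone produces a feature vector that a
trainable linear map projects down to 14 values — the same length as the 14
explicit 3D shape features — giving the learned and the geometric channels
equal weight.  The two 14-vectors are concatenated into a 28-vector that a
single linear layer classifies into (LGG, HGG), followed by softmax.

The backbone is a contract, not a fixed network: anything that maps a
4-channel image to a fixed-length feature vector (and can backpropagate into
its parameters) plugs in.  ``build_backbone("small")`` is a 3-block residual
net sized so training runs on one CPU in minutes; ``build_backbone("resnet50")``
is the 50-layer bottleneck residual design (no pretrained weights).

Shape features are z-scored with a scaler fitted on *training patients only*
and persisted with the model; applying the training scaler to validation
patients is the documented (and tested) anti-leakage rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, eval_transform, lgg_train_transform
from .errors import StateError, ValidationError
from .preprocess import SliceSample
from .volumes import MODALITIES

log = logging.getLogger(__name__)

#: Fixed class order everywhere: index 0 = LGG, index 1 = HGG.
CLASS_ORDER = ("LGG", "HGG")
N_SHAPE_FEATURES = 14


@dataclass
class TrainConfig:
    """Training hyperparameters: Adam, cross-entropy, L2 weight decay."""

    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    gradient_decay: float = 0.9           # Adam beta1
    squared_gradient_decay: float = 0.99  # Adam beta2
    loss: str = "cross-entropy"
    seed: int = 0
    channels: tuple[str, ...] = MODALITIES

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValidationError("learning_rate must be > 0, weight_decay >= 0")
        for name in ("gradient_decay", "squared_gradient_decay"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.loss != "cross-entropy":
            raise ValidationError(f"unsupported loss {self.loss!r}")
        self.channels = tuple(self.channels)
        unknown = set(self.channels) - set(MODALITIES)
        if unknown or not self.channels:
            raise ValidationError(f"channels must be a non-empty subset of {MODALITIES}")


class FeatureScaler:
    """Per-feature z-scoring fitted on training patients only (sd floor 1e-8)."""

    def __init__(self) -> None:
        self.mean: np.ndarray | None = None
        self.sd: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, matrix: np.ndarray) -> "FeatureScaler":
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or matrix.shape[1] != N_SHAPE_FEATURES:
            raise ValidationError(f"expected (n, 14) matrix, got {matrix.shape}")
        self.mean = matrix.mean(axis=0)
        self.sd = np.maximum(matrix.std(axis=0), 1e-8)
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("FeatureScaler used before fitting")
        features = np.asarray(features, dtype=np.float64)
        return (features - self.mean) / self.sd

    def state_hash(self) -> str:
        if not self.fitted:
            raise StateError("FeatureScaler used before fitting")
        h = hashlib.sha256()
        h.update(self.mean.tobytes())
        h.update(self.sd.tobytes())
        return h.hexdigest()

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        s = cls()
        s.mean = np.asarray(d["mean"], dtype=np.float64)
        s.sd = np.asarray(d["sd"], dtype=np.float64)
        return s


class ConvBackbone(nn.Layer):
    """Spatial body + global average pooling; exposes the last spatial maps
    (needed by gradient-weighted class-activation heatmaps)."""

    has_spatial_features = True

    def __init__(self, body: nn.Sequential, feature_dim: int,
                 in_channels: int) -> None:
        super().__init__()
        self.body = body
        self.pool = nn.GlobalAvgPool()
        self.feature_dim = feature_dim
        self.in_channels = in_channels
        self.last_spatial: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self.body.forward(x)
        self.last_spatial = a
        return self.pool.forward(a)

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        return self.body.backward(self.pool.backward(dfeat))

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.body.set_training(flag)

    def named_params(self, prefix: str = "") -> list:
        return self.body.named_params(prefix + "body.")

    def named_grads(self, prefix: str = "") -> list:
        return self.body.named_grads(prefix + "body.")

    def named_buffers(self, prefix: str = "") -> list:
        return self.body.named_buffers(prefix + "body.")


def _res_block(channels: int, rng) -> nn.Residual:
    return nn.Residual(nn.Sequential(
        nn.Conv2d(channels, channels, 3, stride=1, padding=1, rng=rng),
        nn.BatchNorm2d(channels),
        nn.ReLU(),
        nn.Conv2d(channels, channels, 3, stride=1, padding=1, rng=rng),
        nn.BatchNorm2d(channels),
    ))


def small_backbone(in_channels: int = 4, width: int = 8,
                   seed: int = 0) -> ConvBackbone:
    """Small residual net sized for CPU training.

    160x160 -> 40x40 (5x5 stride-4 stem) -> 20x20 -> residual block ->
    10x10 -> residual block -> GAP, feature length 4*width.
    """
    rng = np.random.default_rng(seed)
    body = nn.Sequential(
        nn.Conv2d(in_channels, width, 5, stride=4, padding=2, rng=rng),
        nn.BatchNorm2d(width),
        nn.ReLU(),
        nn.Conv2d(width, 2 * width, 3, stride=2, padding=1, rng=rng),
        nn.BatchNorm2d(2 * width),
        nn.ReLU(),
        _res_block(2 * width, rng),
        nn.Conv2d(2 * width, 4 * width, 3, stride=2, padding=1, rng=rng),
        nn.BatchNorm2d(4 * width),
        nn.ReLU(),
        _res_block(4 * width, rng),
    )
    return ConvBackbone(body, feature_dim=4 * width, in_channels=in_channels)


def _bottleneck(in_ch: int, mid: int, stride: int, rng) -> nn.Residual:
    out_ch = 4 * mid
    main = nn.Sequential(
        nn.Conv2d(in_ch, mid, 1, rng=rng), nn.BatchNorm2d(mid), nn.ReLU(),
        nn.Conv2d(mid, mid, 3, stride=stride, padding=1, rng=rng),
        nn.BatchNorm2d(mid), nn.ReLU(),
        nn.Conv2d(mid, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch),
    )
    shortcut = None
    if stride != 1 or in_ch != out_ch:
        shortcut = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng),
                                 nn.BatchNorm2d(out_ch))
    return nn.Residual(main, shortcut)


def resnet50_backbone(in_channels: int = 4, seed: int = 0) -> ConvBackbone:
    """50-layer bottleneck residual backbone with a 4-channel first conv.

    Stage plan (3, 4, 6, 3) with widths 64/128/256/512 and expansion 4,
    ending in global average pooling over 2048 channels.  Provided for
    full-scale runs; tests train the small backbone instead.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.Conv2d(in_channels, 64, 7, stride=2, padding=3, rng=rng),
        nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d(3, stride=2, padding=1),
    ]
    in_ch = 64
    for stage, (blocks, mid) in enumerate(zip((3, 4, 6, 3), (64, 128, 256, 512))):
        for b in range(blocks):
            stride = 2 if (b == 0 and stage > 0) else 1
            layers.append(_bottleneck(in_ch, mid, stride, rng))
            in_ch = 4 * mid
    return ConvBackbone(nn.Sequential(*layers), feature_dim=2048,
                        in_channels=in_channels)


def build_backbone(name: str, in_channels: int = 4, seed: int = 0,
                   **kwargs) -> ConvBackbone:
    if name == "small":
        return small_backbone(in_channels=in_channels, seed=seed, **kwargs)
    if name == "resnet50":
        return resnet50_backbone(in_channels=in_channels, seed=seed, **kwargs)
    raise ValidationError(f"unknown backbone {name!r}; use 'small' or 'resnet50'")


@dataclass
class SlicePrediction:
    patient_id: str
    probabilities: np.ndarray  # (2,) in CLASS_ORDER, sums to 1
    true_grade: str = ""


class FusionModel:
    """Backbone -> project-to-14 -> concat with 14 shape features -> 28 -> 2."""

    def __init__(self, backbone: ConvBackbone, seed: int = 0,
                 channels: tuple[str, ...] = MODALITIES,
                 zero_shape_features: bool = False) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 1]))
        self.backbone = backbone
        self.projection = nn.Linear(backbone.feature_dim, N_SHAPE_FEATURES, rng=rng)
        self.classifier = nn.Linear(2 * N_SHAPE_FEATURES, 2, rng=rng)
        self.scaler = FeatureScaler()
        self.channels = tuple(channels)
        self.zero_shape_features = zero_shape_features
        self.backbone_spec: dict = {}
        self.seed = seed

    # -- forward / backward ------------------------------------------------
    def forward(self, images: np.ndarray, features: np.ndarray) -> np.ndarray:
        """Class probabilities (N, 2) in order (LGG, HGG); rows sum to 1."""
        images = np.asarray(images, dtype=np.float32)
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != N_SHAPE_FEATURES:
            raise ValidationError(
                f"expected (N, {N_SHAPE_FEATURES}) feature matrix, got {features.shape}")
        if self.zero_shape_features:
            features = np.zeros_like(features)
        f = self.backbone.forward(images)
        p = self.projection.forward(f)
        fused = np.concatenate([p, features], axis=1)  # length 28 always
        self._fused = fused
        logits = self.classifier.forward(fused)
        return nn.softmax(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.classifier.backward(dlogits)
        dproj = dfused[:, :N_SHAPE_FEATURES]
        dfeat = self.projection.backward(dproj)
        self.backbone.backward(dfeat)

    def set_training(self, flag: bool) -> None:
        self.backbone.set_training(flag)

    def named_params(self) -> list:
        return (self.backbone.named_params("backbone.")
                + self.projection.named_params("projection.")
                + self.classifier.named_params("classifier."))

    def named_grads(self) -> list:
        return (self.backbone.named_grads("backbone.")
                + self.projection.named_grads("projection.")
                + self.classifier.named_grads("classifier."))

    def named_buffers(self) -> list:
        return self.backbone.named_buffers("backbone.")

    # -- persistence -------------------------------------------------------
    def save(self, model_dir) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        arrays = {f"param/{k}": v for k, v in self.named_params()}
        arrays.update({f"buffer/{k}": v for k, v in self.named_buffers()})
        np.savez(model_dir / "weights.npz", **arrays)
        manifest = {
            "backbone": self.backbone_spec or {"name": "small"},
            "channels": list(self.channels),
            "class_order": list(CLASS_ORDER),
            "seed": self.seed,
            "zero_shape_features": self.zero_shape_features,
            "scaler": self.scaler.to_dict() if self.scaler.fitted else None,
        }
        (model_dir / "model.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, model_dir) -> "FusionModel":
        model_dir = Path(model_dir)
        manifest = json.loads((model_dir / "model.json").read_text())
        spec = manifest["backbone"]
        backbone = build_backbone(spec["name"], in_channels=len(manifest["channels"]),
                                  seed=manifest["seed"], **spec.get("kwargs", {}))
        model = cls(backbone, seed=manifest["seed"],
                    channels=tuple(manifest["channels"]),
                    zero_shape_features=manifest["zero_shape_features"])
        model.backbone_spec = spec
        if manifest["scaler"] is not None:
            model.scaler = FeatureScaler.from_dict(manifest["scaler"])
        with np.load(model_dir / "weights.npz") as data:
            params = dict(model.named_params())
            buffers = dict(model.named_buffers())
            for key in data.files:
                kind, name = key.split("/", 1)
                target = params[name] if kind == "param" else buffers[name]
                target[...] = data[key]
        return model


class FeaturesOnlyModel:
    """Linear (logistic-style) classifier on the 14 standardized shape
    features alone; the image input is ignored.  Shares the prediction
    interface with FusionModel but exposes no spatial feature maps."""

    has_spatial_features = False

    def __init__(self, seed: int = 0) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 2]))
        self.classifier = nn.Linear(N_SHAPE_FEATURES, 2, rng=rng)
        self.scaler = FeatureScaler()
        self.channels = MODALITIES
        self.zero_shape_features = False
        self.seed = seed

    def forward(self, images, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != N_SHAPE_FEATURES:
            raise ValidationError(
                f"expected (N, {N_SHAPE_FEATURES}) feature matrix, got {features.shape}")
        return nn.softmax(self.classifier.forward(features))

    def backward(self, dlogits: np.ndarray) -> None:
        self.classifier.backward(dlogits)

    def set_training(self, flag: bool) -> None:
        pass

    def named_params(self) -> list:
        return self.classifier.named_params("classifier.")

    def named_grads(self) -> list:
        return self.classifier.named_grads("classifier.")


# -- training --------------------------------------------------------------

def _grade_index(grade: str) -> int:
    return CLASS_ORDER.index(grade)


def _patient_feature_matrix(samples: list[SliceSample]) -> np.ndarray:
    seen: dict[str, np.ndarray] = {}
    for s in samples:
        seen.setdefault(s.patient_id, np.asarray(s.shape_features, dtype=np.float64))
    return np.stack(list(seen.values()))


def _transform_sample(sample: SliceSample, augment_cfg: AugmentConfig | None,
                      rng: np.random.Generator, train: bool) -> np.ndarray:
    if train and sample.grade == "LGG" and augment_cfg is not None:
        return lgg_train_transform(sample.image, augment_cfg, rng)
    return eval_transform(sample.image)


def train_model(train_samples: list[SliceSample], config: TrainConfig,
                backbone: ConvBackbone | None = None,
                augment_config: AugmentConfig | None = None,
                backbone_name: str = "small", backbone_kwargs: dict | None = None,
                zero_shape_features: bool = False, lgg_pipeline: bool = True,
                ) -> tuple[FusionModel, dict]:
    """Train the fusion classifier; returns the model and a training log.

    The feature scaler is fitted on the unique training patients before the
    first epoch.  LGG training slices (including upsampled duplicates) go
    through the stochastic augmentation pipeline, re-randomized every epoch;
    HGG slices get the deterministic center crop.
    """
    grades = {s.grade for s in train_samples}
    if not train_samples or len(grades) < 2:
        raise ValidationError(f"training set must contain both classes, got {sorted(grades)}")
    if augment_config is None:
        augment_config = AugmentConfig()
    backbone_kwargs = backbone_kwargs or {}
    if backbone is None:
        backbone = build_backbone(backbone_name, in_channels=len(config.channels),
                                  seed=config.seed, **backbone_kwargs)
    model = FusionModel(backbone, seed=config.seed, channels=config.channels,
                        zero_shape_features=zero_shape_features)
    model.backbone_spec = {"name": backbone_name, "kwargs": backbone_kwargs}
    model.scaler.fit(_patient_feature_matrix(train_samples))
    scaler_hash = model.scaler.state_hash()

    optimizer = nn.Adam(learning_rate=config.learning_rate,
                        beta1=config.gradient_decay,
                        beta2=config.squared_gradient_decay,
                        weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 3]))
    feats_std = {id(s): model.scaler.transform(s.shape_features) for s in train_samples}
    labels = np.array([_grade_index(s.grade) for s in train_samples])

    epoch_losses: list[float] = []
    model.set_training(True)
    n = len(train_samples)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_samples[i] for i in idx]
            images = np.stack([
                _transform_sample(s, augment_config if lgg_pipeline else None,
                                  rng, train=True)
                for s in batch]).astype(np.float32)
            feats = np.stack([feats_std[id(s)] for s in batch])
            probs = model.forward(images, feats)
            loss, dlogits = nn.cross_entropy(probs, labels[idx])
            model.backward(dlogits.astype(np.float32))
            optimizer.step(model.named_params(), model.named_grads())
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
        log.info("epoch %d/%d mean loss %.4f", epoch + 1, config.epochs, epoch_losses[-1])

    assert model.scaler.state_hash() == scaler_hash, "scaler mutated during training"
    model.set_training(False)
    return model, {"epoch_losses": epoch_losses, "n_samples": n,
                   "config": asdict(config)}


def train_features_only(train_samples: list[SliceSample], config: TrainConfig,
                        ) -> tuple[FeaturesOnlyModel, dict]:
    """Logistic-style training on the 14 standardized features alone."""
    grades = {s.grade for s in train_samples}
    if not train_samples or len(grades) < 2:
        raise ValidationError(f"training set must contain both classes, got {sorted(grades)}")
    model = FeaturesOnlyModel(seed=config.seed)
    model.scaler.fit(_patient_feature_matrix(train_samples))
    feats = np.stack([model.scaler.transform(s.shape_features) for s in train_samples])
    labels = np.array([_grade_index(s.grade) for s in train_samples])
    optimizer = nn.Adam(learning_rate=config.learning_rate,
                        beta1=config.gradient_decay,
                        beta2=config.squared_gradient_decay,
                        weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 4]))
    n = len(train_samples)
    epoch_losses = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs = model.forward(None, feats[idx])
            loss, dlogits = nn.cross_entropy(probs, labels[idx])
            model.backward(dlogits)
            optimizer.step(model.named_params(), model.named_grads())
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
    return model, {"epoch_losses": epoch_losses, "n_samples": n}


def predict_slices(model, samples: list[SliceSample],
                   batch_size: int = 32) -> list[SlicePrediction]:
    """Per-slice class probabilities; deterministic center-crop preprocessing."""
    if not model.scaler.fitted:
        raise StateError("model has no fitted feature scaler")
    model.set_training(False)
    out: list[SlicePrediction] = []
    for start in range(0, len(samples), batch_size):
        batch = samples[start:start + batch_size]
        feats = np.stack([model.scaler.transform(s.shape_features) for s in batch])
        if isinstance(model, FeaturesOnlyModel):
            probs = model.forward(None, feats)
        else:
            images = np.stack([eval_transform(s.image) for s in batch]).astype(np.float32)
            probs = model.forward(images, feats)
        for s, p in zip(batch, probs):
            out.append(SlicePrediction(patient_id=s.patient_id,
                                       probabilities=np.asarray(p, dtype=np.float64),
                                       true_grade=s.grade))
    return out
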