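"""Gradient-weighted class-activation heatmaps over input slices.

For a trained fusion model, the heatmap of a slice for a target class is the
rectified, channel-weighted sum of the backbone's last spatial feature maps,
where each channel's weight is the spatial mean of the target logit's
gradient on that map.  The map is bilinearly upsampled to the input size and
min-max normalized to [0, 1]; a constant (all-rectified-to-zero) map yields
an all-zero heatmap by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .augment import eval_transform
from .errors import CapabilityError, ValidationError
from .model import CLASS_ORDER, FusionModel, N_SHAPE_FEATURES
from .preprocess import SliceSample


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1]
    patient_id: str
    target_class: str


def activation_heatmap(model: FusionModel, sample: SliceSample,
                       target_class: str = "HGG") -> Heatmap:
    """Class-activation heatmap for one slice sample.

    Raises :class:`CapabilityError` when the model exposes no spatial
    feature maps (e.g. the features-only classifier).
    """
    if not getattr(model, "has_spatial_features", True) or not hasattr(model, "backbone"):
        raise CapabilityError("model exposes no spatial feature maps")
    if target_class not in CLASS_ORDER:
        raise ValidationError(f"target class must be one of {CLASS_ORDER}")
    target = CLASS_ORDER.index(target_class)

    model.set_training(False)
    image = eval_transform(sample.image).astype(np.float32)[None]
    feats = model.scaler.transform(np.asarray(sample.shape_features))[None]
    model.forward(image, feats)
    maps = model.backbone.last_spatial[0]  # (C, h, w)

    # gradient of the target logit w.r.t. the pooled backbone features:
    # logit = W_clf[target] @ concat(W_proj f + b, s); chain through the
    # projection, then spread uniformly over space (GAP backward).
    d_fused = model.classifier.params["W"][target]          # (28,)
    d_proj = d_fused[:N_SHAPE_FEATURES]                     # (14,)
    d_feat = model.projection.params["W"].T @ d_proj        # (feature_dim,)
    weights = d_feat / (maps.shape[1] * maps.shape[2])      # spatial-mean grads

    cam = np.maximum((weights[:, None, None] * maps).sum(axis=0), 0.0)
    if float(cam.max()) - float(cam.min()) <= 1e-12:
        values = np.zeros(image.shape[2:], dtype=np.float64)
    else:
        values = _sk_resize(cam.astype(np.float64), image.shape[2:], order=1,
                            mode="edge", anti_aliasing=False, preserve_range=True)
        lo, hi = float(values.min()), float(values.max())
        values = (values - lo) / (hi - lo)
    return Heatmap(values=values, patient_id=sample.patient_id,
                   target_class=target_class)


def save_heatmap_png(heatmap: Heatmap, base_image: np.ndarray, out_path) -> None:
    """Write a grayscale map plus a red-overlay composite next to it."""
    from PIL import Image

    gray = (np.clip(heatmap.values, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(gray, mode="L").save(out_path)

    base = np.asarray(base_image, dtype=np.float64)
    lo, hi = base.min(), base.max()
    base8 = ((base - lo) / (hi - lo) * 255).astype(np.uint8) if hi > lo else \
        np.zeros_like(base, dtype=np.uint8)
    rgb = np.stack([base8, base8, base8], axis=-1).astype(np.float64)
    rgb[..., 0] = np.clip(rgb[..., 0] + 255 * heatmap.values * 0.6, 0, 255)
    overlay_path = str(out_path).replace(".png", "_overlay.png")
    Image.fromarray(rgb.astype(np.uint8), mode="RGB").save(overlay_path)
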