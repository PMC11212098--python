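"""Shared fixtures: phantom cohorts, digitized shapes, and one trained model.

Everything is generated programmatically at test time; the expensive trained
model bundle is session-scoped so the CNN is trained once and reused by the
model, explainability and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from gliofusion.model import TrainConfig, train_model, predict_slices
from gliofusion.phantoms import PhantomSpec, generate_cohort
from gliofusion.preprocess import slice_samples_for_patient, upsample_minority
from gliofusion.shape import extract_shape_features
from gliofusion.volumes import SegmentationMask


def digitized_ball(radius: int, spacing=(1.0, 1.0, 1.0), label: int = 2
                   ) -> SegmentationMask:
    n = 2 * radius + 5
    c = n // 2
    xs, ys, zs = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    inside = (xs - c) ** 2 + (ys - c) ** 2 + (zs - c) ** 2 <= radius ** 2
    return SegmentationMask(labels=(inside * label).astype(np.int16),
                            spacing_mm=spacing)


def digitized_ellipsoid(radii=(20, 10, 5), spacing=(1.0, 1.0, 1.0),
                        label: int = 2) -> SegmentationMask:
    shape = tuple(2 * r + 5 for r in radii)
    c = tuple(s // 2 for s in shape)
    xs, ys, zs = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    inside = (((xs - c[0]) / radii[0]) ** 2 + ((ys - c[1]) / radii[1]) ** 2
              + ((zs - c[2]) / radii[2]) ** 2) <= 1.0
    return SegmentationMask(labels=(inside * label).astype(np.int16),
                            spacing_mm=spacing)


def random_blob_mask(rng: np.random.Generator, n: int = 14) -> SegmentationMask:
    """Small random union-of-balls mask for property tests."""
    grid = np.zeros((n, n, n), dtype=bool)
    xs, ys, zs = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    for _ in range(rng.integers(1, 4)):
        c = rng.uniform(n * 0.3, n * 0.7, size=3)
        r = rng.uniform(1.5, n * 0.25)
        grid |= (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2 <= r ** 2
    return SegmentationMask(labels=(grid * 2).astype(np.int16),
                            spacing_mm=(1.0, 1.0, 1.0))


def build_samples(patients, min_tumor_pixels: int = 50):
    samples = []
    for p in patients:
        fv = extract_shape_features(p.mask).to_array()
        samples.extend(slice_samples_for_patient(
            p.volumes, p.mask, p.grade, fv, min_tumor_pixels=min_tumor_pixels))
    return samples


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient phantom cohort (4 LGG / 8 HGG) plus manifest."""
    spec = PhantomSpec(n_lgg=4, n_hgg=8, seed=7)
    patients, manifest = generate_cohort(spec)
    return spec, patients, manifest


@pytest.fixture(scope="session")
def trained_bundle(small_cohort):
    """A fusion model trained to near-saturation on the small cohort, plus a
    held-out phantom cohort for validation."""
    _, patients, _ = small_cohort
    train_samples = upsample_minority(build_samples(patients))
    val_patients, val_manifest = generate_cohort(PhantomSpec(n_lgg=3, n_hgg=5, seed=99))
    val_samples = build_samples(val_patients)
    config = TrainConfig(epochs=8, batch_size=16, seed=1)
    model, train_log = train_model(train_samples, config)
    return {"model": model, "train_log": train_log, "config": config,
            "train_samples": train_samples, "val_samples": val_samples,
            "val_patients": val_patients, "val_manifest": val_manifest}
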