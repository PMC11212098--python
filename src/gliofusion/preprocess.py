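"""Tumor-masked axial slice extraction, patient-level splits and upsampling.

Training samples are 2D: each axial slice of the tumor, with the four
modalities channel-stacked and every non-tumor pixel zeroed.  The patient's
14 3D shape features travel with every one of their slices, so the fusion
classifier sees both the in-plane appearance and the volumetric geometry.
Splitting is stratified by grade at the *patient* level (never slice level)
so no patient leaks across the train/validation boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .volumes import MODALITIES, MultimodalVolume, SegmentationMask

log = logging.getLogger(__name__)

DEFAULT_SPLIT_RATIO = 0.7
DEFAULT_MIN_TUMOR_PIXELS = 100


@dataclass
class SliceImage:
    """One masked axial slice: channel-stacked (C, H, W) image."""

    image: np.ndarray
    axial_index: int
    tumor_pixels: int


@dataclass
class SliceSample:
    """A slice plus the patient-level context the model needs."""

    image: np.ndarray            # (C, H, W) raw masked slice (pre-transform)
    patient_id: str
    grade: str                   # "LGG" or "HGG"
    shape_features: np.ndarray   # the patient's 14-vector, shared by all slices
    axial_index: int = 0
    tumor_pixels: int = 0
    is_duplicate: bool = False   # set by upsampling; duplicates re-augment independently


@dataclass
class CohortSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    ratio: float
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.val_ids)
        if overlap:
            raise ValidationError(f"patients in both split sides: {sorted(overlap)}")

    def to_dict(self) -> dict:
        return {"train_ids": list(self.train_ids), "val_ids": list(self.val_ids),
                "ratio": self.ratio, "seed": self.seed}


def masked_axial_slices(volume: MultimodalVolume, mask: SegmentationMask,
                        channels: tuple[str, ...] = MODALITIES) -> list[SliceImage]:
    """Channel-stacked axial slices with non-tumor pixels zeroed.

    Slices containing no tumor pixels are omitted; an all-background mask
    yields an empty list with a warning.
    """
    if volume.shape != mask.shape:
        raise ValidationError(
            f"volume shape {volume.shape} != mask shape {mask.shape}")
    tumor = mask.tumor()
    stacked = volume.stack(channels)  # (C, X, Y, Z)
    out: list[SliceImage] = []
    for k in range(volume.shape[2]):
        tumor_slice = tumor[:, :, k]
        n = int(tumor_slice.sum())
        if n == 0:
            continue
        img = stacked[:, :, :, k] * tumor_slice[None, :, :]
        out.append(SliceImage(image=img.astype(np.float32), axial_index=k,
                              tumor_pixels=n))
    if not out:
        log.warning("patient %s: mask contains no tumor; no slices extracted",
                    volume.patient_id)
    return out


def drop_small_tumor_slices(slices: list, min_tumor_pixels: int) -> list:
    """Keep slices whose tumor pixel count is at least the threshold."""
    if min_tumor_pixels < 0:
        raise ValidationError("min_tumor_pixels must be >= 0")
    kept = [s for s in slices if s.tumor_pixels >= min_tumor_pixels]
    if slices and not kept:
        log.warning("all %d slices below the %d-pixel threshold", len(slices),
                    min_tumor_pixels)
    return kept


def slice_samples_for_patient(volume: MultimodalVolume, mask: SegmentationMask,
                              grade: str, shape_features: np.ndarray,
                              min_tumor_pixels: int = DEFAULT_MIN_TUMOR_PIXELS,
                              channels: tuple[str, ...] = MODALITIES
                              ) -> list[SliceSample]:
    """Extract, filter and annotate one patient's training samples."""
    raw = masked_axial_slices(volume, mask, channels)
    kept = drop_small_tumor_slices(raw, min_tumor_pixels)
    feats = np.asarray(shape_features, dtype=np.float64)
    return [SliceSample(image=s.image, patient_id=volume.patient_id, grade=grade,
                        shape_features=feats, axial_index=s.axial_index,
                        tumor_pixels=s.tumor_pixels) for s in kept]


def split_by_patient(manifest: pd.DataFrame, ratio: float = DEFAULT_SPLIT_RATIO,
                     seed: int = 0) -> CohortSplit:
    """Grade-stratified patient split: floor(ratio*n) per class to training.

    The remainder goes to validation, which reproduces 78 train / 34
    validation from 112 LGG patients at ratio 0.7.  Deterministic given seed.
    """
    if not 0.0 < ratio < 1.0:
        raise ValidationError(f"split ratio must lie in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    for grade, group in manifest.groupby("grade", sort=True):
        ids = sorted(group["patient_id"].astype(str))
        if len(ids) < 2:
            raise ValidationError(f"class {grade} has {len(ids)} patient(s); need >= 2")
        order = rng.permutation(len(ids))
        n_train = int(np.floor(ratio * len(ids)))
        shuffled = [ids[i] for i in order]
        train.extend(shuffled[:n_train])
        val.extend(shuffled[n_train:])
    return CohortSplit(train_ids=tuple(sorted(train)), val_ids=tuple(sorted(val)),
                       ratio=ratio, seed=seed)


def upsample_minority(samples: list[SliceSample]) -> list[SliceSample]:
    """Round-robin duplicate minority-class slices until counts match within one.

    Duplicates are flagged so the augmentation stage re-randomizes them
    independently of their source slice.  Majority-class samples are returned
    untouched (same objects).
    """
    by_class: dict[str, list[SliceSample]] = {}
    for s in samples:
        by_class.setdefault(s.grade, []).append(s)
    if len(by_class) != 2:
        raise ValidationError(f"need two classes to upsample, got {sorted(by_class)}")
    (minority, majority) = sorted(by_class.values(), key=len)
    deficit = len(majority) - len(minority)
    extra = [replace(minority[i % len(minority)], is_duplicate=True)
             for i in range(deficit)]
    return samples + extra
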