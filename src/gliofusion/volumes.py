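"""Reading/writing NIfTI volumes, grid-consistency checks, and PNG slice export.

Conventions: arrays are indexed ``(row, column, axial)``; the axial axis is the
third array axis, so a 240x240x155 volume yields 155 axial slices.  All
coordinates are 0-based.  Volumes are assumed co-registered; no resampling is
performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from PIL import Image

from .errors import GridConsistencyError, LabelError, ValidationError

log = logging.getLogger(__name__)

#: BraTS label convention: 0 background, 1 necrotic core, 2 edema, 4 enhancing.
VALID_MASK_LABELS = frozenset({0, 1, 2, 4})
TUMOR_LABELS = (1, 2, 4)
MODALITIES = ("t1", "t2", "t1gd", "flair")

#: Manifest CSV column order shared by the cohort generator and all readers.
MANIFEST_COLUMNS = (
    "patient_id", "t1_path", "t2_path", "t1gd_path", "flair_path",
    "mask_path", "grade", "os_months", "event",
)


@dataclass
class MultimodalVolume:
    """Four co-registered 3D intensity grids plus voxel spacing in mm."""

    t1: np.ndarray
    t2: np.ndarray
    t1gd: np.ndarray
    flair: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        shapes = {m: getattr(self, m).shape for m in MODALITIES}
        if len(set(shapes.values())) != 1:
            raise GridConsistencyError(f"modality grids differ in shape: {shapes}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    def modality(self, name: str) -> np.ndarray:
        if name not in MODALITIES:
            raise ValidationError(f"unknown modality {name!r}; expected one of {MODALITIES}")
        return getattr(self, name)

    def stack(self, channels: tuple[str, ...] = MODALITIES) -> np.ndarray:
        """Channel-stack the requested modalities into a (C, X, Y, Z) array."""
        return np.stack([self.modality(c) for c in channels], axis=0)


@dataclass
class SegmentationMask:
    """Integer-labeled 3D grid on the same lattice as its volume."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise LabelError("mask contains non-integer values")
            self.labels = rounded.astype(np.int16)
        present = set(np.unique(self.labels).tolist())
        bad = present - VALID_MASK_LABELS
        if bad:
            raise LabelError(f"mask contains labels outside {{0,1,2,4}}: {sorted(bad)}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def tumor(self) -> np.ndarray:
        """Boolean whole-tumor grid (labels 1, 2 or 4)."""
        return np.isin(self.labels, TUMOR_LABELS)


@dataclass
class PatientMeta:
    patient_id: str
    grade: str
    os_months: float
    event: int
    extra: dict = field(default_factory=dict)


def _affine_from_spacing(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_nifti(path, data: np.ndarray, spacing_mm) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine_from_spacing(spacing_mm))
    img.header.set_zooms(tuple(float(s) for s in spacing_mm))
    nib.save(img, str(path))


def _load_grid(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def read_patient(row: Mapping) -> tuple[MultimodalVolume, SegmentationMask, PatientMeta]:
    """Load one manifest row into a volume, mask and metadata record.

    Raises :class:`GridConsistencyError` naming the offending file on shape
    mismatch and :class:`LabelError` for labels outside the BraTS convention.
    """
    grids = {}
    spacing = None
    for mod in MODALITIES:
        path = row[f"{mod}_path"]
        grids[mod], spacing = _load_grid(path)
    mask_grid, mask_spacing = _load_grid(row["mask_path"])

    ref_shape = grids["t1"].shape
    for mod in MODALITIES:
        if grids[mod].shape != ref_shape:
            raise GridConsistencyError(
                f"{row[f'{mod}_path']}: shape {grids[mod].shape} != T1 shape {ref_shape}")
    if mask_grid.shape != ref_shape:
        raise GridConsistencyError(
            f"{row['mask_path']}: mask shape {mask_grid.shape} != volume shape {ref_shape}")

    volume = MultimodalVolume(
        t1=np.asarray(grids["t1"], dtype=np.float32),
        t2=np.asarray(grids["t2"], dtype=np.float32),
        t1gd=np.asarray(grids["t1gd"], dtype=np.float32),
        flair=np.asarray(grids["flair"], dtype=np.float32),
        spacing_mm=spacing,
        patient_id=str(row["patient_id"]),
    )
    mask = SegmentationMask(labels=np.asarray(mask_grid), spacing_mm=mask_spacing)
    os_raw = row.get("os_months", np.nan)
    meta = PatientMeta(
        patient_id=str(row["patient_id"]),
        grade=str(row["grade"]),
        os_months=float(os_raw) if os_raw is not None else np.nan,
        event=int(row.get("event", 1)),
    )
    return volume, mask, meta


def export_slices_png(volume: MultimodalVolume, out_dir) -> list[Path]:
    """Write one 8-bit grayscale PNG per axial index per modality.

    Intensities are windowed per volume by min-max to [0, 255]; a constant
    volume yields all-black PNGs (logged, not an error).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    n_axial = volume.shape[2]
    for mod in MODALITIES:
        grid = volume.modality(mod).astype(np.float64)
        lo, hi = float(grid.min()), float(grid.max())
        if hi <= lo:
            log.warning("volume %s/%s is constant; exporting all-black PNGs",
                        volume.patient_id, mod)
            scaled = np.zeros_like(grid)
        else:
            scaled = (grid - lo) / (hi - lo) * 255.0
        scaled = np.clip(np.rint(scaled), 0, 255).astype(np.uint8)
        for k in range(n_axial):
            path = out_dir / f"{volume.patient_id or 'volume'}_{mod}_{k:03d}.png"
            Image.fromarray(scaled[:, :, k], mode="L").save(path)
            written.append(path)
    return written
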