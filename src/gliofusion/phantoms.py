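"""Synthetic multimodal MRI phantoms with grade-dependent tumor geometry.

Each phantom patient carries four co-registered modality volumes (T1, T2,
T1-Gd, FLAIR), a multi-label tumor mask in the BraTS convention, a binary
grade (LGG/HGG) and an overall-survival record.  Tumors are unions of
ellipsoids: one ellipsoid for LGG, several overlapping lobes for HGG, with the
HGG radius range strictly larger so that 3D shape features are
class-informative by construction.  The tumor interior is partitioned, from
the rim inward, into edema (label 2), enhancing tumor (label 4) and necrotic
core (label 1) by Euclidean distance to the tumor boundary.

Randomness is split per patient from the cohort seed via a stable hash of the
patient id, so adding patients to a cohort never perturbs earlier ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .volumes import (MANIFEST_COLUMNS, MODALITIES, MultimodalVolume,
                      SegmentationMask, write_nifti)

LGG, HGG = "LGG", "HGG"
GRADES = (LGG, HGG)

#: Per-modality, per-tissue mean intensities (arbitrary units in [0, 1]).
#: Rows follow clinical contrast ordering: necrosis is T1-dark/T2-bright,
#: edema is FLAIR-bright, enhancing tumor is bright on gadolinium T1.
DEFAULT_CONTRAST: dict[str, dict[str, float]] = {
    "t1":    {"background": 0.45, "necrosis": 0.20, "edema": 0.35, "enhancing": 0.50},
    "t2":    {"background": 0.40, "necrosis": 0.80, "edema": 0.70, "enhancing": 0.55},
    "t1gd":  {"background": 0.45, "necrosis": 0.20, "edema": 0.35, "enhancing": 0.90},
    "flair": {"background": 0.40, "necrosis": 0.55, "edema": 0.85, "enhancing": 0.60},
}

_TISSUE_LABEL = {"necrosis": 1, "edema": 2, "enhancing": 4}


@dataclass
class PhantomSpec:
    """Cohort-level parameters of the phantom generator.

    Defaults give a desk-scale cohort: a 64x64x48 grid at 1 mm isotropic
    spacing, an LGG:HGG imbalance of roughly 1:3.6 and exponential survival
    with a longer LGG scale.  ``full_scale_grid()`` returns the 240x240x155
    grid of the source datasets.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lgg: int = 14
    n_hgg: int = 50
    lgg_radius_mm: tuple[float, float] = (4.0, 8.0)
    hgg_radius_mm: tuple[float, float] = (9.0, 14.0)
    lobe_count_hgg: tuple[int, int] = (2, 4)
    modality_contrast: dict = field(default_factory=lambda: {
        m: dict(t) for m, t in DEFAULT_CONTRAST.items()})
    noise_sd: float = 0.03
    edema_depth_mm: float = 2.0
    rim_depth_mm: float = 2.0
    os_scale_months: dict = field(default_factory=lambda: {LGG: 60.0, HGG: 15.0})
    censor_prob: float = 0.2
    seed: int = 0

    @staticmethod
    def full_scale_grid() -> tuple[int, int, int]:
        return (240, 240, 155)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) <= 0 for g in self.grid_shape):
            raise ValidationError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if self.n_lgg < 0 or self.n_hgg < 0:
            raise ValidationError("cohort sizes must be non-negative")
        for name, rng_ in (("lgg_radius_mm", self.lgg_radius_mm),
                           ("hgg_radius_mm", self.hgg_radius_mm)):
            lo, hi = rng_
            if lo <= 0 or hi < lo:
                raise ValidationError(f"{name} must be a positive range, got {rng_}")
        if not (self.hgg_radius_mm[0] > self.lgg_radius_mm[0]
                and self.hgg_radius_mm[1] > self.lgg_radius_mm[1]):
            raise ValidationError("hgg_radius_mm must be strictly larger than lgg_radius_mm")
        lo, hi = self.lobe_count_hgg
        if lo < 1 or hi < lo:
            raise ValidationError(f"lobe_count_hgg must be an integer range >= 1, got {self.lobe_count_hgg}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not (0.0 <= self.censor_prob <= 1.0):
            raise ValidationError("censor_prob must lie in [0, 1]")
        if not (self.os_scale_months[LGG] > 0 and self.os_scale_months[HGG] > 0):
            raise ValidationError("os_scale_months must be positive")
        if self.os_scale_months[LGG] <= self.os_scale_months[HGG]:
            raise ValidationError("LGG survival scale must exceed HGG scale")
        tissues = {"background", "necrosis", "edema", "enhancing"}
        for m in MODALITIES:
            if m not in self.modality_contrast or set(self.modality_contrast[m]) != tissues:
                raise ValidationError(f"modality_contrast must map {m} to means for {sorted(tissues)}")


@dataclass
class SyntheticPatient:
    patient_id: str
    volumes: MultimodalVolume
    mask: SegmentationMask
    grade: str
    os_months: float
    event: int
    #: generator provenance: list of (center_mm, radii_mm) per ellipsoid lobe
    lobes: list = field(default_factory=list)


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    # crc32 keeps the per-patient entropy stable across runs and platforms
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(patient_id.encode())]))


def _voxel_coords_mm(grid_shape, spacing_mm):
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing_mm)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grid_shape, spacing_mm, center_mm, radii_mm) -> np.ndarray:
    xs, ys, zs = _voxel_coords_mm(grid_shape, spacing_mm)
    q = (((xs - center_mm[0]) / radii_mm[0]) ** 2
         + ((ys - center_mm[1]) / radii_mm[1]) ** 2
         + ((zs - center_mm[2]) / radii_mm[2]) ** 2)
    return q <= 1.0


def _clip_radii(radii, center_mm, extent_mm, margin_mm):
    """Shrink radii so the ellipsoid stays inside the grid with a margin."""
    clipped = []
    for r, c, e in zip(radii, center_mm, extent_mm):
        room = min(c, e - c) - margin_mm
        clipped.append(max(min(r, room), 1.5))
    return tuple(clipped)


def generate_patient(spec: PhantomSpec, grade: str,
                     rng: np.random.Generator) -> SyntheticPatient:
    """Build one phantom patient of the requested grade.

    The tumor is a union of one (LGG) or ``lobe_count_hgg`` (HGG) overlapping
    ellipsoids; radii that would cross the grid boundary are clipped.  Each
    modality grid is the per-tissue contrast mean plus i.i.d. Gaussian noise.
    Survival time is exponential with the grade's scale; ``event`` is 1 with
    probability ``1 - censor_prob``.
    """
    if grade not in GRADES:
        raise ValidationError(f"grade must be one of {GRADES}, got {grade!r}")
    shape, spacing = spec.grid_shape, spec.spacing_mm
    extent_mm = tuple((n - 1) * s for n, s in zip(shape, spacing))
    radius_range = spec.lgg_radius_mm if grade == LGG else spec.hgg_radius_mm
    n_lobes = 1 if grade == LGG else int(rng.integers(spec.lobe_count_hgg[0],
                                                      spec.lobe_count_hgg[1] + 1))
    margin = 2.0 * max(spacing)

    center0 = tuple(e / 2 + rng.uniform(-0.1, 0.1) * e for e in extent_mm)
    tumor = np.zeros(shape, dtype=bool)
    lobes = []
    for i in range(n_lobes):
        if i == 0:
            center = center0
        else:
            base_r = lobes[0][1]
            center = tuple(np.clip(c + rng.uniform(-0.7, 0.7) * r, margin, e - margin)
                           for c, r, e in zip(center0, base_r, extent_mm))
        radii = tuple(rng.uniform(*radius_range) for _ in range(3))
        radii = _clip_radii(radii, center, extent_mm, margin)
        tumor |= _ellipsoid_mask(shape, spacing, center, radii)
        lobes.append((center, radii))

    # partition interior: edema band at the rim, enhancing ring, necrotic core
    depth = ndimage.distance_transform_edt(tumor, sampling=spacing)
    labels = np.zeros(shape, dtype=np.int16)
    labels[tumor] = 2
    inner = tumor & (depth > spec.edema_depth_mm)
    labels[inner] = 4
    core = tumor & (depth > spec.edema_depth_mm + spec.rim_depth_mm)
    labels[core] = 1

    tissue_of_label = {0: "background", 1: "necrosis", 2: "edema", 4: "enhancing"}
    grids = {}
    for mod in MODALITIES:
        means = spec.modality_contrast[mod]
        grid = np.zeros(shape, dtype=np.float32)
        for lab, tissue in tissue_of_label.items():
            grid[labels == lab] = means[tissue]
        if spec.noise_sd > 0:
            grid = grid + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        grids[mod] = grid.astype(np.float32)

    os_months = float(rng.exponential(spec.os_scale_months[grade]))
    os_months = max(os_months, 0.1)
    event = int(rng.uniform() < 1.0 - spec.censor_prob)

    volume = MultimodalVolume(spacing_mm=spacing, patient_id="", **grids)
    mask = SegmentationMask(labels=labels, spacing_mm=spacing)
    return SyntheticPatient(patient_id="", volumes=volume, mask=mask, grade=grade,
                            os_months=os_months, event=event, lobes=lobes)


def generate_cohort(spec: PhantomSpec, out_dir=None
                    ) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate the full cohort and its manifest.

    Returns ``n_lgg`` LGG followed by ``n_hgg`` HGG patients with unique ids.
    When ``out_dir`` is given, writes per-modality/mask NIfTI files and a
    manifest CSV there; otherwise path columns are empty strings.
    """
    if spec.n_lgg + spec.n_hgg < 1:
        raise ValidationError("cohort must contain at least one patient")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    patients: list[SyntheticPatient] = []
    rows = []
    plan = [(LGG, i) for i in range(spec.n_lgg)] + [(HGG, i) for i in range(spec.n_hgg)]
    for grade, i in plan:
        pid = f"{grade}-{i:03d}"
        patient = generate_patient(spec, grade, _patient_rng(spec.seed, pid))
        patient.patient_id = pid
        patient.volumes.patient_id = pid
        paths = {f"{m}_path": "" for m in MODALITIES}
        mask_path = ""
        if out_path is not None:
            for mod in MODALITIES:
                p = out_path / f"{pid}_{mod}.nii.gz"
                write_nifti(p, patient.volumes.modality(mod), spec.spacing_mm)
                paths[f"{mod}_path"] = str(p)
            p = out_path / f"{pid}_mask.nii.gz"
            write_nifti(p, patient.mask.labels, spec.spacing_mm)
            mask_path = str(p)
        rows.append({"patient_id": pid, **paths, "mask_path": mask_path,
                     "grade": grade, "os_months": round(patient.os_months, 4),
                     "event": patient.event})
        patients.append(patient)

    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return patients, manifest
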