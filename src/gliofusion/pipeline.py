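"""End-to-end orchestration: simulate -> features -> split -> train ->
evaluate -> survival -> explain, with one config, seed control and a run
directory holding every stage's outputs and config echo."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .errors import GlioFusionError
from .evaluate import aggregate_by_patient, confusion_and_metrics
from .explain import activation_heatmap, save_heatmap_png
from .model import (FusionModel, TrainConfig, predict_slices, train_model)
from .phantoms import PhantomSpec, generate_cohort
from .preprocess import (DEFAULT_MIN_TUMOR_PIXELS, slice_samples_for_patient,
                         split_by_patient, upsample_minority)
from .shape import FEATURE_NAMES, extract_shape_features
from .survival import (impute_missing_os, km_estimate, km_plot, logrank,
                       records_from_manifest)
from .volumes import read_patient

log = logging.getLogger(__name__)

ABLATION_ROWS = ("w/o Augment", "w/o CyclicShift", "w/o Rotation", "w/o Flip",
                 "w/o Duplication", "Our work")


class StageError(GlioFusionError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str = "run"
    manifest_path: str | None = None     # None -> simulate a phantom cohort
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    split_ratio: float = 0.7
    split_seed: int = 0
    min_tumor_pixels: int = DEFAULT_MIN_TUMOR_PIXELS
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    backbone: str = "small"
    backbone_kwargs: dict = field(default_factory=dict)
    zero_shape_features: bool = False
    lgg_geometry_pipeline: bool = True   # False = center crop only ("w/o Augment")
    make_heatmap: bool = True

    def echo(self) -> dict:
        d = asdict(self)
        return d


def compute_features_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """patient_id + the 14 shape features (fixed order) for every patient."""
    rows = []
    for row in manifest.to_dict("records"):
        _, mask, meta = read_patient(row)
        vec = extract_shape_features(mask)
        rows.append({"patient_id": meta.patient_id,
                     **dict(zip(FEATURE_NAMES, vec.to_array()))})
    return pd.DataFrame(rows, columns=["patient_id", *FEATURE_NAMES])


def load_slice_samples(manifest: pd.DataFrame, ids, features: pd.DataFrame,
                       min_tumor_pixels: int, channels) -> list:
    feat_by_id = {str(r["patient_id"]): np.array([r[n] for n in FEATURE_NAMES])
                  for r in features.to_dict("records")}
    samples = []
    wanted = set(ids)
    for row in manifest.to_dict("records"):
        pid = str(row["patient_id"])
        if pid not in wanted:
            continue
        volume, mask, meta = read_patient(row)
        samples.extend(slice_samples_for_patient(
            volume, mask, meta.grade, feat_by_id[pid],
            min_tumor_pixels=min_tumor_pixels, channels=tuple(channels)))
    return samples


def run_end_to_end(config: RunConfig) -> Path:
    """Run the whole pipeline; returns the run directory.

    A failing stage raises :class:`StageError` naming the stage; outputs of
    completed stages are retained in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.echo(), indent=2, default=str))
    stage = "simulate"
    timings: dict[str, float] = {}
    try:
        t0 = time.time()
        if config.manifest_path is None:
            _, manifest = generate_cohort(config.phantom, out_dir=out / "cohort")
            manifest_path = out / "cohort" / "manifest.csv"
        else:
            manifest_path = Path(config.manifest_path)
            manifest = pd.read_csv(manifest_path)
        timings[stage] = time.time() - t0

        stage = "features"
        t0 = time.time()
        features = compute_features_table(manifest)
        features.to_csv(out / "features.csv", index=False)
        timings[stage] = time.time() - t0

        stage = "split"
        split = split_by_patient(manifest, ratio=config.split_ratio,
                                 seed=config.split_seed)
        (out / "split.json").write_text(json.dumps(split.to_dict(), indent=2))

        stage = "preprocess"
        t0 = time.time()
        channels = config.train.channels
        train_samples = load_slice_samples(manifest, split.train_ids, features,
                                           config.min_tumor_pixels, channels)
        val_samples = load_slice_samples(manifest, split.val_ids, features,
                                         config.min_tumor_pixels, channels)
        if config.augment.enable_duplication:
            train_samples = upsample_minority(train_samples)
        timings[stage] = time.time() - t0

        stage = "train"
        t0 = time.time()
        model, train_log = train_model(
            train_samples, config.train, augment_config=config.augment,
            backbone_name=config.backbone, backbone_kwargs=config.backbone_kwargs,
            zero_shape_features=config.zero_shape_features,
            lgg_pipeline=config.lgg_geometry_pipeline)
        model_dir = out / "model"
        model.save(model_dir)
        (model_dir / "training_log.json").write_text(json.dumps(train_log, indent=2))
        timings[stage] = time.time() - t0

        stage = "evaluate"
        t0 = time.time()
        slice_preds = predict_slices(model, val_samples)
        patients = aggregate_by_patient(slice_preds)
        report = confusion_and_metrics(patients)
        report_dict = {"metrics": report.rounded(),
                       "roc_points": [list(p) for p in report.roc_points],
                       "n_patients": len(patients),
                       "channels": list(channels),
                       "config": config.echo()}
        (out / "report.json").write_text(json.dumps(report_dict, indent=2, default=str))
        timings[stage] = time.time() - t0

        stage = "survival"
        records = records_from_manifest(manifest)
        for group in ("LGG", "HGG"):
            records = impute_missing_os(records, group)
        curves = {g: km_estimate([r for r in records if r.group == g])
                  for g in ("LGG", "HGG")}
        lr = logrank([r for r in records if r.group == "LGG"],
                     [r for r in records if r.group == "HGG"])
        surv = {"logrank": {"chi_square": lr.chi_square, "p_value": lr.p_value,
                            "df": lr.df},
                "km": {g: {"event_times": c.event_times.tolist(),
                           "survival_probs": c.survival_probs.tolist(),
                           "at_risk": c.at_risk.tolist()}
                       for g, c in curves.items()}}
        (out / "survival.json").write_text(json.dumps(surv, indent=2))
        km_plot(curves, out / "km.png")

        stage = "explain"
        if config.make_heatmap and val_samples:
            sample = max(val_samples, key=lambda s: s.tumor_pixels)
            hm = activation_heatmap(model, sample, target_class=sample.grade)
            from .augment import eval_transform
            save_heatmap_png(hm, eval_transform(sample.image)[0],
                             out / f"heatmap_{sample.patient_id}.png")
    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        raise StageError(stage, exc) from exc

    (out / "run.json").write_text(json.dumps(
        {"stages": list(timings), "seconds": timings}, indent=2))
    return out


def _row_config(base: RunConfig, row: str, out_root: Path) -> RunConfig:
    aug = AugmentConfig(**asdict(base.augment))
    lgg_pipeline = base.lgg_geometry_pipeline
    if row == "w/o Augment":
        aug = AugmentConfig.disabled()
        lgg_pipeline = False
    elif row == "w/o CyclicShift":
        aug.enable_cyclic_shift = False
    elif row == "w/o Rotation":
        aug.enable_rotation = False
    elif row == "w/o Flip":
        aug.enable_flip = False
    elif row == "w/o Duplication":
        aug.enable_duplication = False
    elif row != "Our work":
        raise GlioFusionError(f"unknown ablation row {row!r}")
    cfg = RunConfig(**{**asdict(base), "augment": aug,
                       "phantom": base.phantom, "train": base.train,
                       "lgg_geometry_pipeline": lgg_pipeline,
                       "out_dir": str(out_root / row.replace("/", "").replace(" ", "_"))})
    return cfg


def ablation_matrix(base: RunConfig, rows=ABLATION_ROWS) -> pd.DataFrame:
    """One full run per augmentation-ablation row, shared seeds throughout."""
    out_root = Path(base.out_dir)
    results = []
    for row in rows:
        cfg = _row_config(base, row, out_root)
        run_dir = run_end_to_end(cfg)
        report = json.loads((run_dir / "report.json").read_text())["metrics"]
        results.append({"row": row, **{k: report[k] for k in
                                       ("auc", "acc", "apca", "sen", "spe")}})
    table = pd.DataFrame(results)
    table.to_csv(out_root / "ablation.csv", index=False)
    return table
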