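# gliofusion

Glioma grading from multimodal MRI by fusing a 2D convolutional network with
explicit 3D tumor-shape features.

**Who it is for.** Researchers in medical image analysis who want a tested,
self-contained reference implementation of CNN–radiomics feature fusion for
binary tumor grading (low-grade vs high-grade glioma), including the full
surrounding pipeline: tumor-masked slice extraction, class-imbalance
handling, augmentation, per-patient aggregation, the clinical metric suite,
Kaplan-Meier/log-rank survival analysis and activation heatmaps.  A
synthetic phantom generator makes every stage runnable and testable with no
data download.

## The model

Inputs per patient: four co-registered volumes (T1, T2, T1-Gd, FLAIR) and a
BraTS-convention segmentation (0 background, 1 necrosis, 2 edema,
4 enhancing).  For each tumor-bearing axial slice, the four modalities are
channel-stacked with non-tumor pixels zeroed and passed to a convolutional
backbone (a CPU-sized residual net by default; a 50-layer bottleneck
residual builder is included).  The backbone's pooled features are projected
to 14 values and concatenated with the patient's 14 standardized 3D shape
descriptors:

> mesh volume, voxel volume, surface area, surface/volume ratio, sphericity
> = (36πV²)^⅓/A, maximum 3D diameter, maximum 2D diameter (slice / column /
> row), major / minor / least axis length (4·√λᵢ of the voxel-cloud
> covariance), elongation = √(λ₂/λ₁), flatness = √(λ₃/λ₁)

The 28-vector feeds one linear layer with softmax over (LGG, HGG).  Training
uses Adam (lr 1e-3, β₁ 0.9, β₂ 0.99, weight decay 5e-4), cross-entropy,
batch 16, with flip / cyclic-shift / rotation / salt-and-pepper augmentation
and upsampling applied to the minority LGG class only.  Per-patient
predictions are the mean of the slice softmax pairs; metrics (AUC, Acc,
APCA = (SEN+SPE)/2, SEN, SPE) are computed at patient level with HGG as the
positive class.  See `docs/methods.md` for the full account.

## Worked example

`examples/03_train_and_evaluate.py` trains on 12 phantom patients (4 LGG /
8 HGG) and scores a held-out 8-patient cohort:

```text
epoch losses: [0.6506, 0.3608, 0.206]
validation metrics: {'auc': 1.0, 'acc': 1.0, 'apca': 1.0, 'sen': 1.0,
                     'spe': 1.0, 'confusion': {'tp': 5, 'fn': 0, 'fp': 0, 'tn': 3}}
```

The loss falls across epochs and the held-out phantoms are graded perfectly
— phantom grade is determined by tumor size and shape, which both fusion
channels carry.  `examples/04_survival.py` shows the survival side:

```text
LGG: 22 event times, median OS ~ 42.6 months
HGG: 26 event times, median OS ~ 13.8 months
log-rank chi2 = 14.84, p = 1.17e-04
```

The other examples cover cohort simulation, shape-feature extraction on an
analytic sphere, and activation heatmaps.  The same stages are scriptable
from a shell:

```bash
gliofusion simulate --n-lgg 4 --n-hgg 8 --seed 0 --out cohort/
gliofusion features --manifest cohort/manifest.csv --out features.csv
gliofusion run --out run/ --seed 0          # full pipeline in one command
gliofusion ablate --out ablation/ --seed 0  # augmentation ablation table
```

## Layout

- `src/gliofusion/` — `phantoms` (synthetic cohorts), `volumes` (NIfTI/PNG
  I/O), `shape` (14 descriptors), `preprocess`, `augment`, `nn` (numpy
  network engine), `model` (fusion classifier), `evaluate`, `survival`,
  `explain`, `pipeline`, `cli`
- `tests/` — unit, property and acceptance suites
- `examples/` — one short narrative script per capability
- `docs/methods.md` — model, assumptions, parameter choices, limitations
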