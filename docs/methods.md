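# Methods

## The model

gliofusion grades gliomas as low-grade (LGG, WHO I–II) versus high-grade
(HGG, WHO III–IV) from four co-registered MRI modalities — T1, T2,
gadolinium-enhanced T1 (T1-Gd) and FLAIR — plus an integer-labeled tumor
segmentation in the BraTS convention (0 background, 1 necrotic core, 2 edema,
4 enhancing tumor).

The classifier is a fusion of two information channels:

1. **2D appearance.** Each axial slice that contains tumor is extracted with
   the four modalities channel-stacked and every non-tumor pixel zeroed, and
   fed to a 2D convolutional backbone.  The backbone's pooled feature vector
   is projected by a trainable affine map to 14 values.
2. **3D geometry.** Fourteen explicit shape descriptors of the whole tumor
   (see below), standardized and attached to every slice of the patient.

The projected 14-vector and the standardized 14 shape features are
concatenated into a 28-vector and classified by a single linear layer with
softmax into (LGG, HGG) — class order fixed everywhere, HGG is the positive
class.  Projecting the learned features to exactly the length of the shape
vector gives the two channels equal nominal weight.  The projection is a
plain affine map (no nonlinearity or extra bias beyond the linear layer's);
nothing in the fusion design requires more.

Slice-level probability pairs are averaged per patient (arithmetic mean) and
the patient's grade is the argmax, ties resolved toward HGG as the clinically
conservative call.  All metrics — AUC, accuracy, average per-class accuracy
(APCA = (SEN+SPE)/2 in the binary case), sensitivity, specificity — are
computed at the patient level, never the slice level.

### Backbones

The backbone is a contract: any module mapping a 4-channel image to a fixed
feature vector, with backpropagation into its parameters.  Two builders ship:

- `small` (default for tests and desk-scale runs): a residual net
  160→40→20→10 with two residual blocks and global average pooling, feature
  length `4*width` (default width 8 → 32).  Sized so a full training run
  takes minutes on one CPU core.
- `resnet50`: the 50-layer bottleneck residual design (stages 3/4/6/3,
  widths 64–512, expansion 4, 7×7 stem and max-pooling, 2048 features),
  with a 4-channel first convolution.  No pretrained weights are bundled.

The whole network stack (convolution via im2col, batch normalization,
pooling, linear layers, softmax cross-entropy and Adam with L2 weight decay)
is implemented on numpy in `gliofusion.nn`; backpropagation is verified
against central differences in the test suite to ~1e-7 relative error in
float64.

### Training

Adam with learning rate 1e-3, weight decay 5e-4, gradient decay (β₁) 0.9 and
squared-gradient decay (β₂) 0.99; cross-entropy loss; batch size 16; 20
epochs at full scale (tests and the smoke pipeline use 3–8 epochs).  The
feature scaler (per-feature z-score, sd floored at 1e-8) is fitted on
training patients only and persisted with the model; a hash assertion guards
against refitting during training.  Training is bitwise reproducible for a
fixed seed in single-threaded mode.

## The 14 shape descriptors

Computed from the whole tumor (union of labels 1, 2, 4), following the
IBSI-style morphology definitions:

| group | features | definition |
|---|---|---|
| volume | mesh_volume, voxel_volume | signed-tetrahedron sum over the surface mesh; voxel count × voxel volume |
| surface | surface_area, surface_volume_ratio, sphericity | triangle-area sum; A/V; (36πV²)^⅓/A |
| diameters | max_3d_diameter + slice/column/row 2D variants | max pairwise vertex distance; 2D variants restrict to vertex pairs whose coordinate along the perpendicular axis agrees within half a voxel |
| axes | major/minor/least_axis_length, elongation, flatness | 4·√λᵢ for eigenvalues of the population covariance of physical voxel centers; √(λ₂/λ₁); √(λ₃/λ₁) |

The surface mesh is marching cubes at iso-level 0.5 on the mask zero-padded
by one voxel per side, so single-voxel and boundary-touching tumors still
yield closed meshes; vertices are in physical mm.  The maximum-diameter
search reduces large vertex sets to their convex hull (exact: the maximum is
attained between hull vertices) and otherwise matches an O(n²) brute force
bit-for-bit, which the tests assert.

**Numerical notes.** A discretization study on digitized balls (r = 4–18
voxels) shows the mesh volume converges quickly (within 5% by r≈6, within 1%
by r≈10), while marching cubes on a binary grid inflates surface area by a
resolution-independent ~8–10% (the staircase effect, shared by any
mesh-from-binary pipeline).  Sphericity of digitized balls therefore
plateaus at 0.91–0.92 rather than 1.0; the test band [0.88, 1.0] is frozen
from that study.  Orderings (ball rounder than ellipsoid) and all scaling
covariances (volumes ∝ s³, areas ∝ s², lengths ∝ s, dimensionless features
invariant) hold exactly.  Degenerate inputs: a single voxel yields zero axis
lengths and ratios with a warning; an empty tumor is an error; a zero-volume
mesh is an error.

## Preprocessing and augmentation

Slices are filtered by a minimum tumor pixel count (default 100,
configurable — the exclusion rule for "too small" tumors has no published
threshold, so it is exposed and logged).  The train/validation split is
stratified by grade at the patient level with floor(0.7·n) per class to
training — floor rounding reproduces a 78/34 split of 112 LGG patients.
Minority-class (LGG) slices are duplicated round-robin until slice counts
balance; duplicates are flagged and re-augmented independently every epoch.

LGG training slices go through: resize to 448 → center-crop 224 →
random-crop 160, then each enabled stochastic augment independently with
probability 0.5: horizontal/vertical flip, cyclic shift (translation with
wrap-around fill, conserving the exact pixel multiset; magnitude bounded by
half the image), rotation uniform in [−180°, 180°] (bilinear, zero fill) and
salt-and-pepper noise (default fraction 0.02, same positions across
channels).  HGG training slices and *all* validation slices get a
deterministic center crop to 160×160.  Slices smaller than the nominal
240×240 are symmetrically zero-padded first, so the LGG path's effective
magnification is the same at every grid scale.  The per-transform
probability 0.5 and the noise fraction are package choices; each augment has
an ablation toggle (`w/o Augment` additionally bypasses the LGG geometry
path, leaving center cropping only).

## Synthetic phantom cohort

The generator emulates the statistical structure the pipeline assumes, not
brain anatomy:

- **Geometry.** Tumors are unions of ellipsoids — one for LGG (radii 4–8 mm)
  and 2–4 overlapping lobes for HGG (radii 9–14 mm each), so HGG tumors are
  larger and more irregular and the shape features are class-informative by
  construction.  The interior is partitioned by depth from the tumor
  boundary: edema (label 2) in the outer 2 mm, enhancing tumor (label 4) in
  the next 2 mm, necrotic core (label 1) deeper — guaranteeing necrosis and
  enhancement in every HGG phantom.
- **Intensities.** Per-modality, per-tissue contrast means on a [0, 1] scale
  chosen to mimic clinical contrast ordering (necrosis T1-dark/T2-bright,
  edema FLAIR-bright, enhancing tumor bright on T1-Gd), plus i.i.d. Gaussian
  noise (sd 0.03).  The source cohorts' intensity distributions are not
  published; these are free parameters, not estimates.
- **Cohort.** Default 14 LGG / 50 HGG (≈1:3.6, the class imbalance of the
  combined source cohorts at desk scale) on a 64×64×48 grid at 1 mm; the
  full 240×240×155 grid is available via `PhantomSpec.full_scale_grid()`.
- **Survival.** Overall survival is exponential with scale 60 months (LGG)
  vs 15 months (HGG) — medians in the clinically realistic range and ordered
  LGG > HGG; censoring probability 0.2.
- **Reproducibility.** One seed per cohort, split per patient by a CRC32
  hash of the patient id, so enlarging a cohort never perturbs existing
  patients.

What the phantoms do **not** model: anatomy, bias fields, motion artifacts,
registration error, scanner effects, non-ellipsoidal infiltrative growth,
and any real correlation between appearance and outcome beyond size/shape.
Passing tests therefore demonstrate that the pipeline's machinery is correct
and that the fusion architecture can exploit a geometric grading signal —
not that the model reaches any particular accuracy on clinical data.

## Survival analysis

Missing overall survival is imputed with a trimmed group mean: sort the
group's observed times, drop the 10 largest and 10 smallest, average the
rest (with ≤20 observations the plain mean is used and loudly logged).  The
Kaplan-Meier estimator is the standard product-limit form with events
processed before censorings at tied times; the two-group log-rank statistic
is (ΣO−E)²/ΣV with a χ²(1) p-value.  Both agree with lifelines to 1e-10 on
random cohorts in the tests.

## Explainability

Heatmaps are gradient-weighted class activation maps: channel weights are
the spatial means of the target logit's gradient on the backbone's last
spatial feature maps; the rectified weighted sum is bilinearly upsampled to
the input size and min-max normalized to [0, 1] (an all-constant map yields
all zeros).  The heatmap algorithm is a package choice — the community
default for CNN attribution.  Models without spatial feature maps (the
features-only classifier) raise a capability error.

## Problem sizes used in tests and the acceptance script

Desk-scale settings keep the full suite within CPU budgets: 12–40 phantom
patients per cohort on the 64×64×48 grid, the `small` backbone (width 8),
3–8 training epochs, one full-scale 240×240×155 phantom for the slice-count
contract.  These sizes are the package's chosen demonstration conditions;
the architecture and all defaults are unchanged at full scale.

## Known limitations

- The headline clinical accuracy of the fusion approach is a property of the
  real UCSF-PDGM/BraTS cohorts and a fully trained 50-layer backbone; it is
  out of scope here and nothing in this package claims it.
- The 2D-diameter vertex-grouping tolerance (half a voxel) is one reasonable
  reading of the feature definitions; no published formula fixes it.
- The numpy network trains on one core; no GPU path.
- The asymmetric LGG geometry pipeline (magnification relative to the center
  crop) can let the CNN use scale as a shortcut on small cohorts; the
  patient-level validation protocol applies the same deterministic transform
  to both classes, so reported metrics are unaffected by the asymmetry.
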