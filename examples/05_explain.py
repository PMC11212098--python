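"""Class-activation heatmap for a trained fusion model.

After training, the gradient-weighted activation map shows where the
backbone looks when calling a slice HGG; on tumor-masked inputs the mass
should sit on the tumor.
"""

import numpy as np

from gliofusion import (PhantomSpec, TrainConfig, activation_heatmap,
                        generate_cohort, train_model, upsample_minority)
from gliofusion.augment import eval_transform
from gliofusion.explain import save_heatmap_png
from gliofusion.preprocess import slice_samples_for_patient
from gliofusion.shape import extract_shape_features

patients, _ = generate_cohort(PhantomSpec(n_lgg=4, n_hgg=8, seed=7))
samples = []
for p in patients:
    features = extract_shape_features(p.mask).to_array()
    samples.extend(slice_samples_for_patient(
        p.volumes, p.mask, p.grade, features, min_tumor_pixels=50))

model, _ = train_model(upsample_minority(samples), TrainConfig(epochs=8, seed=1))

sample = max(samples, key=lambda s: s.tumor_pixels)
heatmap = activation_heatmap(model, sample, target_class=sample.grade)
support = eval_transform(sample.image).max(axis=0) != 0
print(f"slice {sample.axial_index} of {sample.patient_id} ({sample.grade})")
print(f"mean heatmap intensity inside tumor:  {heatmap.values[support].mean():.3f}")
print(f"mean heatmap intensity outside tumor: {heatmap.values[~support].mean():.3f}")
save_heatmap_png(heatmap, eval_transform(sample.image)[0], "heatmap.png")
print("wrote heatmap.png and heatmap_overlay.png")
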