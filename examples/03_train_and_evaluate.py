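"""Train the fusion classifier on phantoms and score a held-out cohort.

The run takes a minute or two on one CPU core: 12 training patients, the
small residual backbone, 3 epochs.  Slice-level softmax outputs are averaged
per patient before any metric is computed.
"""

from gliofusion import (PhantomSpec, TrainConfig, aggregate_by_patient,
                        confusion_and_metrics, generate_cohort, predict_slices,
                        train_model, upsample_minority)
from gliofusion.preprocess import slice_samples_for_patient
from gliofusion.shape import extract_shape_features


def build_samples(patients):
    samples = []
    for p in patients:
        features = extract_shape_features(p.mask).to_array()
        samples.extend(slice_samples_for_patient(
            p.volumes, p.mask, p.grade, features, min_tumor_pixels=50))
    return samples


train_patients, _ = generate_cohort(PhantomSpec(n_lgg=4, n_hgg=8, seed=7))
val_patients, _ = generate_cohort(PhantomSpec(n_lgg=3, n_hgg=5, seed=99))

train_samples = upsample_minority(build_samples(train_patients))
model, log = train_model(train_samples, TrainConfig(epochs=3, seed=1))
print("epoch losses:", [round(l, 4) for l in log["epoch_losses"]])

patients = aggregate_by_patient(predict_slices(model, build_samples(val_patients)))
report = confusion_and_metrics(patients)
print("validation metrics:", report.rounded())
# auc/acc/apca/sen/spe are patient-level; the confusion matrix counts
# patients with HGG as the positive class.
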