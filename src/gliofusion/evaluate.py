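"""Per-patient aggregation and the grading metric suite.

A patient's prediction is the arithmetic mean of their slice-level softmax
pairs; the predicted grade is the argmax with ties resolved toward HGG (the
clinically conservative call).  Metrics are always computed at the patient
level: accuracy, sensitivity (HGG recall — HGG is the positive class),
specificity (LGG recall), APCA = average per-class accuracy = (SEN+SPE)/2
for two classes, and AUC of the HGG mean probability by the rank
(Mann-Whitney) formulation with half-credit for ties, alongside an explicit
ROC threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError, ValidationError
from .model import CLASS_ORDER, SlicePrediction

HGG_INDEX = CLASS_ORDER.index("HGG")


@dataclass
class PatientPrediction:
    patient_id: str
    mean_probabilities: np.ndarray  # (2,), order (LGG, HGG)
    predicted_grade: str
    true_grade: str

    @property
    def hgg_score(self) -> float:
        return float(self.mean_probabilities[HGG_INDEX])


@dataclass
class ConfusionMatrix2x2:
    """Positive class = HGG: tp/fn count HGG patients, fp/tn count LGG."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass
class MetricsReport:
    auc: float | None
    acc: float
    apca: float | None
    sen: float | None
    spe: float | None
    confusion: ConfusionMatrix2x2
    roc_points: list = field(default_factory=list)

    def rounded(self, digits: int = 4) -> dict:
        def r(v):
            return None if v is None else round(float(v), digits)
        return {"auc": r(self.auc), "acc": r(self.acc), "apca": r(self.apca),
                "sen": r(self.sen), "spe": r(self.spe),
                "confusion": self.confusion.to_dict()}


def aggregate_by_patient(slice_predictions: list[SlicePrediction]
                         ) -> list[PatientPrediction]:
    """Mean slice probability pair per patient; argmax ties go to HGG."""
    by_patient: dict[str, list[SlicePrediction]] = {}
    for p in slice_predictions:
        by_patient.setdefault(p.patient_id, []).append(p)
    out = []
    for pid in sorted(by_patient):
        preds = by_patient[pid]
        mean = np.mean([p.probabilities for p in preds], axis=0)
        grades = {p.true_grade for p in preds}
        if len(grades) != 1:
            raise ValidationError(f"patient {pid} has inconsistent grades {grades}")
        predicted = "HGG" if mean[HGG_INDEX] >= mean[1 - HGG_INDEX] else "LGG"
        out.append(PatientPrediction(patient_id=pid, mean_probabilities=mean,
                                     predicted_grade=predicted,
                                     true_grade=grades.pop()))
    return out


def confusion_and_metrics(predictions: list[PatientPrediction]) -> MetricsReport:
    """Threshold metrics from patient-level argmax predictions.

    acc = (tp+tn)/total, sen = tp/(tp+fn), spe = tn/(tn+fp),
    apca = (sen+spe)/2.  A metric whose class is absent is reported as None
    (undefined), never as 0.  AUC is filled in when both classes are present.
    """
    if not predictions:
        raise ValidationError("no predictions to score")
    tp = sum(1 for p in predictions if p.true_grade == "HGG" and p.predicted_grade == "HGG")
    fn = sum(1 for p in predictions if p.true_grade == "HGG" and p.predicted_grade == "LGG")
    tn = sum(1 for p in predictions if p.true_grade == "LGG" and p.predicted_grade == "LGG")
    fp = sum(1 for p in predictions if p.true_grade == "LGG" and p.predicted_grade == "HGG")
    cm = ConfusionMatrix2x2(tp=tp, fn=fn, fp=fp, tn=tn)
    acc = (tp + tn) / cm.total
    sen = tp / (tp + fn) if (tp + fn) > 0 else None
    spe = tn / (tn + fp) if (tn + fp) > 0 else None
    apca = (sen + spe) / 2 if (sen is not None and spe is not None) else None
    auc, roc = (None, [])
    if sen is not None and spe is not None:
        auc, roc = roc_auc(predictions)
    return MetricsReport(auc=auc, acc=acc, apca=apca, sen=sen, spe=spe,
                         confusion=cm, roc_points=roc)


def roc_auc(predictions: list[PatientPrediction]
            ) -> tuple[float, list[tuple[float, float]]]:
    """AUC of the HGG mean probability plus the ROC polyline.

    AUC uses the Mann-Whitney rank statistic with half-credit for ties;
    roc_points sweep thresholds over the unique scores from (0,0) to (1,1),
    each point being (FPR, TPR) for "predict HGG when score >= threshold".
    """
    y = np.array([p.true_grade == "HGG" for p in predictions], dtype=bool)
    scores = np.array([p.hgg_score for p in predictions], dtype=np.float64)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(scores)  # average ranks give ties half credit
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    points = [(0.0, 0.0)]
    for t in np.sort(np.unique(scores))[::-1]:
        call = scores >= t
        tpr = float((call & y).sum() / n_pos)
        fpr = float((call & ~y).sum() / n_neg)
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return float(auc), points


def trapezoidal_auc(roc_points: list[tuple[float, float]]) -> float:
    """Area under the ROC polyline (independent cross-check of the rank AUC)."""
    pts = np.asarray(roc_points, dtype=np.float64)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))
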