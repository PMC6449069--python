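"""Subject-level diagnosis from the two per-eye predictions.

Optic-neuritis status is an eye-level property, so the subject diagnosis is
drawn from the four classes Controls / RIS / CIS / MS.  If both eyes map to
the same subject class, that class is the diagnosis; if they disagree, the
diagnosis follows the eye with the higher mean signal-to-noise ratio (the
better-recorded eye); a single available eye decides by itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError
from .metrics import ConfusionMatrix
from .records import SUBJECT_CLASSES, to_subject_class


@dataclass
class SubjectDiagnosis:
    subject_id: str
    eye_predictions: dict          # eye -> 6-class label
    eye_mean_snr: dict             # eye -> float
    subject_class: str
    rule_used: str                 # agreement | best_snr | single_eye

    def __post_init__(self) -> None:
        if self.subject_class not in SUBJECT_CLASSES:
            raise FormatError(f"invalid subject class {self.subject_class!r}")


def fuse_subject(eye_preds: dict, eye_mean_snr: dict, subject_id: str = "",
                 agreement_on_subject_class: bool = True) -> SubjectDiagnosis:
    """Fuse one subject's per-eye predictions into a 4-class diagnosis.

    ``agreement_on_subject_class`` selects whether agreement is judged after
    merging ON/non-ON (default: CIS-ON and CIS-non-ON count as agreement on
    CIS) or on the raw 6-class labels.  On disagreement the eye with the
    larger mean SNR wins; at exactly equal SNR the right eye (OD) wins.
    """
    if not eye_preds:
        raise FormatError(f"subject {subject_id!r} has no eye predictions")
    if set(eye_preds) - {"OD", "OS"}:
        raise FormatError(f"invalid eye keys {sorted(eye_preds)}")

    if len(eye_preds) == 1:
        eye = next(iter(eye_preds))
        return SubjectDiagnosis(subject_id, dict(eye_preds), dict(eye_mean_snr),
                                to_subject_class(eye_preds[eye]), "single_eye")

    od, osin = eye_preds["OD"], eye_preds["OS"]
    agree = (to_subject_class(od) == to_subject_class(osin)
             if agreement_on_subject_class else od == osin)
    if agree:
        return SubjectDiagnosis(subject_id, dict(eye_preds), dict(eye_mean_snr),
                                to_subject_class(od), "agreement")
    snr_od = eye_mean_snr.get("OD", np.nan)
    snr_os = eye_mean_snr.get("OS", np.nan)
    if not (np.isfinite(snr_od) and np.isfinite(snr_os)):
        raise FormatError(f"subject {subject_id!r}: mean SNR required to break "
                          "a disagreement")
    winner = od if snr_od >= snr_os else osin
    return SubjectDiagnosis(subject_id, dict(eye_preds), dict(eye_mean_snr),
                            to_subject_class(winner), "best_snr")


def fuse_cohort(predictions: pd.DataFrame,
                agreement_on_subject_class: bool = True,
                ) -> tuple[pd.DataFrame, ConfusionMatrix]:
    """Fuse per-eye predictions for a whole cohort.

    ``predictions`` needs columns ``subject_id, eye, label, prediction,
    mean_snr`` (one row per eye, as produced by cross-validation).  Returns
    a per-subject table and the 4-class subject confusion matrix (true
    subject class derived from the eye labels).
    """
    rows = []
    truth, pred = [], []
    for sid, grp in predictions.groupby("subject_id", sort=True):
        eye_preds = dict(zip(grp["eye"], grp["prediction"]))
        eye_snr = dict(zip(grp["eye"], grp["mean_snr"]))
        diag = fuse_subject(eye_preds, eye_snr, subject_id=str(sid),
                            agreement_on_subject_class=agreement_on_subject_class)
        true_classes = {to_subject_class(lbl) for lbl in grp["label"]}
        if len(true_classes) != 1:
            raise FormatError(f"subject {sid}: inconsistent true subject classes")
        truth.append(true_classes.pop())
        pred.append(diag.subject_class)
        rows.append({
            "subject_id": str(sid),
            "true_class": truth[-1],
            "predicted_class": diag.subject_class,
            "rule_used": diag.rule_used,
            "pred_OD": eye_preds.get("OD"),
            "pred_OS": eye_preds.get("OS"),
            "snr_OD": eye_snr.get("OD"),
            "snr_OS": eye_snr.get("OS"),
        })
    cm = ConfusionMatrix.from_predictions(truth, pred, classes=list(SUBJECT_CLASSES))
    return pd.DataFrame(rows), cm
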