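"""Published benchmark confusion matrices for a 192-eye clinical mfVEP cohort.

These matrices summarise 5-fold cross-validated eye classification (flat
multiclass and hierarchical k-NN) and the fused subject diagnosis reported
for a clinical cohort of 44 control, 30 RIS, 62 CIS and 56 MS eyes
(96 subjects).  The raw recordings behind them are not public; the matrices
serve as fixed inputs for validating the metrics module against the
independently reported performance figures (accuracy 0.54 / 0.74 for the
flat and hierarchical eye classifiers, 0.95 for subjects; multiclass
Matthews coefficients 0.43 / 0.68 and 0.93).
"""

from __future__ import annotations

import numpy as np

from .metrics import ConfusionMatrix
from .records import EYE_CLASSES, SUBJECT_CLASSES

#: Flat multiclass eye classifier, rows = true class, cols = predicted.
#: Class order: Controls, RIS, CIS-ON, CIS-non-ON, MS-ON, MS-non-ON.
FMC_EYE_COUNTS = np.array([
    [36, 0, 1, 7, 0, 0],
    [2, 17, 0, 11, 0, 0],
    [1, 0, 1, 9, 2, 0],
    [1, 8, 2, 32, 4, 2],
    [0, 0, 1, 18, 14, 4],
    [0, 3, 1, 5, 6, 4],
])

#: Hierarchical eye classifier, same layout.
HC_EYE_COUNTS = np.array([
    [43, 0, 0, 1, 0, 0],
    [0, 27, 3, 0, 0, 0],
    [0, 0, 6, 7, 0, 0],
    [0, 5, 10, 34, 0, 0],
    [0, 0, 7, 0, 27, 3],
    [0, 0, 1, 0, 13, 5],
])

#: Subject classifier (hierarchical eye predictions fused per subject).
#: Class order: Controls, RIS, CIS, MS.
SUBJECT_COUNTS = np.array([
    [22, 0, 0, 0],
    [0, 14, 1, 0],
    [0, 3, 28, 0],
    [0, 0, 1, 27],
])


def fmc_eye_matrix() -> ConfusionMatrix:
    return ConfusionMatrix(list(EYE_CLASSES), FMC_EYE_COUNTS.copy())


def hc_eye_matrix() -> ConfusionMatrix:
    return ConfusionMatrix(list(EYE_CLASSES), HC_EYE_COUNTS.copy())


def subject_matrix() -> ConfusionMatrix:
    return ConfusionMatrix(list(SUBJECT_CLASSES), SUBJECT_COUNTS.copy())
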