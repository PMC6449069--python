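"""Confusion-matrix algebra, multiclass performance metrics and group statistics.

Per-class metrics use one-vs-rest collapsing of the confusion matrix
(rows = true class, columns = predicted class):

* sensitivity (recall)  = TP / (TP + FN) = cm[c, c] / row-sum
* specificity           = TN / (TN + FP)
* precision             = TP / (TP + FP) = cm[c, c] / column-sum

Overall performance is summarised by accuracy (trace / total) and the
extended (multiclass) Matthews correlation coefficient

    EMCC = (c*s - sum_k p_k t_k) /
           sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

with c the number of correct predictions, s the total, t_k the true and
p_k the predicted counts of class k.  EMCC is +1 for perfect agreement,
~0 for predictions independent of the truth and -1 for total disagreement;
on 2x2 matrices it reduces exactly to the binary Matthews coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Square integer count matrix with class names; rows=true, cols=predicted."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.classes):
            raise ValueError("class list does not match matrix size")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.counts.sum() <= 0:
            raise ValueError("empty confusion matrix")
        self.counts = self.counts.astype(np.int64)

    @classmethod
    def from_predictions(cls, truth, predicted, classes=None) -> "ConfusionMatrix":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        if classes is None:
            classes = sorted(set(truth) | set(predicted))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(truth, predicted):
            counts[index[t], index[p]] += 1
        return cls(list(classes), counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.counts, index=self.classes, columns=self.classes) \
            .to_csv(path, index_label="true\\predicted")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy())


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correct predictions: trace / total."""
    return float(np.trace(cm.counts) / cm.total)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s; reporting 0", what)
        return 0.0
    return num / den


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest sensitivity, specificity and precision per class,
    plus a ``macro`` row of unweighted means."""
    m = cm.counts.astype(float)
    total = m.sum()
    rows = m.sum(axis=1)
    cols = m.sum(axis=0)
    diag = np.diag(m)
    out = {}
    for i, c in enumerate(cm.classes):
        tp = diag[i]
        fn = rows[i] - tp
        fp = cols[i] - tp
        tn = total - tp - fn - fp
        out[c] = {
            "sensitivity": _safe_div(tp, tp + fn, f"sensitivity[{c}]"),
            "specificity": _safe_div(tn, tn + fp, f"specificity[{c}]"),
            "precision": _safe_div(tp, tp + fp, f"precision[{c}]"),
        }
    df = pd.DataFrame(out).T
    df.loc["macro"] = df.mean(axis=0)
    return df


def emcc(cm: ConfusionMatrix) -> float:
    """Extended multiclass Matthews correlation coefficient of the matrix.

    Degenerate margins (all mass in one true or one predicted class) make
    the denominator zero; 0 is returned in that case.
    """
    m = cm.counts.astype(float)
    s = m.sum()
    c = np.trace(m)
    t = m.sum(axis=1)
    p = m.sum(axis=0)
    num = c * s - float(p @ t)
    den = np.sqrt((s * s - float(p @ p)) * (s * s - float(t @ t)))
    if den == 0:
        logger.warning("degenerate confusion matrix margins; EMCC reported as 0")
        return 0.0
    return float(num / den)


@dataclass
class MetricReport:
    """Full evaluation of one confusion matrix."""

    classes: list[str]
    per_class: pd.DataFrame = field(repr=False)
    accuracy: float = 0.0
    emcc: float = 0.0

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "MetricReport":
        return cls(classes=list(cm.classes), per_class=per_class_metrics(cm),
                   accuracy=accuracy(cm), emcc=emcc(cm))

    def to_dict(self, ndigits: int | None = None) -> dict:
        def r(v: float) -> float:
            return round(float(v), ndigits) if ndigits is not None else float(v)
        d = {
            "classes": self.classes,
            "accuracy": r(self.accuracy),
            "emcc": r(self.emcc),
            "per_class": {
                c: {k: r(v) for k, v in row.items()}
                for c, row in self.per_class.iterrows()
            },
        }
        return d


# ---------------------------------------------------------------------------
# group summary statistics
# ---------------------------------------------------------------------------

def group_summary(summaries: pd.DataFrame,
                  params: tuple[str, ...] | None = None,
                  group_col: str = "label") -> pd.DataFrame:
    """Per-group mean (sd) of eye-level parameters plus a one-way ANOVA p-value.

    ``summaries`` is the frame produced by
    :func:`mfvepcad.features.summaries_to_frame`: one row per eye with a
    group label column and one column per parameter.  Returns one row per
    parameter with ``<group>_mean``, ``<group>_sd`` columns and ``anova_p``
    comparing the group means (NaN values are dropped per parameter).
    """
    if params is None:
        params = tuple(c for c in summaries.columns
                       if c not in ("subject_id", "eye", group_col))
    groups = list(dict.fromkeys(summaries[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least two groups for a summary")
    rows = []
    for p in params:
        row: dict = {"parameter": p}
        samples = []
        for g in groups:
            vals = summaries.loc[summaries[group_col] == g, p].dropna().to_numpy()
            row[f"{g}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{g}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            if vals.size >= 2:
                samples.append(vals)
        if len(samples) >= 2:
            if all(np.ptp(s) == 0 for s in samples) and \
                    len({s[0] for s in samples}) == 1:
                row["anova_p"] = 1.0   # identical constant groups
            else:
                row["anova_p"] = float(stats.f_oneway(*samples).pvalue)
        else:
            row["anova_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")
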