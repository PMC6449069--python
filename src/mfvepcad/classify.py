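"""k-nearest-neighbour eye classification: flat multiclass and hierarchical.

The flat multiclass classifier (FMC) is a single 6-class k-NN over the ring
feature vector with σ1..σ4 and k = 1.  The hierarchical classifier (HC)
decomposes the problem into five binary k-NN stages arranged as a tree:

    CLAS1  Controls vs Patients            base features,      k = 1
    CLAS2  RIS vs (CIS + MS)               base + σ4..σ7,      k = 1
    CLAS3  CIS vs MS                       base features,      k = 1
    CLAS4  CIS-ON vs CIS-non-ON            base + σ1..σ3,      k = 1
    CLAS5  MS-ON vs MS-non-ON              base + σ1..σ3,      k = 10

"base features" are the 24 ring parameters (mean SNR, NAS count and the two
latencies per ring).  Each stage trains on the training eyes belonging to
its two super-classes (ground-truth routing) and test eyes are routed down
the tree by the stage predictions.

Distances are Euclidean on per-feature z-scored values (train-fold mean/sd);
features constant in a training fold are dropped from the distance.  Voting
ties are broken by the class of the nearest neighbour among the tied
classes, and distance ties by training-row order, so predictions are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import EyeFeatures, select_feature_indices
from .metrics import ConfusionMatrix
from .records import EYE_CLASSES, to_subject_class

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# core k-NN
# ---------------------------------------------------------------------------

@dataclass
class KnnModel:
    """Stored training set with standardisation parameters."""

    X: np.ndarray            # (M, d) standardized training vectors
    labels: np.ndarray       # (M,) class labels
    k: int
    feature_indices: np.ndarray   # original vector positions used
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray         # boolean mask over feature_indices (sd > 0)


def knn_fit(features: np.ndarray, labels, k: int | str = 1,
            feature_indices=None) -> KnnModel:
    """Store (standardised) training vectors for k-NN prediction.

    ``k`` may be an integer or ``"all"`` (every training row votes).
    Features whose training standard deviation is zero carry no distance
    information and are dropped with a warning.
    """
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise ValueError("features must be (M, d) with one label per row")
    M = X.shape[0]
    if M == 0:
        raise ValueError("empty training set")
    if isinstance(k, str):
        if k.lower() != "all":
            raise ValueError(f"k must be a positive integer or 'all', got {k!r}")
        k = M
    k = int(k)
    if not (1 <= k <= M):
        raise ValueError(f"k={k} out of range for M={M} training rows")
    idx = np.arange(X.shape[1]) if feature_indices is None \
        else np.asarray(feature_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("feature_indices must be nonempty")
    Xs = X[:, idx]
    mean = Xs.mean(axis=0)
    sd = Xs.std(axis=0, ddof=0)
    kept = sd > 0
    if not kept.any():
        raise ValueError("all selected features are constant in the training set")
    if not kept.all():
        logger.warning("dropping %d constant feature(s) from k-NN distance",
                       int((~kept).sum()))
    Z = (Xs[:, kept] - mean[kept]) / sd[kept]
    return KnnModel(X=Z, labels=labels, k=k, feature_indices=idx,
                    mean=mean, sd=sd, kept=kept)


def _standardize_query(model: KnnModel, Q: np.ndarray) -> np.ndarray:
    Qs = Q[:, model.feature_indices]
    return (Qs[:, model.kept] - model.mean[model.kept]) / model.sd[model.kept]


def knn_predict(model: KnnModel, query: np.ndarray):
    """Predict one query vector (full, un-restricted dimension)."""
    return knn_predict_many(model, np.asarray(query, dtype=np.float64)[None, :])[0]


def knn_predict_many(model: KnnModel, queries: np.ndarray) -> np.ndarray:
    """Majority vote among the k nearest training rows for each query.

    Vote ties are resolved in favour of the tied class containing the single
    nearest neighbour; equal distances rank by training-row order.
    """
    Q = np.asarray(queries, dtype=np.float64)
    if Q.ndim != 2:
        raise ValueError("queries must be 2-D")
    Z = _standardize_query(model, Q)
    d2 = np.sum((Z[:, None, :] - model.X[None, :, :]) ** 2, axis=2)
    order = np.argsort(d2, axis=1, kind="stable")   # row order breaks distance ties
    out = []
    for row in order:
        nn = model.labels[row[:model.k]]
        classes, counts = np.unique(nn, return_counts=True)
        top = classes[counts == counts.max()]
        if top.size == 1:
            out.append(top[0])
        else:
            tied = set(top.tolist())
            winner = next(lbl for lbl in nn if lbl in tied)
            out.append(winner)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# eye classifiers
# ---------------------------------------------------------------------------

def _matrix(feats: list[EyeFeatures]) -> tuple[np.ndarray, np.ndarray, int]:
    X = np.stack([f.values for f in feats])
    y = np.asarray([f.label for f in feats])
    return X, y, feats[0].i_sv


def fmc_classify(train: list[EyeFeatures], test: list[EyeFeatures],
                 sv_subset: tuple[int, ...] = (1, 2, 3, 4),
                 k: int | str = 1) -> np.ndarray:
    """Flat multiclass classification: one 6-class k-NN over base + σ subset."""
    Xtr, ytr, i_sv = _matrix(train)
    Xte, _, i_te = _matrix(test)
    if i_te != i_sv:
        raise ValueError("train and test feature vectors use different i_sv")
    missing = set(EYE_CLASSES) - set(ytr)
    if missing:
        logger.warning("training folds missing classes %s; prediction proceeds",
                       sorted(missing))
    idx = select_feature_indices(i_sv, sv_subset)
    model = knn_fit(Xtr, ytr, k=k, feature_indices=idx)
    return knn_predict_many(model, Xte)


@dataclass(frozen=True)
class StageSpec:
    """One binary k-NN stage of the hierarchical classifier."""

    name: str
    sv_subset: tuple[int, ...]
    k: int | str


@dataclass(frozen=True)
class HierarchySpec:
    clas1: StageSpec = StageSpec("Controls vs Patients", (), 1)
    clas2: StageSpec = StageSpec("RIS vs CIS+MS", (4, 5, 6, 7), 1)
    clas3: StageSpec = StageSpec("CIS vs MS", (), 1)
    clas4: StageSpec = StageSpec("CIS-ON vs CIS-non-ON", (1, 2, 3), 1)
    clas5: StageSpec = StageSpec("MS-ON vs MS-non-ON", (1, 2, 3), 10)


def default_hierarchy() -> HierarchySpec:
    return HierarchySpec()


def _stage_predict(stage: StageSpec, Xtr, groups_tr, Xte, i_sv) -> np.ndarray:
    """Binary stage; degenerates to the single present class if one side is empty.

    The stage's σ subset is intersected with the σ values the feature
    vectors actually carry, and k is clamped to the stage's training size,
    so small folds degrade gracefully instead of failing.
    """
    present = np.unique(groups_tr)
    if present.size == 0:
        raise ValueError(f"stage {stage.name!r} has an empty training set")
    if present.size == 1:
        logger.warning("stage %r trained with a single class %s", stage.name, present[0])
        return np.full(Xte.shape[0], present[0])
    subset = tuple(k for k in stage.sv_subset if 1 <= k <= i_sv)
    if subset != tuple(stage.sv_subset):
        logger.warning("stage %r: σ subset %s reduced to %s (i_sv=%d)",
                       stage.name, stage.sv_subset, subset, i_sv)
    k = stage.k
    if isinstance(k, int) and k > Xtr.shape[0]:
        logger.warning("stage %r: k=%d clamped to %d training rows",
                       stage.name, k, Xtr.shape[0])
        k = Xtr.shape[0]
    idx = select_feature_indices(i_sv, subset)
    model = knn_fit(Xtr, groups_tr, k=k, feature_indices=idx)
    return knn_predict_many(model, Xte)


def hc_classify(train: list[EyeFeatures], test: list[EyeFeatures],
                spec: HierarchySpec | None = None) -> np.ndarray:
    """Route test eyes down the five-stage binary tree.

    Stage training sets are selected by ground-truth super-class; test eyes
    follow the stage predictions.  Downstream stages can therefore never
    output ``Controls`` for an eye that passed stage 1 as a patient.
    """
    spec = spec or HierarchySpec()
    Xtr, ytr, i_sv = _matrix(train)
    Xte, _, i_te = _matrix(test)
    if i_te != i_sv:
        raise ValueError("train and test feature vectors use different i_sv")
    n = Xte.shape[0]
    pred = np.empty(n, dtype=object)

    # CLAS1: Controls vs Patients, on all training eyes
    g1 = np.where(ytr == "Controls", "Controls", "Patients")
    p1 = _stage_predict(spec.clas1, Xtr, g1, Xte, i_sv)
    pred[p1 == "Controls"] = "Controls"
    down = p1 == "Patients"

    # CLAS2: RIS vs CIS+MS, trained on patient eyes
    pat = ytr != "Controls"
    if down.any():
        g2 = np.where(ytr[pat] == "RIS", "RIS", "CIS+MS")
        p2 = _stage_predict(spec.clas2, Xtr[pat], g2, Xte[down], i_sv)
        idx_down = np.flatnonzero(down)
        pred[idx_down[p2 == "RIS"]] = "RIS"
        cisms = idx_down[p2 == "CIS+MS"]
    else:
        cisms = np.array([], dtype=int)

    # CLAS3: CIS vs MS
    tr3 = np.isin(ytr, ("CIS-ON", "CIS-non-ON", "MS-ON", "MS-non-ON"))
    if cisms.size:
        g3 = np.asarray([to_subject_class(lbl) for lbl in ytr[tr3]])
        p3 = _stage_predict(spec.clas3, Xtr[tr3], g3, Xte[cisms], i_sv)
        cis_idx = cisms[p3 == "CIS"]
        ms_idx = cisms[p3 == "MS"]
    else:
        cis_idx = ms_idx = np.array([], dtype=int)

    # CLAS4 / CLAS5: ON vs non-ON within CIS and within MS
    for idx_te, stage, classes in (
            (cis_idx, spec.clas4, ("CIS-ON", "CIS-non-ON")),
            (ms_idx, spec.clas5, ("MS-ON", "MS-non-ON"))):
        if not idx_te.size:
            continue
        tr_mask = np.isin(ytr, classes)
        p = _stage_predict(stage, Xtr[tr_mask], ytr[tr_mask], Xte[idx_te], i_sv)
        pred[idx_te] = p

    assert not any(p is None for p in pred)
    return pred.astype(str)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvPlan:
    """Fold assignment for every eye (parallel to the feature list)."""

    n_folds: int
    fold_of: np.ndarray
    seed: int
    stratified: bool = True
    grouped_by_subject: bool = True


def make_cv_plan(feats: list[EyeFeatures], n_folds: int = 5, seed: int = 0,
                 group_by_subject: bool = True) -> CvPlan:
    """Stratified fold assignment.

    By default both eyes of a subject are kept in the same fold (stratifying
    on the subject class) to avoid fellow-eye leakage; with
    ``group_by_subject=False`` eyes are assigned independently, stratified
    on the 6-level eye class.  Classes with fewer members than folds trigger
    a fall back to unstratified assignment with a warning.
    """
    rng = np.random.default_rng(seed)
    n = len(feats)
    fold_of = np.full(n, -1, dtype=int)

    if group_by_subject:
        subjects = {}
        for i, f in enumerate(feats):
            subjects.setdefault(f.subject_id, {"class": f.subject_class, "rows": []})
            subjects[f.subject_id]["rows"].append(i)
        sids = sorted(subjects)
        strata = {}
        for sid in sids:
            strata.setdefault(subjects[sid]["class"], []).append(sid)
        stratified = all(len(v) >= n_folds for v in strata.values())
        if not stratified:
            logger.warning("a subject class has fewer members than folds; "
                           "falling back to unstratified assignment")
            strata = {"all": list(sids)}
        assign = {}
        for members in strata.values():
            members = list(members)
            rng.shuffle(members)
            for j, sid in enumerate(members):
                assign[sid] = j % n_folds
        for sid, info in subjects.items():
            for i in info["rows"]:
                fold_of[i] = assign[sid]
        return CvPlan(n_folds, fold_of, seed, stratified, True)

    labels = np.asarray([f.label for f in feats])
    strata = {}
    for i, lbl in enumerate(labels):
        strata.setdefault(lbl, []).append(i)
    stratified = all(len(v) >= n_folds for v in strata.values())
    if not stratified:
        logger.warning("a class has fewer members than folds; "
                       "falling back to unstratified assignment")
        strata = {"all": list(range(n))}
    for members in strata.values():
        members = list(members)
        rng.shuffle(members)
        for j, i in enumerate(members):
            fold_of[i] = j % n_folds
    return CvPlan(n_folds, fold_of, seed, stratified, False)


def cross_validate(feats: list[EyeFeatures], classifier: str = "hc",
                   plan: CvPlan | None = None, n_folds: int = 5, seed: int = 0,
                   group_by_subject: bool = True,
                   spec: HierarchySpec | None = None,
                   fmc_sv: tuple[int, ...] = (1, 2, 3, 4), fmc_k: int | str = 1,
                   ) -> tuple[ConfusionMatrix, pd.DataFrame]:
    """k-fold cross-validation of an eye classifier.

    Every eye is validated exactly once; the returned 6-class confusion
    matrix has row sums equal to the true class counts.  ``classifier`` is
    ``"hc"``, ``"fmc"`` or a callable ``(train, test) -> predictions``.
    """
    if plan is None:
        plan = make_cv_plan(feats, n_folds=n_folds, seed=seed,
                            group_by_subject=group_by_subject)
    if callable(classifier):
        run = classifier
    elif classifier == "hc":
        run = lambda tr, te: hc_classify(tr, te, spec=spec)  # noqa: E731
    elif classifier == "fmc":
        run = lambda tr, te: fmc_classify(tr, te, sv_subset=fmc_sv, k=fmc_k)  # noqa: E731
    else:
        raise ValueError(f"unknown classifier {classifier!r}")

    n = len(feats)
    preds = np.empty(n, dtype=object)
    for fold in range(plan.n_folds):
        te_idx = np.flatnonzero(plan.fold_of == fold)
        tr_idx = np.flatnonzero(plan.fold_of != fold)
        if not te_idx.size:
            continue
        preds[te_idx] = run([feats[i] for i in tr_idx], [feats[i] for i in te_idx])
    assert not any(p is None for p in preds), "every eye must be predicted once"

    truth = [f.label for f in feats]
    cm = ConfusionMatrix.from_predictions(truth, preds.astype(str),
                                          classes=list(EYE_CLASSES))
    table = pd.DataFrame({
        "subject_id": [f.subject_id for f in feats],
        "eye": [f.eye for f in feats],
        "label": truth,
        "prediction": preds.astype(str),
        "fold": plan.fold_of,
        "mean_snr": [f.mean_snr for f in feats],
    })
    return cm, table
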