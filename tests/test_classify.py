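"""From-scratch k-NN, flat and hierarchical eye classifiers, cross-validation."""

import numpy as np
import pytest

import mfvepcad as m
from mfvepcad.classify import make_cv_plan

from conftest import make_features


class TestKnnCore:
    def test_k_all_resolves_to_training_size(self):
        X = np.arange(6, dtype=float).reshape(3, 2)
        model = m.knn_fit(X, ["A", "B", "A"], k="all")
        assert model.k == 3

    def test_self_prediction_k1(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 4))
        y = rng.choice(list("ABC"), size=25)
        model = m.knn_fit(X, y, k=1)
        assert np.array_equal(m.knn_predict_many(model, X), y)

    def test_small_instance_brute_force(self):
        # {(0,0):A, (1,0):A, (5,0):B}, query (0.4, 0), k=3 -> majority A
        X = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        model = m.knn_fit(X, ["A", "A", "B"], k=3)
        assert m.knn_predict(model, np.array([0.4, 0.0])) == "A"

    def test_constant_feature_dropped(self, caplog):
        X = np.array([[0.0, 7.0], [1.0, 7.0], [5.0, 7.0]])
        with caplog.at_level("WARNING"):
            model = m.knn_fit(X, ["A", "A", "B"], k=1)
        assert model.kept.sum() == 1
        assert m.knn_predict(model, np.array([4.9, -100.0])) == "B"

    def test_oracle_equivalence_scikit_learn(self):
        """Predictions match an independent exhaustive-search implementation
        on >=100 random instances (continuous data: ties have measure zero)."""
        from sklearn.neighbors import KNeighborsClassifier
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(120):
            M = int(rng.integers(6, 50))
            d = int(rng.integers(2, 8))
            k = int(rng.choice([1, 3, 5]))
            X = rng.normal(size=(M, d))
            y = rng.choice(["A", "B"], size=M)
            Q = rng.normal(size=(8, d))
            mine = m.knn_predict_many(m.knn_fit(X, y, k=k), Q)
            mu, sd = X.mean(0), X.std(0)
            oracle = KNeighborsClassifier(n_neighbors=k) \
                .fit((X - mu) / sd, y).predict((Q - mu) / sd)
            assert np.array_equal(mine, oracle)
            checked += len(Q)
        assert checked >= 100

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = rng.choice(["A", "B", "C"], size=30)
        Q = rng.normal(size=(12, 5))
        base = m.knn_predict_many(m.knn_fit(X, y, k=3), Q)
        X2, Q2 = X.copy(), Q.copy()
        X2[:, 2] = 1e3 * X2[:, 2] - 40.0
        Q2[:, 2] = 1e3 * Q2[:, 2] - 40.0
        assert np.array_equal(m.knn_predict_many(m.knn_fit(X2, y, k=3), Q2), base)

    def test_vote_tie_broken_by_nearest(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["A", "A", "B", "B"])
        model = m.knn_fit(X, y, k=4)
        assert m.knn_predict(model, np.array([2.0])) == "A"
        assert m.knn_predict(model, np.array([9.0])) == "B"

    @pytest.mark.parametrize("k", [0, 5, "some"])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            m.knn_fit(np.zeros((3, 2)) + np.arange(3)[:, None], list("ABA"), k=k)


def _toy_cohort(rng, n_per_class=8, spread=0.3):
    """Six well-separated clusters wrapped as EyeFeatures (i_sv=0).

    Every feature is informative (distinct class centres on all 24
    coordinates), so the separation survives per-feature standardisation.
    """
    centres = np.random.default_rng(99).normal(0.0, 10.0,
                                               size=(len(m.EYE_CLASSES), 24))
    feats = []
    for ci, label in enumerate(m.EYE_CLASSES):
        for j in range(n_per_class):
            vec = centres[ci] + spread * rng.normal(size=24)
            sid = f"{label}-{j // 2}"
            eye = "OD" if j % 2 == 0 else "OS"
            feats.append(make_features(sid, eye, label, vec))
    return feats


class TestEyeClassifiers:
    def test_fmc_self_classification_perfect(self):
        feats = _toy_cohort(np.random.default_rng(3))
        pred = m.fmc_classify(feats, feats, sv_subset=(), k=1)
        assert np.array_equal(pred, [f.label for f in feats])

    def test_hc_self_classification_perfect(self):
        feats = _toy_cohort(np.random.default_rng(4))
        pred = m.hc_classify(feats, feats)
        assert np.array_equal(pred, [f.label for f in feats])

    def test_hc_controls_only_from_stage_one(self):
        """Downstream stages never output Controls: a test eye is labelled
        Controls exactly when the Controls-vs-Patients stage routes it there."""
        rng = np.random.default_rng(5)
        train = _toy_cohort(rng)
        test = _toy_cohort(rng, n_per_class=4, spread=3.0)  # noisy queries
        pred = m.hc_classify(train, test)
        # replicate stage 1 with the public k-NN API
        Xtr = np.stack([f.values for f in train])
        g1 = np.where(np.asarray([f.label for f in train]) == "Controls",
                      "Controls", "Patients")
        stage1 = m.knn_predict_many(m.knn_fit(Xtr, g1, k=1),
                                    np.stack([f.values for f in test]))
        assert np.array_equal(pred == "Controls", stage1 == "Controls")

    def test_exaggerated_cohort_high_accuracy(self, exaggerated_cohort):
        _, feats = exaggerated_cohort
        cm_fmc, _ = m.cross_validate(feats, classifier="fmc", seed=2)
        cm_hc, _ = m.cross_validate(feats, classifier="hc", seed=2)
        assert m.accuracy(cm_fmc) > 0.9
        assert m.accuracy(cm_hc) >= m.accuracy(cm_fmc) - 0.05

    def test_mismatched_i_sv_rejected(self):
        rng = np.random.default_rng(6)
        a = _toy_cohort(rng)
        b = [make_features("x", "OD", "RIS", np.zeros(30), i_sv=1)]
        with pytest.raises(ValueError):
            m.fmc_classify(a, b, sv_subset=())


class TestCrossValidation:
    def test_partition_and_row_sums(self, cohort30):
        _, feats = cohort30
        cm, preds = m.cross_validate(feats, classifier="fmc", seed=3)
        assert cm.total == len(feats)
        truth = np.asarray([f.label for f in feats])
        for i, c in enumerate(cm.classes):
            assert cm.counts[i].sum() == np.sum(truth == c)
        assert len(preds) == len(feats)

    def test_same_seed_same_folds_and_matrix(self, cohort30):
        _, feats = cohort30
        cm1, p1 = m.cross_validate(feats, classifier="fmc", seed=11)
        cm2, p2 = m.cross_validate(feats, classifier="fmc", seed=11)
        assert np.array_equal(cm1.counts, cm2.counts)
        assert p1.equals(p2)

    def test_fellow_eyes_share_folds_by_default(self, cohort30):
        _, feats = cohort30
        plan = make_cv_plan(feats, n_folds=5, seed=0, group_by_subject=True)
        folds = {}
        for f, fold in zip(feats, plan.fold_of):
            folds.setdefault(f.subject_id, set()).add(int(fold))
        assert all(len(v) == 1 for v in folds.values())

    def test_leave_one_out_separable(self):
        feats = _toy_cohort(np.random.default_rng(7), n_per_class=3,
                            spread=0.05)
        cm, _ = m.cross_validate(feats, classifier="fmc", n_folds=len(feats),
                                 seed=0, group_by_subject=False, fmc_sv=())
        assert m.accuracy(cm) == 1.0

    def test_unstratified_fallback_warns(self, caplog):
        feats = _toy_cohort(np.random.default_rng(8), n_per_class=2)
        with caplog.at_level("WARNING"):
            make_cv_plan(feats, n_folds=5, seed=0, group_by_subject=True)
        assert any("unstratified" in r.message for r in caplog.records)
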