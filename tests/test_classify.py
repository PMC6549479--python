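"""SVM optimality, one-vs-one voting, LOSO fold structure and
confusion-matrix metrics (dense-QP and hand-formula oracles)."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from drivestyle.classify import (
    classification_report,
    confusion_matrix,
    loso_cross_validate,
    loso_fold_plan,
    predict_ovo,
    train_ovo,
    train_svm_binary,
)
from drivestyle.features import FEATURE_NAMES


def _qp_oracle_objective(X, y, C):
    """Reference dual solution via SLSQP on the full quadratic program."""
    n = len(y)
    Q = (X * y[:, None]) @ (X * y[:, None]).T
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1,
        bounds=[(0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    w = X.T @ (res.x * y)
    return 0.5 * w @ w


class TestBinarySVM:
    def test_symmetric_two_point_problem(self):
        m = train_svm_binary(np.array([[-1.0, 0.0], [1.0, 0.0]]),
                             np.array([-1.0, 1.0]), C=1e8)
        assert np.allclose(m.w, [1.0, 0.0], atol=1e-9)
        assert m.b == pytest.approx(0.0, abs=1e-9)
        assert m.margin == pytest.approx(2.0, rel=1e-9)

    def test_kkt_conditions_at_convergence(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=30) > 0, 1.0, -1.0)
        C = 5.0
        m = train_svm_binary(X, y, C=C)
        assert ((m.alpha >= -1e-9) & (m.alpha <= C + 1e-9)).all()
        assert m.alpha @ y == pytest.approx(0.0, abs=1e-8)
        margins = y * m.decision_function(X)
        on_margin = (m.alpha > 1e-6) & (m.alpha < C - 1e-6)
        assert np.allclose(margins[on_margin], 1.0, atol=1e-6)
        assert m.duality_gap < 1e-6

    @pytest.mark.parametrize("trial", range(4))
    def test_objective_matches_dense_qp_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = 16
        X = rng.normal(size=(n, 2))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1.0, -1.0)
        X[:, 0] += y * 1.5                      # make separable
        C = 1e4
        m = train_svm_binary(X, y, C=C)
        ours = 0.5 * m.w @ m.w
        oracle = _qp_oracle_objective(X, y, C)
        assert ours == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_duplicating_non_support_vector_changes_nothing(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        X[:, 0] += y * 2.0
        m = train_svm_binary(X, y, C=1e8)
        far = int(np.argmax(y * m.decision_function(X)))   # deep inside its class
        X2 = np.vstack([X, X[far]])
        y2 = np.append(y, y[far])
        m2 = train_svm_binary(X2, y2, C=1e8)
        assert np.allclose(m.w, m2.w, atol=1e-6)
        assert m.b == pytest.approx(m2.b, abs=1e-6)

    def test_feature_scaling_law_hard_margin(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        X[:, 0] += y * 2.0
        m1 = train_svm_binary(X, y, C=1e8)
        m2 = train_svm_binary(3.0 * X, y, C=1e8)
        assert np.linalg.norm(m2.w) == pytest.approx(np.linalg.norm(m1.w) / 3.0, rel=1e-5)
        assert np.array_equal(m1.predict(X), m2.predict(3.0 * X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            train_svm_binary(np.eye(3), np.ones(3))


class TestOVO:
    def _blobs(self, rng, sep=6.0):
        centers = np.array([[0.0, 0.0], [sep, 0.0], [0.0, sep]])
        X = np.vstack([rng.normal(size=(12, 2)) * 0.4 + c for c in centers])
        y = np.repeat(["a", "b", "c"], 12)
        return X, y, centers

    def test_blob_centers_classified_to_own_blob(self, rng):
        X, y, centers = self._blobs(rng)
        ens = train_ovo(X, y, C=10.0)
        assert list(predict_ovo(ens, centers)) == ["a", "b", "c"]

    def test_unanimous_vote_wins(self, rng):
        X, y, centers = self._blobs(rng)
        ens = train_ovo(X, y, C=10.0)
        probe = centers[1] + np.array([0.5, -0.2])
        for (neg, pos), m in ens.models.items():
            if "b" in (neg, pos):
                pred = pos if m.decision_function(probe[None])[0] >= 0 else neg
                assert pred == "b"
        assert predict_ovo(ens, probe[None])[0] == "b"

    def test_vote_cycle_broken_deterministically(self):
        """A constructed 1-1-1 cycle resolves identically across calls."""
        from drivestyle.classify import OVOEnsemble, SVMBinaryModel

        def fixed(neg, pos, w, b):
            return SVMBinaryModel(w=np.array(w), b=b, C=1.0,
                                  alpha=np.zeros(1), support_indices=np.array([]),
                                  classes=(neg, pos), duality_gap=0.0, converged=True)

        ens = OVOEnsemble(classes=("a", "b", "c"))
        ens.models[("a", "b")] = fixed("a", "b", [1.0, 0.0], 0.0)   # votes b at x>0
        ens.models[("b", "c")] = fixed("b", "c", [2.0, 0.0], 0.0)   # votes c, strongly
        ens.models[("a", "c")] = fixed("a", "c", [-1.0, 0.0], 0.0)  # votes a
        x = np.array([[0.5, 0.0]])
        first = predict_ovo(ens, x)[0]
        assert all(predict_ovo(ens, x)[0] == first for _ in range(5))
        # signed-score sums over the 1-1-1 cycle: a = 0, b = -0.5, c = +0.5
        assert first == "c"

    def test_untrained_ensemble_rejected(self):
        from drivestyle.classify import OVOEnsemble

        with pytest.raises(ValueError, match="trained"):
            predict_ovo(OVOEnsemble(classes=("a", "b")), np.zeros((1, 2)))


def _feature_frame(rng, n_subjects=8, tasks_per=3, sep=4.0):
    rows = []
    styles = ["Aggressive", "Moderate", "Conservative"]
    shift = {"Aggressive": 0.0, "Moderate": sep, "Conservative": 2 * sep}
    tid = 0
    for s in range(n_subjects):
        style = styles[s % 3]
        for _ in range(tasks_per):
            feats = rng.normal(size=8)
            feats[0] += shift[style]
            rows.append({"task_id": tid, "subject_id": s,
                         **dict(zip(FEATURE_NAMES, feats)), "label": style})
            tid += 1
    return pd.DataFrame(rows)


class TestLOSO:
    def test_one_fold_per_subject_partitioning_tasks(self, rng):
        feats = _feature_frame(rng)
        plan = loso_fold_plan(feats)
        assert len(plan.folds) == 8
        all_test = [t for _, _, test in plan.folds for t in test]
        assert sorted(all_test) == sorted(feats["task_id"])
        for subject, train, test in plan.folds:
            assert set(train).isdisjoint(test)
            assert (feats.set_index("task_id").loc[list(test), "subject_id"] == subject).all()

    def test_pooled_confusion_total_equals_task_count(self, rng):
        feats = _feature_frame(rng)
        res = loso_cross_validate(feats, C=10.0, lda_scope="fold")
        assert res.report.confusion.to_numpy().sum() == len(feats)

    def test_separable_features_classified_well(self, rng):
        feats = _feature_frame(rng, sep=6.0)
        res = loso_cross_validate(feats, C=10.0, lda_scope="fold")
        assert res.report.accuracy > 0.9

    def test_fold_order_invariance(self, rng):
        feats = _feature_frame(rng)
        shuffled = feats.sample(frac=1.0, random_state=5).reset_index(drop=True)
        r1 = loso_cross_validate(feats, C=10.0)
        r2 = loso_cross_validate(shuffled, C=10.0)
        pd.testing.assert_frame_equal(r1.report.confusion, r2.report.confusion)


class TestReport:
    def test_published_style_confusion_matrix_metrics(self):
        """The 75-task confusion matrix with rows (15,2,1),(3,21,6),(1,2,24)
        yields 80.0% accuracy, precisions 83.3/70.0/88.9, recalls
        78.9/84.0/77.4 and F 76.4 (Moderate), 82.8 (Conservative)."""
        cm = pd.DataFrame([[15, 2, 1], [3, 21, 6], [1, 2, 24]],
                          index=["Aggressive", "Moderate", "Conservative"],
                          columns=["Aggressive", "Moderate", "Conservative"])
        rep = classification_report(cm)
        assert rep.as_percent(rep.accuracy) == 80.0
        assert [rep.as_percent(rep.precision[c]) for c in cm.index] == [83.3, 70.0, 88.9]
        assert [rep.as_percent(rep.recall[c]) for c in cm.index] == [78.9, 84.0, 77.4]
        assert rep.as_percent(rep.f_measure["Moderate"]) == 76.4
        assert rep.as_percent(rep.f_measure["Conservative"]) == 82.8
        # the Aggressive F from unrounded precision/recall
        assert rep.as_percent(rep.f_measure["Aggressive"]) == 81.1

    def test_identity_matrix_is_perfect(self):
        cm = pd.DataFrame(np.eye(3, dtype=int) * 5, index=list("abc"), columns=list("abc"))
        rep = classification_report(cm)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.precision.values())
        assert all(v == 1.0 for v in rep.f_measure.values())

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matrices_match_hand_formulas(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.integers(1, 20, size=(3, 3))
        cm = pd.DataFrame(M, index=list("abc"), columns=list("abc"))
        rep = classification_report(cm)
        assert rep.accuracy == pytest.approx(np.trace(M) / M.sum())
        for i, c in enumerate("abc"):
            assert rep.precision[c] == pytest.approx(M[i, i] / M[i, :].sum())
            assert rep.recall[c] == pytest.approx(M[i, i] / M[:, i].sum())
            p, r = rep.precision[c], rep.recall[c]
            assert rep.f_measure[c] == pytest.approx(2 * p * r / (p + r))

    def test_zero_column_flagged_undefined_not_nan(self):
        cm = pd.DataFrame([[3, 0, 1], [0, 0, 0], [1, 0, 2]],
                          index=list("abc"), columns=list("abc"))
        rep = classification_report(cm)
        assert rep.recall["b"] is None
        assert rep.precision["b"] is None
        assert rep.f_measure["b"] is None
        assert rep.accuracy == pytest.approx(5 / 7)
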