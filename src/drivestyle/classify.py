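"""Linear soft-margin SVM, one-vs-one multiclass voting and
leave-one-subject-out evaluation.

The binary SVM maximises the margin 2/||W|| between the supporting
hyperplanes W.S + b = +/-1, softened by hinge slack with box parameter
C. The dual is solved by SMO-style pairwise coordinate ascent on the
alpha variables (linear kernel); W = sum_i alpha_i y_i S_i and b comes
from support-vector complementarity. Multiclass prediction trains one
binary model per unordered class pair and takes the majority vote, with
ties broken by the largest sum of signed decision values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import STYLES
from .features import FEATURE_NAMES, lda_reduce


# --------------------------------------------------------------------------
# binary SVM via SMO
# --------------------------------------------------------------------------

@dataclass
class SVMBinaryModel:
    w: np.ndarray
    b: float
    C: float
    alpha: np.ndarray
    support_indices: np.ndarray
    classes: tuple            # (negative class, positive class)
    duality_gap: float
    converged: bool

    @property
    def margin(self) -> float:
        return 2.0 / float(np.linalg.norm(self.w))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        neg, pos = self.classes
        return np.where(self.decision_function(X) >= 0, pos, neg)


def _smo(K: np.ndarray, y: np.ndarray, C: float, tol: float,
         max_sweeps: int) -> tuple[np.ndarray, bool]:
    """Most-violating-pair coordinate ascent on the SVM dual.

    Maximises sum(alpha) - 0.5 aQa (Q_ij = y_i y_j K_ij) subject to
    0 <= alpha <= C and sum(alpha * y) = 0. At each step the pair
    (i, j) with the largest KKT violation v_i - v_j (v = y - f,
    f_i = sum_j alpha_j y_j K_ij) moves along the equality-feasible
    direction by the analytic step, clipped to the box.
    """
    n = len(y)
    alpha = np.zeros(n)
    f = np.zeros(n)
    eps = 1e-12
    for _ in range(max_sweeps):
        v = y - f
        up = ((y == 1) & (alpha < C - eps)) | ((y == -1) & (alpha > eps))
        lo = ((y == -1) & (alpha < C - eps)) | ((y == 1) & (alpha > eps))
        if not up.any() or not lo.any():
            return alpha, True
        i = int(np.argmax(np.where(up, v, -np.inf)))
        j = int(np.argmin(np.where(lo, v, np.inf)))
        if v[i] - v[j] < tol:
            return alpha, True
        eta = max(K[i, i] + K[j, j] - 2 * K[i, j], 1e-18)
        t = (v[i] - v[j]) / eta
        # alpha_i moves by +y_i t, alpha_j by -y_j t; keep both in [0, C]
        t_hi = min(C - alpha[i] if y[i] == 1 else alpha[i],
                   alpha[j] if y[j] == 1 else C - alpha[j])
        t = min(t, t_hi)
        if t <= 0:
            return alpha, True
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        f += t * (K[:, i] - K[:, j])
    return alpha, False


def train_svm_binary(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                     tol: float = 1e-9, max_sweeps: int = 200000,
                     classes: tuple = (-1, 1)) -> SVMBinaryModel:
    """Fit the linear soft-margin SVM dual by SMO coordinate ascent.

    ``y`` must be +/-1. Hard-margin behaviour is recovered with large C.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("both classes (+1/-1) must be present")
    K = X @ X.T
    alpha, converged = _smo(K, y, C, tol, max_sweeps)
    w = X.T @ (alpha * y)
    sv = np.flatnonzero(alpha > 1e-10)
    on_margin = np.flatnonzero((alpha > 1e-8) & (alpha < C - 1e-8))
    idx = on_margin if len(on_margin) else sv
    b = float(np.mean(y[idx] - X[idx] @ w)) if len(idx) else 0.0

    # duality gap: primal (with hinge slack) minus dual objective
    margins = y * (X @ w + b)
    primal = 0.5 * w @ w + C * np.clip(1 - margins, 0, None).sum()
    dual = alpha.sum() - 0.5 * w @ w
    gap = float((primal - dual) / max(1.0, abs(primal)))
    if not converged:
        warnings.warn(f"SMO did not converge; duality gap {gap:.2e}")
    return SVMBinaryModel(w=w, b=b, C=C, alpha=alpha, support_indices=sv,
                          classes=tuple(classes), duality_gap=gap,
                          converged=converged)


# --------------------------------------------------------------------------
# one-vs-one multiclass
# --------------------------------------------------------------------------

@dataclass
class OVOEnsemble:
    classes: tuple
    models: dict[tuple, SVMBinaryModel] = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return len(self.models) == len(self.classes) * (len(self.classes) - 1) // 2


def train_ovo(X: np.ndarray, labels, C: float = 1.0) -> OVOEnsemble:
    """One binary SVM per unordered class pair; within each pair the
    alphabetically-first class is encoded -1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    ens = OVOEnsemble(classes=classes)
    for neg, pos in itertools.combinations(classes, 2):
        sel = (y == neg) | (y == pos)
        yy = np.where(y[sel] == pos, 1.0, -1.0)
        ens.models[(neg, pos)] = train_svm_binary(X[sel], yy, C=C, classes=(neg, pos))
    return ens


def predict_ovo(ensemble: OVOEnsemble, X: np.ndarray) -> np.ndarray:
    """Majority vote over pair models; ties broken by the largest sum of
    signed decision values among the tied classes, then lexicographically."""
    if not ensemble.trained:
        raise ValueError("ensemble is not fully trained")
    X = np.asarray(X, dtype=float)
    classes = ensemble.classes
    votes = {c: np.zeros(len(X)) for c in classes}
    scores = {c: np.zeros(len(X)) for c in classes}
    for (neg, pos), model in ensemble.models.items():
        f = model.decision_function(X)
        votes[pos] += f >= 0
        votes[neg] += f < 0
        scores[pos] += f
        scores[neg] -= f
    out = []
    for i in range(len(X)):
        vmax = max(votes[c][i] for c in classes)
        tied = [c for c in classes if votes[c][i] == vmax]
        if len(tied) > 1:
            smax = max(scores[c][i] for c in tied)
            tied = sorted(c for c in tied if scores[c][i] == smax)
        out.append(tied[0])
    return np.asarray(out)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix (rows = predicted, columns = true) with accuracy
    and per-class precision/recall/F-measure as fractions in [0, 1];
    classes absent from predictions or truth carry None."""

    confusion: pd.DataFrame
    accuracy: float
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    f_measure: dict[str, float | None]

    def as_percent(self, value: float | None) -> float | None:
        return None if value is None else round(100 * value, 1)

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.confusion.index:
            rows.append({
                "class": c,
                "precision_pct": self.as_percent(self.precision[c]),
                "recall_pct": self.as_percent(self.recall[c]),
                "f_measure_pct": self.as_percent(self.f_measure[c]),
            })
        return pd.DataFrame(rows).set_index("class")

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.as_percent(self.accuracy),
            "confusion": self.confusion.to_dict(),
            "precision_pct": {c: self.as_percent(v) for c, v in self.precision.items()},
            "recall_pct": {c: self.as_percent(v) for c, v in self.recall.items()},
            "f_measure_pct": {c: self.as_percent(v) for c, v in self.f_measure.items()},
        }


def confusion_matrix(y_true, y_pred, classes: tuple = STYLES) -> pd.DataFrame:
    """Rows = predicted label, columns = true label."""
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[p, t] += 1
    cm.index.name = "predicted"
    cm.columns.name = "true"
    return cm


def classification_report(cm: pd.DataFrame, rounded_f: bool = False) -> ClassificationReport:
    """Accuracy, precision, recall and F per class from a predicted-rows /
    true-columns confusion matrix.

    F is the harmonic mean of the unrounded precision and recall by
    default; ``rounded_f=True`` chains the one-decimal percentages
    instead (some published tables do).
    """
    M = cm.to_numpy()
    if M.shape[0] != M.shape[1] or (M < 0).any() or not np.issubdtype(M.dtype, np.number):
        raise ValueError("confusion matrix must be square and non-negative")
    total = M.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(M) / total
    precision, recall, f_measure = {}, {}, {}
    for i, c in enumerate(cm.index):
        row, col = M[i, :].sum(), M[:, i].sum()
        p = M[i, i] / row if row > 0 else None
        r = M[i, i] / col if col > 0 else None
        precision[c], recall[c] = p, r
        if p is None or r is None or (p + r) == 0:
            f_measure[c] = None
        elif rounded_f:
            pr, rr = round(100 * p, 1), round(100 * r, 1)
            f_measure[c] = (2 * pr * rr / (pr + rr)) / 100
        else:
            f_measure[c] = 2 * p * r / (p + r)
    return ClassificationReport(confusion=cm.copy(), accuracy=float(accuracy),
                                precision=precision, recall=recall,
                                f_measure=f_measure)


# --------------------------------------------------------------------------
# leave-one-subject-out cross-validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CVFoldPlan:
    folds: tuple[tuple[int, tuple[int, ...], tuple[int, ...]], ...]
    # (held-out subject, train task ids, test task ids)


@dataclass
class LOSOResult:
    report: ClassificationReport
    plan: CVFoldPlan
    predictions: pd.DataFrame     # task_id, subject_id, true, predicted
    skipped_subjects: list


def loso_fold_plan(features: pd.DataFrame) -> CVFoldPlan:
    """One fold per subject (sorted order); test sets partition all tasks."""
    subjects = sorted(features["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    folds = []
    for s in subjects:
        test = tuple(features.loc[features["subject_id"] == s, "task_id"])
        train = tuple(features.loc[features["subject_id"] != s, "task_id"])
        folds.append((s, train, test))
    return CVFoldPlan(folds=tuple(folds))


def loso_cross_validate(features: pd.DataFrame, C: float = 1.0,
                        lda_scope: str = "fold", lda_dim: int = 2,
                        classes: tuple = STYLES) -> LOSOResult:
    """Leave-one-subject-out evaluation of the LDA + OVO-SVM classifier.

    ``lda_scope='fold'`` refits the discriminant projection inside each
    training split (no leakage); ``'global'`` fits it once on all data;
    ``'none'`` feeds the 8-D features to the SVM directly. Folds whose
    training split misses a class are skipped with a warning and
    reported in the result.
    """
    if lda_scope not in ("fold", "global", "none"):
        raise ValueError("lda_scope must be 'fold', 'global' or 'none'")
    feats = features.reset_index(drop=True)
    Xall = feats[list(FEATURE_NAMES)].to_numpy(dtype=float)
    yall = feats["label"].to_numpy()
    plan = loso_fold_plan(feats)
    tid_to_row = {t: i for i, t in enumerate(feats["task_id"])}

    if lda_scope == "global":
        Xall_lda, _ = lda_reduce(Xall, yall, d=lda_dim)

    pred_rows, skipped = [], []
    for subject, train_ids, test_ids in plan.folds:
        tr = [tid_to_row[t] for t in train_ids]
        te = [tid_to_row[t] for t in test_ids]
        y_tr = yall[tr]
        if set(classes) - set(y_tr):
            warnings.warn(f"subject {subject}: training split missing a class; fold skipped")
            skipped.append(subject)
            continue
        if lda_scope == "fold":
            Z_tr, model = lda_reduce(Xall[tr], y_tr, d=lda_dim)
            Z_te = model.transform(Xall[te])
        elif lda_scope == "global":
            Z_tr, Z_te = Xall_lda[tr], Xall_lda[te]
        else:
            Z_tr, Z_te = Xall[tr], Xall[te]
        ens = train_ovo(Z_tr, y_tr, C=C)
        y_hat = predict_ovo(ens, Z_te)
        for t, row, p in zip(test_ids, te, y_hat):
            pred_rows.append({"task_id": t, "subject_id": subject,
                              "true": yall[row], "predicted": p})
    preds = pd.DataFrame(pred_rows).sort_values("task_id").reset_index(drop=True)
    cm = confusion_matrix(preds["true"], preds["predicted"], classes=classes)
    return LOSOResult(report=classification_report(cm), plan=plan,
                      predictions=preds, skipped_subjects=skipped)
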