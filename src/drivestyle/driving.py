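"""Driving-style labelling from behavioural driving variables.

The labelling stage standardises the seven driving variables (Z-score),
reduces them to two principal components, clusters the 2-D scores with
Lloyd's K-means (best of several random-observation initialisations),
selects the number of clusters by the Calinski-Harabasz criterion, and
names the K = 3 clusters Aggressive / Moderate / Conservative by
descending mean vehicle velocity. A one-way ANOVA characterises the
groups per variable.

K-means, the Calinski-Harabasz score and PCA are implemented here (they
are the core of the labelling stage); tests cross-check them against
independent reference implementations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .defaults import DRIVING_VARIABLES, STYLES


class PerfectSeparationError(ValueError):
    """All clusters are internally identical: within-scatter is zero and
    the Calinski-Harabasz ratio is not a finite number."""


# --------------------------------------------------------------------------
# standardisation and PCA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizedMatrix:
    values: np.ndarray            # tasks x p, column-wise Z-scores
    columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray               # sample SD, n-1 denominator


@dataclass(frozen=True)
class PCAModel:
    loadings: np.ndarray          # p x d, orthonormal columns
    explained_variance_ratio: np.ndarray


def zscore_standardize(table: pd.DataFrame, columns: tuple[str, ...] = DRIVING_VARIABLES) -> StandardizedMatrix:
    """Column-wise (x - mean) / SD with sample SD (n-1 denominator)."""
    X = table[list(columns)].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    if np.isnan(X).any():
        raise ValueError("missing values in driving table")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(f"constant column {columns[j]!r} (SD = 0) cannot be standardized")
    return StandardizedMatrix((X - means) / sds, tuple(columns), means, sds)


def pca_reduce(m: StandardizedMatrix | np.ndarray, d: int = 2) -> tuple[np.ndarray, PCAModel]:
    """Project onto the top-d eigenvectors of the covariance matrix.

    Eigenvalues descending; each loading's sign is fixed so its
    largest-magnitude entry is positive.
    """
    X = m.values if isinstance(m, StandardizedMatrix) else np.asarray(m, dtype=float)
    n, p = X.shape
    if d > p:
        raise ValueError(f"d={d} exceeds dimensionality {p}")
    if n <= d:
        raise ValueError("need more rows than output dimensions")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 0) * 1e-12))
    if d > rank:
        raise ValueError(f"d={d} exceeds data rank {rank}")
    L = evecs[:, :d]
    for j in range(d):
        k = np.argmax(np.abs(L[:, j]))
        if L[k, j] < 0:
            L[:, j] = -L[:, j]
    total = evals.sum()
    ratio = evals[:d] / total if total > 0 else np.zeros(d)
    return Xc @ L, PCAModel(L, ratio)


# --------------------------------------------------------------------------
# K-means and model selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KMeansResult:
    K: int
    centroids: np.ndarray         # K x p
    assignment: np.ndarray        # n, int cluster index
    ess: float                    # total within-cluster squared error
    n_iterations: int
    seed: int | None


def _lloyd(X: np.ndarray, K: int, rng: np.random.Generator, max_iter: int) -> tuple[np.ndarray, np.ndarray, float, int]:
    n = X.shape[0]
    # initial centroids: K distinct observations sampled at random
    uniq = np.unique(X, axis=0)
    centroids = uniq[rng.choice(len(uniq), size=K, replace=False)].copy()
    assignment = np.full(n, -1)
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)  # distance ties -> lowest cluster index
        # repair empty clusters: seize the point farthest from its centroid
        for k in range(K):
            if not (new_assign == k).any():
                far = int(np.argmax(d2[np.arange(n), new_assign]))
                new_assign[far] = k
                d2[far, :] = np.inf
                d2[far, k] = 0.0
        if (new_assign == assignment).all():
            break
        assignment = new_assign
        centroids = np.vstack([X[assignment == k].mean(axis=0) for k in range(K)])
    d2 = ((X - centroids[assignment]) ** 2).sum()
    return centroids, assignment, float(d2), it


def kmeans(points: np.ndarray, K: int, seed: int | None = 0,
           n_restarts: int = 10, max_iter: int = 300) -> KMeansResult:
    """Lloyd's algorithm, best of ``n_restarts`` random initialisations.

    Initial centroids are K distinct observations; iteration stops when
    no observation is reassigned; the restart with the lowest total
    within-cluster squared error (ESS) wins.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n_distinct = len(np.unique(X, axis=0))
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the number of distinct points ({n_distinct})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        cen, asg, ess, it = _lloyd(X, K, rng, max_iter)
        if best is None or ess < best[2]:
            best = (cen, asg, ess, it)
    cen, asg, ess, it = best
    return KMeansResult(K=K, centroids=cen, assignment=asg, ess=ess, n_iterations=it, seed=seed)


def calinski_harabasz(points: np.ndarray, assignment: np.ndarray) -> float:
    """s(k) = [tr(B_k)/tr(W_k)] * [(m-k)/(k-1)].

    B_k is the between-cluster scatter about the grand mean, W_k the
    pooled within-cluster scatter about the cluster means. Zero
    within-scatter is signalled as :class:`PerfectSeparationError`.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(assignment)
    clusters = np.unique(labels)
    k, m = len(clusters), len(X)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    grand = X.mean(axis=0)
    tr_b = tr_w = 0.0
    for c in clusters:
        Xi = X[labels == c]
        if len(Xi) == 0:
            raise ValueError("empty cluster")
        mu = Xi.mean(axis=0)
        tr_b += len(Xi) * float(((mu - grand) ** 2).sum())
        tr_w += float(((Xi - mu) ** 2).sum())
    if tr_w == 0:
        raise PerfectSeparationError("all clusters internally identical (tr(W) = 0)")
    return (tr_b / tr_w) * ((m - k) / (k - 1))


@dataclass(frozen=True)
class CHCurve:
    ks: tuple[int, ...]
    scores: tuple[float, ...]     # math.inf marks perfect separation
    k_star: int


def select_k(points: np.ndarray, k_range: tuple[int, ...] | range = range(2, 7),
             seed: int | None = 0, n_restarts: int = 10) -> CHCurve:
    """Run K-means per candidate K and pick the Calinski-Harabasz argmax.

    Ties (and equal perfect-separation scores) break toward smaller K.
    """
    ks = tuple(k_range)
    if not ks:
        raise ValueError("empty candidate range")
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"candidate K values must lie in [2, {n - 1}]")
    scores = []
    for k in ks:
        km = kmeans(X, k, seed=seed, n_restarts=n_restarts)
        try:
            scores.append(calinski_harabasz(X, km.assignment))
        except PerfectSeparationError:
            scores.append(math.inf)
    best = max(range(len(ks)), key=lambda i: (scores[i], -ks[i]))
    return CHCurve(ks=ks, scores=tuple(scores), k_star=ks[best])


# --------------------------------------------------------------------------
# style naming and group characterisation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StyleAssignment:
    labels: pd.Series             # task_id -> style
    cluster_to_style: dict[int, str]
    cluster_means: pd.DataFrame   # per-cluster mean driving variables


def assign_style_labels(km: KMeansResult, table: pd.DataFrame) -> StyleAssignment:
    """Name K = 3 clusters by descending mean vehicle velocity:
    fastest -> Aggressive, middle -> Moderate, slowest -> Conservative.
    Velocity ties break by mean steering angular acceleration, descending.
    """
    if km.K != 3:
        raise ValueError(f"style naming requires K = 3 clusters, got K = {km.K}")
    df = table.reset_index(drop=True)
    means = (
        pd.DataFrame({"cluster": km.assignment})
        .join(df[list(DRIVING_VARIABLES)])
        .groupby("cluster")
        .mean()
    )
    ranked = means.sort_values(
        ["velocity_kmh", "ang_acc_rad_s2"], ascending=[False, False]
    ).index
    mapping = {int(c): style for c, style in zip(ranked, STYLES)}
    task_ids = df["task_id"] if "task_id" in df else pd.Series(np.arange(len(df)))
    labels = pd.Series(
        [mapping[int(c)] for c in km.assignment],
        index=pd.Index(task_ids, name="task_id"),
        name="style",
    )
    return StyleAssignment(labels=labels, cluster_to_style=mapping, cluster_means=means)


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame           # per variable: F, p, eta2
    pairwise: pd.DataFrame        # per variable x group pair: Welch t p-value


def anova_oneway(table: pd.DataFrame, labels: pd.Series | np.ndarray,
                 columns: tuple[str, ...] = DRIVING_VARIABLES) -> AnovaResult:
    """Per-variable one-way F test with eta^2 = SSB/SST, plus pairwise
    Welch t comparisons (uncorrected).

    Zero pooled within-variance with distinct group means is reported as
    F = inf, p = 0 (infinite-separation sentinel).
    """
    y = np.asarray(labels)
    groups = [g for g in pd.unique(y)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (y == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    rows, pair_rows = [], []
    for var in columns:
        x = table[var].to_numpy(dtype=float)
        parts = [x[y == g] for g in groups]
        grand = x.mean()
        ssb = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
        ssw = sum(((p - p.mean()) ** 2).sum() for p in parts)
        sst = ssb + ssw
        dfb, dfw = len(groups) - 1, len(x) - len(groups)
        if ssw == 0:
            F, p = (math.inf, 0.0) if ssb > 0 else (0.0, 1.0)
        else:
            F = (ssb / dfb) / (ssw / dfw)
            p = float(stats.f.sf(F, dfb, dfw))
        eta2 = ssb / sst if sst > 0 else 0.0
        rows.append({"variable": var, "F": F, "p": p, "eta2": eta2})
        for a, b in itertools.combinations(groups, 2):
            t = stats.ttest_ind(x[y == a], x[y == b], equal_var=False)
            pair_rows.append({"variable": var, "group_a": a, "group_b": b,
                              "p": float(t.pvalue)})
    return AnovaResult(pd.DataFrame(rows).set_index("variable"),
                       pd.DataFrame(pair_rows))


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two labelings (contingency form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    n = len(a)
    ct = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(ct).sum()
    sum_a = comb(ct.sum(axis=1)).sum()
    sum_b = comb(ct.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
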