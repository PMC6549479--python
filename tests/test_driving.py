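"""Driving-style labelling stage: standardisation, PCA, K-means,
Calinski-Harabasz selection, style naming, ANOVA. Reference
implementations (scikit-learn, scipy) serve as independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drivestyle.defaults import DRIVING_VARIABLES, STYLES
from drivestyle.driving import (
    PerfectSeparationError,
    adjusted_rand_index,
    anova_oneway,
    assign_style_labels,
    calinski_harabasz,
    kmeans,
    pca_reduce,
    select_k,
    zscore_standardize,
)
from drivestyle.synthetic import DrivingGroupSpec, generate_driving_tasks


def _table(values: np.ndarray) -> pd.DataFrame:
    cols = DRIVING_VARIABLES[: values.shape[1]]
    return pd.DataFrame(values, columns=cols)


class TestZscore:
    def test_hand_computed_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        std = zscore_standardize(df, columns=("x",))
        assert np.allclose(std.values[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_input(self, driving_specs):
        df = generate_driving_tasks(driving_specs, seed=0)
        once = zscore_standardize(df)
        twice = zscore_standardize(_table(once.values))
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_output_columns_have_zero_mean_unit_sd(self, driving_specs):
        df = generate_driving_tasks(driving_specs, seed=1)
        std = zscore_standardize(df)
        assert np.allclose(std.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(std.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [5.0, 5.0]})
        with pytest.raises(ValueError, match="'y'"):
            zscore_standardize(df, columns=("x", "y"))


class TestPCA:
    def test_collinear_points_give_full_first_component(self):
        pts = np.array([[t, t] for t in np.linspace(-1, 1, 9)])
        _, model = pca_reduce(pts, d=1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, driving_specs):
        df = generate_driving_tasks(driving_specs, seed=2)
        _, model = pca_reduce(zscore_standardize(df), d=2)
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(2), atol=1e-9)

    def test_matches_sklearn_eigendecomposition(self, rng):
        from sklearn.decomposition import PCA

        X = rng.normal(size=(40, 7))
        scores, model = pca_reduce(X, d=3)
        sk = PCA(n_components=3).fit(X)
        for j in range(3):
            dot = abs(model.loadings[:, j] @ sk.components_[j])
            assert dot == pytest.approx(1.0, abs=1e-9)
            assert model.explained_variance_ratio[j] == pytest.approx(
                sk.explained_variance_ratio_[j], rel=1e-9)
        assert np.allclose(np.abs(scores), np.abs(sk.transform(X)), atol=1e-8)

    def test_rank_violation_rejected(self):
        pts = np.array([[t, t] for t in np.linspace(-1, 1, 9)])
        with pytest.raises(ValueError, match="rank"):
            pca_reduce(pts, d=2)


class TestKMeans:
    def test_two_well_separated_pairs(self):
        res = kmeans(np.array([0.0, 1.0, 10.0, 11.0]), K=2, seed=0, n_restarts=5)
        groups = {tuple(sorted(np.flatnonzero(res.assignment == k))) for k in range(2)}
        assert groups == {(0, 1), (2, 3)}
        assert res.ess == pytest.approx(1.0)

    def test_k_equals_n_gives_zero_ess(self, rng):
        X = rng.normal(size=(6, 2))
        res = kmeans(X, K=6, seed=0)
        assert res.ess == pytest.approx(0.0)

    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(20, 3))
        res = kmeans(X, K=1, seed=0)
        assert np.allclose(res.centroids[0], X.mean(axis=0))
        assert res.ess == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    def test_assignment_is_fixed_point(self, rng):
        X = rng.normal(size=(30, 2))
        res = kmeans(X, K=3, seed=1)
        d2 = ((X[:, None, :] - res.centroids[None]) ** 2).sum(axis=2)
        assert np.array_equal(np.argmin(d2, axis=1), res.assignment)
        for k in range(3):
            assert np.allclose(res.centroids[k], X[res.assignment == k].mean(axis=0))

    @pytest.mark.parametrize("n,K", [(6, 2), (7, 3), (8, 3)])
    def test_matches_exhaustive_partition_optimum(self, n, K, rng):
        """Best-of-20-restarts ESS equals the global optimum found by
        enumerating every K-labelling of <= 8 points."""
        X = rng.normal(size=(n, 2))
        res = kmeans(X, K=K, seed=0, n_restarts=20)
        best = np.inf
        for labels in itertools.product(range(K), repeat=n):
            if len(set(labels)) < K:
                continue
            lab = np.array(labels)
            ess = sum(
                ((X[lab == k] - X[lab == k].mean(axis=0)) ** 2).sum()
                for k in range(K)
            )
            best = min(best, ess)
        assert res.ess == pytest.approx(best, rel=1e-9)

    def test_k_above_distinct_points_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans(np.array([1.0, 1.0, 2.0]), K=3)


class TestCalinskiHarabasz:
    def test_hand_evaluated_pairs(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        assert calinski_harabasz(pts, [0, 0, 1, 1]) == pytest.approx(200.0)

    def test_identical_centroids_score_zero(self):
        pts = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        assert calinski_harabasz(pts, [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_zero_within_scatter_signalled(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        with pytest.raises(PerfectSeparationError):
            calinski_harabasz(pts, [0, 0, 1, 1])

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        for _ in range(5):
            X = rng.normal(size=(25, 3))
            labels = rng.integers(0, 3, size=25)
            if len(set(labels)) < 2:
                continue
            ours = calinski_harabasz(X, labels)
            ref = calinski_harabasz_score(X, labels)
            assert ours == pytest.approx(ref, rel=1e-9)


class TestSelectK:
    def test_two_separated_blobs_select_two(self, rng):
        X = np.vstack([rng.normal(size=(20, 2)) * 0.2,
                       rng.normal(size=(20, 2)) * 0.2 + 10.0])
        assert select_k(X, range(2, 6), seed=0).k_star == 2

    def test_single_candidate(self, rng):
        X = rng.normal(size=(12, 2))
        curve = select_k(X, (2,), seed=0)
        assert curve.k_star == 2 and curve.ks == (2,)

    def test_empty_range_rejected(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(size=(10, 2)), ())


class TestStyleNaming:
    def _cluster_table(self, velocities, accelerations=None):
        rows = []
        for c, v in enumerate(velocities):
            for i in range(3):
                row = {var: 0.0 for var in DRIVING_VARIABLES}
                row["velocity_kmh"] = v + 0.001 * i
                if accelerations is not None:
                    row["ang_acc_rad_s2"] = accelerations[c]
                row["task_id"] = 3 * c + i
                rows.append(row)
        return pd.DataFrame(rows)

    def test_velocity_ranking_names_styles(self):
        df = self._cluster_table([68.2, 62.2, 51.4])
        km = kmeans(df[["velocity_kmh"]].to_numpy(), K=3, seed=0, n_restarts=20)
        sa = assign_style_labels(km, df)
        by_vel = df.assign(style=sa.labels.values).groupby("style")["velocity_kmh"].mean()
        assert by_vel["Aggressive"] > by_vel["Moderate"] > by_vel["Conservative"]

    def test_permutation_of_cluster_ids_is_irrelevant(self):
        df = self._cluster_table([68.2, 62.2, 51.4])
        km = kmeans(df[["velocity_kmh"]].to_numpy(), K=3, seed=0, n_restarts=20)
        base = assign_style_labels(km, df)
        perm = np.array([2, 0, 1])
        from drivestyle.driving import KMeansResult

        km2 = KMeansResult(K=3, centroids=km.centroids[np.argsort(perm)],
                           assignment=perm[km.assignment], ess=km.ess,
                           n_iterations=km.n_iterations, seed=km.seed)
        assert (assign_style_labels(km2, df).labels == base.labels).all()

    def test_velocity_tie_broken_by_angular_acceleration(self):
        df = self._cluster_table([60.0, 60.0, 50.0], accelerations=[900.0, 400.0, 100.0])
        df["velocity_kmh"] = [60.0] * 3 + [60.0] * 3 + [50.0] * 3  # exact tie
        assignment = np.repeat([0, 1, 2], 3)
        from drivestyle.driving import KMeansResult

        km = KMeansResult(K=3, centroids=np.zeros((3, 1)), assignment=assignment,
                          ess=0.0, n_iterations=1, seed=0)
        sa = assign_style_labels(km, df)
        assert sa.cluster_to_style == {0: "Aggressive", 1: "Moderate", 2: "Conservative"}

    def test_wrong_k_rejected(self, rng):
        km = kmeans(rng.normal(size=(10, 2)), K=2, seed=0)
        with pytest.raises(ValueError, match="K = 3"):
            assign_style_labels(km, _table(rng.normal(size=(10, 7))))


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = anova_oneway(df, np.repeat(["a", "b"], 3), columns=("x",))
        assert res.table.loc["x", "F"] == pytest.approx(0.0)
        assert res.table.loc["x", "eta2"] == pytest.approx(0.0)

    def test_two_group_f_equals_pooled_t_squared(self, rng):
        x = np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 15)])
        labels = np.repeat(["a", "b"], [12, 15])
        res = anova_oneway(pd.DataFrame({"x": x}), labels, columns=("x",))
        t = stats.ttest_ind(x[:12], x[12:], equal_var=True)
        assert res.table.loc["x", "F"] == pytest.approx(t.statistic ** 2, rel=1e-9)

    def test_matches_scipy_f_oneway(self, driving_specs):
        df = generate_driving_tasks(driving_specs, seed=5)
        res = anova_oneway(df, df["true_style"])
        for var in DRIVING_VARIABLES:
            parts = [df.loc[df["true_style"] == s, var] for s in STYLES]
            ref = stats.f_oneway(*parts)
            assert res.table.loc[var, "F"] == pytest.approx(ref.statistic, rel=1e-9)
            assert res.table.loc[var, "p"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_eta_squared_in_unit_interval(self, driving_specs):
        df = generate_driving_tasks(driving_specs, seed=6)
        res = anova_oneway(df, df["true_style"])
        assert res.table["eta2"].between(0, 1).all()


class TestAdjustedRandIndex:
    def test_perfect_and_permuted_agreement(self):
        a = [0, 0, 1, 1, 2, 2]
        assert adjusted_rand_index(a, a) == pytest.approx(1.0)
        assert adjusted_rand_index(a, [1, 1, 2, 2, 0, 0]) == pytest.approx(1.0)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for _ in range(5):
            a = rng.integers(0, 3, 30)
            b = rng.integers(0, 4, 30)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), rel=1e-12, abs=1e-12)


class TestLabelRecovery:
    def test_style_recovery_ari(self, driving_specs):
        """Median adjusted Rand index between recovered and generating
        styles >= 0.8 over 20 seeded replicates of the default study."""
        aris = []
        for seed in range(20):
            df = generate_driving_tasks(driving_specs, seed=seed)
            scores, _ = pca_reduce(zscore_standardize(df), d=2)
            km = kmeans(scores, K=3, seed=seed)
            sa = assign_style_labels(km, df)
            aris.append(adjusted_rand_index(sa.labels.values, df["true_style"].values))
        assert np.median(aris) >= 0.8
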