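"""K-means++ seeding, Lloyd fits vs brute force, elbow, state mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from stemstate import synth
from stemstate.cluster import (
    AmbiguousStateError,
    KMeansPlusPlus,
    assign_states,
    cluster_cells,
    elbow_select,
    fit_kmeans,
    kmeanspp_seed,
    proportion_table,
)
from stemstate.features import FeatureTable, normalize_features


def brute_force_wcss(points, k):
    """Exhaustive-partition optimum over all assignments (oracle, n <= 10)."""
    n = len(points)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        w = 0.0
        for j in range(k):
            members = points[np.array(assign) == j]
            w += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    return best


class TestSeeding:
    def test_k_equals_n_is_permutation(self):
        pts = np.array([[0.0], [1.0], [5.0], [9.0]])
        seeds = kmeanspp_seed(pts, 4, np.random.default_rng(0))
        assert sorted(seeds.ravel().tolist()) == [0.0, 1.0, 5.0, 9.0]

    def test_two_points_always_split(self):
        pts = np.array([[0.0], [10.0]])
        for s in range(50):
            seeds = kmeanspp_seed(pts, 2, np.random.default_rng(s))
            assert sorted(seeds.ravel().tolist()) == [0.0, 10.0]

    def test_three_blobs_one_seed_each(self):
        """D^2 weighting puts one seed per far-apart blob almost surely."""
        rng = np.random.default_rng(1)
        blobs = np.vstack(
            [rng.normal(c, 0.05, size=(10, 2)) for c in ((0, 0), (10, 0), (0, 10))]
        )
        hits = 0
        for s in range(1000):
            seeds = kmeanspp_seed(blobs, 3, np.random.default_rng(s))
            labels = {tuple(np.round(c / 5).astype(int)) for c in seeds}
            hits += len(labels) == 3
        assert hits >= 950

    def test_k_too_large_rejected(self):
        pts = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(ValueError):
            kmeanspp_seed(pts, 3, np.random.default_rng(0))


class TestFitKmeans:
    def test_two_pairs_exact_solution(self):
        pts = np.array([[0.0], [1.0], [9.0], [10.0]])
        model = fit_kmeans(pts, 2, seed=0)
        assert sorted(model.centroids.ravel().tolist()) == [0.5, 9.5]
        assert model.wcss == pytest.approx(1.0, abs=1e-12)

    def test_k1_closed_form(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(40, 2))
        model = fit_kmeans(pts, 1, seed=0)
        assert np.allclose(model.centroids[0], pts.mean(axis=0))
        assert model.wcss == pytest.approx(((pts - pts.mean(axis=0)) ** 2).sum())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_partition_optimum(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(rng.integers(5, 9), 2))
        model = fit_kmeans(pts, 2, seed=seed)
        assert model.wcss == pytest.approx(brute_force_wcss(pts, 2), abs=1e-9)

    def test_matches_sklearn_inertia(self):
        """Independent route: sklearn's KMeans on the same data must reach
        an equally good (not better) optimum."""
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(c, 0.3, size=(50, 3)) for c in (0.0, 2.0, 5.0)])
        ours = fit_kmeans(pts, 3, seed=1)
        ref = KMeans(n_clusters=3, n_init=10, random_state=1).fit(pts)
        assert ours.wcss == pytest.approx(ref.inertia_, rel=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(100, 3))
        m1 = fit_kmeans(pts, 4, seed=5)
        m2 = fit_kmeans(pts, 4, seed=5)
        assert np.array_equal(m1.assignments, m2.assignments)
        assert np.array_equal(m1.centroids, m2.centroids)

    def test_row_shuffle_changes_only_labels(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(c, 0.2, size=(30, 2)) for c in (0.0, 3.0, 6.0)])
        m1 = fit_kmeans(pts, 3, seed=2)
        perm = rng.permutation(len(pts))
        m2 = fit_kmeans(pts[perm], 3, seed=4)
        co1 = m1.assignments[:, None] == m1.assignments[None, :]
        labels2 = np.empty_like(m2.assignments)
        labels2[perm] = m2.assignments
        co2 = labels2[:, None] == labels2[None, :]
        assert np.array_equal(co1, co2)

    def test_sklearn_estimator_protocol(self):
        est = KMeansPlusPlus(n_clusters=2, random_state=0)
        params = est.get_params()
        assert params["n_clusters"] == 2
        est.set_params(n_clusters=3)
        X = np.random.default_rng(0).normal(size=(30, 2))
        est.fit(X)
        assert est.cluster_centers_.shape == (3, 2)
        assert np.array_equal(est.predict(X), est.labels_)


class TestElbow:
    def test_three_blob_table_selects_three(self):
        tab = synth.sample_feature_table(150, modality="FLIM_A2", seed=0)
        ft = normalize_features(FeatureTable(tab, ("area", "a2_peak", "a2_fwhm")))
        res = elbow_select(ft.matrix(), seed=0)
        assert res.k_selected == 3
        assert not res.flat

    def test_single_cloud_flagged_flat(self):
        X = np.random.default_rng(0).normal(0.5, 0.1, size=(500, 3))
        res = elbow_select(X, seed=0)
        assert res.flat

    def test_curve_non_increasing(self):
        tab = synth.sample_feature_table(80, modality="SRS", seed=3)
        cols = ("area", "perimeter", "circularity", "mean_gray")
        ft = normalize_features(FeatureTable(tab, cols))
        res = elbow_select(ft.matrix(), seed=1)
        curve = np.array(res.wcss_curve)
        assert (np.diff(curve) <= 1e-9).all()

    def test_short_range_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        with pytest.raises(ValueError):
            elbow_select(X, k_range=range(2, 4), seed=0)


class TestStateAssignment:
    def _drifting(self):
        rng = np.random.default_rng(0)
        days = np.repeat([1, 28], 200)
        frac_first = [0.8, 0.1, 0.1]
        frac_last = [0.05, 0.25, 0.70]
        a_first = rng.choice(3, size=200, p=frac_first)
        a_last = rng.choice(3, size=200, p=frac_last)
        return np.concatenate([a_first, a_last]), days

    def test_drift_maps_states(self):
        assignments, days = self._drifting()
        mapping = assign_states(assignments, days)
        assert mapping[0] == "undiff"
        assert mapping[2] == "diff"
        assert mapping[1] == "differentiating"

    def test_permutation_invariance(self):
        assignments, days = self._drifting()
        perm = np.array([2, 0, 1])  # relabel clusters
        mapping_a = assign_states(assignments, days)
        mapping_b = assign_states(perm[assignments], days)
        for c in range(3):
            assert mapping_a[c] == mapping_b[perm[c]]

    def test_symmetric_mixture_ambiguous(self):
        days = np.repeat([1, 28], 90)
        assignments = np.tile([0, 1, 2], 60)
        with pytest.raises(AmbiguousStateError):
            assign_states(assignments, days)

    def test_wrong_k_rejected(self):
        with pytest.raises(ValueError):
            assign_states(np.zeros(10, int), np.repeat([1, 28], 5), k=2)


class TestProportionTable:
    def test_single_field_full_occupancy(self):
        table = proportion_table(np.zeros(10, int), np.ones(10, int), np.zeros(10, int), k=1)
        row = table.rows.iloc[0]
        assert row["mean_fraction"] == 1.0
        assert row["sd_fraction"] == 0.0

    def test_two_field_sd(self):
        assignments = np.array([0] * 4 + [1] * 6 + [0] * 6 + [1] * 4)
        days = np.ones(20, int)
        fields = np.repeat([0, 1], 10)
        table = proportion_table(assignments, days, fields, k=2)
        c0 = table.rows[table.rows["cluster"] == 0].iloc[0]
        assert c0["mean_fraction"] == pytest.approx(0.5)
        assert c0["sd_fraction"] == pytest.approx(0.1414, abs=1e-4)

    def test_fractions_sum_to_one_per_day(self):
        rng = np.random.default_rng(5)
        assignments = rng.choice(3, size=300)
        days = rng.choice([1, 7, 14], size=300)
        fields = rng.choice(3, size=300)
        table = proportion_table(assignments, days, fields, k=3)
        for total in table.per_day_sums():
            assert total == pytest.approx(1.0, abs=1e-9)


class TestClusterCells:
    def test_unnormalized_table_rejected(self):
        tab = synth.sample_feature_table(30, seed=0)
        table = FeatureTable(tab, ("area", "a2_peak", "a2_fwhm"))
        with pytest.raises(ValueError, match="normalized"):
            cluster_cells(table, k=3)

    def test_fixed_k_skips_elbow(self):
        tab = synth.sample_feature_table(50, seed=0)
        ft = normalize_features(FeatureTable(tab, ("area", "a2_peak", "a2_fwhm")))
        model, elbow = cluster_cells(ft, k=3, seed=0)
        assert model.k == 3 and elbow is None

    def test_mixture_recovery(self):
        """Recovered per-day state fractions track the generating mixtures."""
        tab = synth.sample_feature_table(150, seed=42)
        ft = normalize_features(FeatureTable(tab.copy(), ("area", "a2_peak", "a2_fwhm")))
        model, _ = cluster_cells(ft, k=3, seed=0)
        mapping = assign_states(model.assignments, tab["day"].to_numpy())
        states = np.array([mapping[c] for c in model.assignments])
        errs = []
        for day in tab["day"].unique():
            sel = (tab["day"] == day).to_numpy()
            for name in ("undiff", "differentiating", "diff"):
                true_frac = (tab.loc[sel, "state"] == name).mean()
                errs.append(abs((states[sel] == name).mean() - true_frac))
        assert np.median(errs) <= 0.10
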