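"""Profile clustering, correlation extension, course specificity."""

from itertools import combinations

import numpy as np
import pytest
from sklearn.cluster import KMeans

from methylerase import synthetic_data as sd
from methylerase.clustering import (classify_course_specificity,
                                    cluster6_template,
                                    extend_cluster_by_correlation,
                                    find_focal_cluster, group_induction_summary,
                                    kmeans_profiles, pearson_to_profile)
from methylerase.errors import MatrixValidationError
from methylerase.normalization import zero_center_rows
from methylerase.track_io import TimeCourseMatrix


def matrix_from(values, ids=None):
    values = np.asarray(values, dtype=float)
    return TimeCourseMatrix(ids=ids or [f"n{i}" for i in range(len(values))],
                            times=np.arange(values.shape[1]) * 5.0,
                            values=values)


class TestKMeans:
    def test_separated_groups_recovered_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.05, size=(10, 6)) + 10.0
        b = rng.normal(0, 0.05, size=(10, 6)) - 10.0
        m = matrix_from(np.vstack([a, b]))
        res = kmeans_profiles(m, k=2, seed=0)
        labels = [res.assignments[f"n{i}"] for i in range(20)]
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_matches_exhaustive_bipartition_on_six_profiles(self):
        # brute-force oracle: best of all 31 bipartitions of 6 profiles
        rng = np.random.default_rng(7)
        x = rng.normal(size=(6, 4))
        m = matrix_from(x)
        res = kmeans_profiles(m, k=2, seed=0, n_restarts=50)

        def wcss(groups):
            return sum(((x[list(g)] - x[list(g)].mean(axis=0)) ** 2).sum()
                       for g in groups if g)

        best = min(
            wcss(([i for i in range(6) if i in sub],
                  [i for i in range(6) if i not in sub]))
            for r in range(1, 6) for sub in map(set, combinations(range(6), r)))
        assert res.inertia == pytest.approx(best, rel=1e-9)

    def test_lloyd_objective_non_increasing(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 5))
        init = x[:3].copy()
        inertias = []
        for iters in (1, 2, 5):
            km = KMeans(n_clusters=3, init=init, n_init=1, max_iter=iters)
            km.fit(x)
            inertias.append(km.inertia_)
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        m = matrix_from(rng.normal(size=(30, 6)))
        res = kmeans_profiles(m, k=3, seed=5)
        perm = rng.permutation(30)
        m2 = matrix_from(m.values[perm], ids=[m.ids[i] for i in perm])
        res2 = kmeans_profiles(m2, k=3, seed=5)
        assert res.assignments == res2.assignments

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(MatrixValidationError):
            kmeans_profiles(matrix_from(np.zeros((3, 4))), k=4)

    def test_missing_cells_rejected(self):
        vals = np.zeros((4, 4))
        vals[0, 0] = np.nan
        with pytest.raises(MatrixValidationError, match="missing"):
            kmeans_profiles(matrix_from(vals), k=2)

    def test_centroids_are_member_means(self):
        rng = np.random.default_rng(3)
        m = matrix_from(rng.normal(size=(20, 5)))
        res = kmeans_profiles(m, k=3, seed=0)
        for c in range(3):
            idx = [m.ids.index(rid) for rid in res.members(c)]
            np.testing.assert_allclose(res.centroids[c],
                                       m.values[idx].mean(axis=0), atol=1e-12)


class TestCorrelationExtension:
    def test_pearson_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        # independent arithmetic oracle: explicit sum formula
        n = 4
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x ** 2).sum() - x.sum() ** 2) * \
            np.sqrt(n * (y ** 2).sum() - y.sum() ** 2)
        expected = num / den
        r, _ = pearson_to_profile(matrix_from(y[None, :]), x)
        assert r.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_exact_and_negated_rows(self):
        centroid = np.array([1.0, 0.0, -1.0, 0.5])
        m = matrix_from(np.vstack([centroid, -centroid]))
        ids, _ = extend_cluster_by_correlation(m, centroid, r_min=0.5)
        assert ids == {"n0"}

    def test_threshold_extremes(self):
        rng = np.random.default_rng(4)
        centroid = rng.normal(size=5)
        rows = np.vstack([rng.normal(size=(6, 5)),
                          2.0 * centroid + 1.0,       # positively proportional
                          np.full(5, 3.0)])           # zero variance
        m = matrix_from(rows)
        all_ids, excluded = extend_cluster_by_correlation(m, centroid, r_min=-1.0)
        assert all_ids == set(m.ids) - {"n7"} and excluded == ["n7"]
        only_prop, _ = extend_cluster_by_correlation(m, centroid, r_min=1.0)
        assert only_prop == {"n6"}

    def test_zero_variance_centroid_rejected(self):
        with pytest.raises(MatrixValidationError, match="centroid"):
            extend_cluster_by_correlation(matrix_from(np.zeros((2, 4))),
                                          np.ones(4))


class TestCourseSpecificity:
    def test_examples(self):
        labels, order = classify_course_specificity(
            {"a": 0.1, "b": 0.5, "c": 0.9},
            {"a": 0.9, "b": 0.5, "c": 0.1}, margin=0.2)
        assert labels["a"] == "TS>A"
        assert labels["b"] == "TS~A"
        assert labels["c"] == "A>TS"
        assert order == ["a", "b", "c"]  # sorted by decreasing rTS - rA

    def test_group_summary_arithmetic(self):
        out = group_induction_summary({"a": "g1", "b": "g1", "c": "g2"},
                                      {"a": 1.0, "b": 3.0, "c": 5.0})
        assert out.loc["g1", "mean"] == 2.0
        assert out.loc["g1", "sem"] == 1.0
        assert out.loc["g2", "sem"] == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_induction_summary({"a": "g1"}, {"a": np.nan})


@pytest.fixture(scope="module")
def cca_clustering():
    seed = 0
    params = sd.default_params(seed=seed)
    panel, _ = sd.make_cluster6_panel(500, 1500, seed=seed)
    sim = sd.simulate_experiment(panel, params, sd.cca_condition())
    centered = zero_center_rows(sim.me3)
    km = kmeans_profiles(centered, k=6, seed=seed, n_restarts=50)
    focal = find_focal_cluster(
        km, cluster6_template(centered.times, params.s_phase_window))
    idx = [centered.ids.index(rid) for rid in km.members(focal)]
    centroid = centered.values[idx].mean(axis=0)
    extended, _ = extend_cluster_by_correlation(centered, centroid, 0.5)
    membership = extended | set(km.members(focal))
    truth_c6 = set(sim.truth.index[sim.truth["arrest_excess_log2"] > 0])
    return membership, truth_c6, set(centered.ids) - truth_c6


class TestEndToEnd:
    """Cluster discovery on the default synthetic panels.

    At the study noise level the Pearson-extension statistic recovers most,
    not all, arrest-induced loci (early-replicating, low-excess loci carry
    their signature in very few samples); the asserted bounds are the
    measured operating point, far above the background rate.
    """

    def test_recovery_far_exceeds_background_rate(self, cca_clustering):
        membership, c6, bg = cca_clustering
        recovery = len(membership & c6) / len(c6)
        fpr = len(membership & bg) / len(bg)
        assert recovery >= 0.70
        assert fpr <= 0.05
        assert recovery > 10 * fpr

    def test_heat_class_labelled_ts_specific(self):
        # loci induced only by the temperature arrest correlate with the
        # erasure profile in CCTS, not CCA
        seed = 0
        panels, _ = sd.make_two_course_panel(100, 100, 400, seed=seed)
        sim_a = sd.simulate_experiment(panels["CCA"], sd.default_params(seed=seed),
                                       sd.cca_condition())
        sim_ts = sd.simulate_experiment(panels["CCTS"], sd.ccts_params(seed=seed),
                                        sd.ccts_condition())
        truth = sim_a.truth["induction_class"]

        def centroid_of(sim, cls):
            centered = zero_center_rows(sim.me3)
            ids = [rid for rid in centered.ids if truth[rid] == cls]
            idx = [centered.ids.index(rid) for rid in ids]
            return centered, centered.values[idx].mean(axis=0)

        cen_a, prof_a = centroid_of(sim_a, "alpha")
        cen_ts, prof_ts = centroid_of(sim_ts, "heat")
        r_a, _ = pearson_to_profile(cen_a, prof_a)
        r_ts, _ = pearson_to_profile(cen_ts, prof_ts)
        labels, _ = classify_course_specificity(r_a, r_ts, margin=0.2)
        heat_ids = [rid for rid in labels.index if truth[rid] == "heat"]
        assert (labels.loc[heat_ids] == "TS>A").mean() >= 0.90
        # and the TS-specific group is the heat-induced one
        summary = group_induction_summary(
            labels.to_dict(),
            {rid: (2.5 if truth[rid] == "heat" else 0.0) for rid in labels.index})
        assert summary.loc["TS>A", "mean"] > summary.loc["A>TS", "mean"]
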