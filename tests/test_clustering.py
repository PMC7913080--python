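import itertools

import numpy as np
import pytest
from sklearn.base import clone

from clonalsig.clustering import (
    OUTLIER,
    ClusteringParams,
    VAFMatrix,
    VAFTrajectoryClustering,
    build_vaf_matrix,
    estimate_purity,
    kmeans_vaf,
    label_trajectory,
    merge_clusters,
    prune_outliers,
)

from conftest import make_record


def _vafs(X, labels=None):
    X = np.asarray(X, dtype=float)
    return VAFMatrix(
        mutation_ids=[str(i) for i in range(X.shape[0])],
        timepoint_labels=[f"T{i}" for i in range(X.shape[1])],
        values=X,
    )


class TestBuildVafMatrix:
    def test_tumor_samples_only_in_timepoint_order(self, samples4):
        rec = make_record(samples4, tumor_counts=((10, 10), (30, 0), (5, 15)))
        m = build_vaf_matrix([rec], samples4)
        assert m.timepoint_labels == ["Dx", "R1", "R2"]
        np.testing.assert_allclose(m.values, [[0.5, 0.0, 0.75]])

    def test_row_order_is_input_order(self, samples4):
        recs = [make_record(samples4, pos=p) for p in (5, 3, 9)]
        m = build_vaf_matrix(recs, samples4)
        assert m.mutation_ids == [r.key for r in recs]

    def test_single_timepoint_fatal(self):
        from clonalsig.io import SampleDescriptor

        samples = [SampleDescriptor("T0", "tumor", 0, "Dx"),
                   SampleDescriptor("C", "control")]
        rec = make_record(samples, tumor_counts=((10, 10),))
        with pytest.raises(ValueError, match="2 tumor timepoints"):
            build_vaf_matrix([rec], samples)


class TestKMeans:
    def setup_method(self):
        gen = np.array([[0.5, 0, 0], [0, 0.5, 0], [0.4, 0.4, 0.4]])
        self.X = np.repeat(gen, 100, axis=0)
        self.truth = np.repeat([0, 1, 2], 100)

    def test_noiseless_exact_partition(self):
        cs = kmeans_vaf(_vafs(self.X), ClusteringParams(k_initial=3, seed=0))
        # exact partition: each planted vector maps to one cluster
        for t in range(3):
            assert len(set(cs.labels[self.truth == t])) == 1
        got = {tuple(np.round(c, 12)) for c in cs.centroids.values()}
        expected = {(0.5, 0, 0), (0, 0.5, 0), (0.4, 0.4, 0.4)}
        assert got == expected

    def test_overclustering_never_mixes_distinct_points(self):
        cs = kmeans_vaf(_vafs(self.X), ClusteringParams(k_initial=5, seed=0))
        assert len(cs.centroids) <= 5
        # members of different generating vectors never share a cluster
        for t1, t2 in itertools.combinations(range(3), 2):
            l1 = set(cs.labels[self.truth == t1])
            l2 = set(cs.labels[self.truth == t2])
            assert not (l1 & l2)

    def test_k_above_row_count_fatal(self):
        with pytest.raises(ValueError, match="smaller K"):
            kmeans_vaf(_vafs(self.X), ClusteringParams(k_initial=301, seed=0))

    def test_k_capped_at_distinct_rows(self):
        cs = kmeans_vaf(_vafs(self.X), ClusteringParams(k_initial=5, seed=0))
        assert len(cs.centroids) == 3
        assert cs.provenance["k_effective"] == 3

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(200, 3))
        a = kmeans_vaf(_vafs(X), ClusteringParams(k_initial=6, seed=5))
        b = kmeans_vaf(_vafs(X), ClusteringParams(k_initial=6, seed=5))
        assert (a.labels == b.labels).all()


def _oracle_agglomerate(X, labels, merge_distance):
    """Independent greedy agglomeration: repeatedly merge the closest pair
    of clusters (L-infinity between member-mean centroids) while below the
    threshold. Recomputed from scratch each round."""
    labels = labels.copy()
    while True:
        ids = sorted(set(labels))
        cents = {c: X[labels == c].mean(axis=0) for c in ids}
        pairs = sorted(
            ((np.abs(cents[a] - cents[b]).max(), a, b)
             for a, b in itertools.combinations(ids, 2))
        )
        if not pairs or pairs[0][0] >= merge_distance:
            return labels
        _, a, b = pairs[0]
        labels[labels == b] = a


class TestMerge:
    def test_close_pair_merges(self):
        X = np.repeat([[0.48, 0.01, 0.02], [0.52, 0.03, 0.01]], 10, axis=0)
        cs = kmeans_vaf(_vafs(X), ClusteringParams(k_initial=2, seed=0))
        merged = merge_clusters(cs, _vafs(X), ClusteringParams(merge_distance=0.10))
        assert len(merged.centroids) == 1

    def test_distant_pair_unchanged(self):
        X = np.repeat([[0.5, 0, 0], [0, 0.5, 0]], 10, axis=0)
        cs = kmeans_vaf(_vafs(X), ClusteringParams(k_initial=2, seed=0))
        merged = merge_clusters(cs, _vafs(X), ClusteringParams(merge_distance=0.10))
        assert len(merged.centroids) == 2
        assert (merged.labels == cs.labels).all()

    def test_chain_matches_independent_oracle(self):
        # A-B close, B-C close, A-C far: result depends on centroid
        # recomputation after the first merge
        X = np.concatenate([
            np.repeat([[0.10, 0.0]], 30, axis=0),
            np.repeat([[0.18, 0.0]], 10, axis=0),
            np.repeat([[0.26, 0.0]], 30, axis=0),
        ])
        vafs = _vafs(X)
        cs = kmeans_vaf(vafs, ClusteringParams(k_initial=3, seed=0))
        merged = merge_clusters(cs, vafs, ClusteringParams(merge_distance=0.09))
        oracle = _oracle_agglomerate(X, cs.labels, 0.09)
        # same partition (labels may differ in name)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(oracle, merged.labels) == 1.0

    def test_manual_map_overrides_and_validates(self):
        X = np.repeat([[0.5, 0, 0], [0, 0.5, 0]], 10, axis=0)
        vafs = _vafs(X)
        cs = kmeans_vaf(vafs, ClusteringParams(k_initial=2, seed=0))
        a, b = sorted(cs.centroids)
        merged = merge_clusters(cs, vafs, ClusteringParams(), manual_map={b: a})
        assert len(merged.centroids) == 1
        with pytest.raises(ValueError, match="unknown cluster"):
            merge_clusters(cs, vafs, ClusteringParams(), manual_map={99: 0})


class TestPruneOutliers:
    def test_planted_outliers_flagged_exactly(self):
        X = np.repeat([[0.5, 0, 0]], 50, axis=0)
        X[:3] = [0.9, 0, 0]  # three planted outliers (distance 0.4 > 0.2)
        vafs = _vafs(X)
        cs = kmeans_vaf(vafs, ClusteringParams(k_initial=1, seed=0))
        pruned = prune_outliers(cs, vafs, ClusteringParams(outlier_distance=0.2))
        assert pruned.n_outliers == 3
        assert set(np.flatnonzero(pruned.labels == OUTLIER)) == {0, 1, 2}
        # centroids recomputed after pruning
        np.testing.assert_allclose(list(pruned.centroids.values())[0], [0.5, 0, 0])

    def test_idempotent_when_all_members_close(self):
        X = np.repeat([[0.5, 0, 0]], 20, axis=0)
        vafs = _vafs(X)
        cs = kmeans_vaf(vafs, ClusteringParams(k_initial=1, seed=0))
        pruned = prune_outliers(cs, vafs, ClusteringParams())
        assert pruned.n_outliers == 0
        assert (pruned.labels == cs.labels).all()


class TestTrajectoryLabels:
    @pytest.mark.parametrize(
        "centroid,expected",
        [
            ((0.42, 0.40, 0.45), "ancestral"),
            ((0.0, 0.33, 0.0), "transient"),
            ((0.04, 0.04), "other"),
            ((0.4, 0.0, 0.0), "falling"),
            ((0.0, 0.2, 0.4), "rising"),
            ((0.4, 0.0, 0.4), "other"),  # present at both ends, gap between
        ],
    )
    def test_examples(self, centroid, expected):
        assert label_trajectory(np.array(centroid), 0.05) == expected

    def test_exhaustive_truth_table(self):
        """All 2^T presence patterns at T=3 and T=4 match first-principles
        label definitions."""
        for T in (3, 4):
            for bits in itertools.product([0, 1], repeat=T):
                centroid = np.array([0.4 if b else 0.0 for b in bits])
                present = np.array(bits, dtype=bool)
                if present.all():
                    want = "ancestral"
                elif present[0] and not present[-1]:
                    want = "falling"
                elif not present[0] and present[-1]:
                    want = "rising"
                elif not present[0] and not present[-1] and present.any():
                    want = "transient"
                else:
                    want = "other"
                assert label_trajectory(centroid, 0.05) == want, bits


class TestPurity:
    def _clusterset(self, X):
        vafs = _vafs(X)
        return vafs, kmeans_vaf(vafs, ClusteringParams(k_initial=1, seed=0))

    def test_heterozygous_diploid_identity(self):
        vafs, cs = self._clusterset(np.full((21, 2), 0.40))
        assert estimate_purity(vafs, cs)["T0"] == pytest.approx(0.80)

    def test_clipped_at_one(self):
        vafs, cs = self._clusterset(np.full((21, 2), 0.55))
        assert estimate_purity(vafs, cs)["T1"] == pytest.approx(1.0)

    def test_missing_when_nothing_present(self):
        vafs, cs = self._clusterset(np.column_stack(
            [np.full(21, 0.4), np.full(21, 0.0)]))
        out = estimate_purity(vafs, cs)
        assert np.isnan(out["T1"])

    def test_recovers_planted_purity_from_simulation(self, catalog):
        """Planted purity 0.9 at depth 100 recovered within +-0.05."""
        from clonalsig.simulate import CloneSpec, SimulationConfig, simulate_patient

        cfg = SimulationConfig(
            timepoint_labels=["Dx", "R1"],
            purity_per_timepoint=[0.9, 0.9],
            clones=[CloneSpec("anc", [1.0, 1.0], 400, {"SBS5": 1.0})],
            mean_depth=100.0,
            n_background_samples=0,
            decoys_per_rule=0,
            germline_contamination_rate=0.0,
            seed=3,
        )
        sim = simulate_patient(cfg, catalog)
        vafs = build_vaf_matrix(sim.records, sim.sample_descriptors)
        cs = kmeans_vaf(vafs, ClusteringParams(k_initial=1, seed=0))
        purity = estimate_purity(vafs, cs)
        for t in ("Dx", "R1"):
            assert purity[t] == pytest.approx(0.9, abs=0.05)


class TestEstimator:
    def test_partition_invariant_and_sklearn_compat(self):
        rng = np.random.default_rng(4)
        X = np.clip(np.concatenate([
            rng.normal(0.45, 0.04, size=(150, 3)),
            rng.normal([0.4, 0.0, 0.0], 0.04, size=(150, 3)),
        ]), 0, 1)
        est = VAFTrajectoryClustering(k_initial=4, min_cluster_size=10, random_state=0)
        labels = est.fit_predict(X)
        assert labels.shape == (300,)
        sizes = sum(est.clusterset_.sizes.values())
        assert sizes + est.clusterset_.n_outliers == 300
        # get_params/set_params round trip (sklearn clone contract)
        est2 = clone(est)
        assert est2.get_params() == est.get_params()

    def test_determinism(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, size=(300, 3))
        a = VAFTrajectoryClustering(k_initial=6, random_state=1,
                                    min_cluster_size=1).fit(X)
        b = VAFTrajectoryClustering(k_initial=6, random_state=1,
                                    min_cluster_size=1).fit(X)
        assert (a.labels_ == b.labels_).all()
        np.testing.assert_array_equal(a.cluster_centers_, b.cluster_centers_)

    def test_small_clusters_dissolved_unless_kept(self):
        X = np.concatenate([
            np.repeat([[0.5, 0.5]], 100, axis=0),
            np.repeat([[0.0, 0.4]], 5, axis=0),
        ])
        dropped = VAFTrajectoryClustering(
            k_initial=2, min_cluster_size=20, random_state=0).fit(X)
        assert dropped.n_clusters_ == 1
        assert dropped.clusterset_.n_outliers == 5
        kept = VAFTrajectoryClustering(
            k_initial=2, min_cluster_size=20, keep_small_clusters=True,
            random_state=0).fit(X)
        assert kept.n_clusters_ == 2
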