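import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from angiosig import (
    complete_linkage_order,
    consensus_cluster,
    generate_cohort,
    kmeans_best_of,
    select_k,
    subset_panel,
)
from angiosig.cluster import ConsensusResult, consensus_cdf_area

from conftest import three_cluster_config


def two_clouds(rng, n=20, sep=50.0, d=4):
    a = rng.normal(0, 1, size=(n, d))
    b = rng.normal(sep, 1, size=(n, d))
    return np.vstack([a, b]), np.array([0] * n + [1] * n)


class TestKmeansBestOf:
    def test_k1_wss_is_total_centered_ss(self, rng):
        x = rng.normal(size=(15, 3))
        labels, wss = kmeans_best_of(x, 1, restarts=3, seed=0)
        assert np.all(labels == 0)
        assert wss == pytest.approx(((x - x.mean(axis=0)) ** 2).sum(), rel=1e-10)

    def test_separated_clouds_recovered(self, rng):
        x, truth = two_clouds(rng)
        labels, _ = kmeans_best_of(x, 2, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_wss_matches_exhaustive_partition_minimum(self, rng):
        """n=8, k=2: the returned WSS equals the brute-force minimum over
        all 2-partitions."""
        x = rng.normal(size=(8, 2))
        _, wss = kmeans_best_of(x, 2, restarts=50, seed=3)

        def partition_wss(mask):
            total = 0.0
            for grp in (x[mask], x[~mask]):
                if len(grp):
                    total += ((grp - grp.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            partition_wss(np.array([(code >> i) & 1 for i in range(8)], dtype=bool))
            for code in range(1, 2 ** 7)  # nonempty, up to symmetry
        )
        assert wss == pytest.approx(best, rel=1e-9)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(30, 5))
        l1, w1 = kmeans_best_of(x, 3, seed=7)
        l2, w2 = kmeans_best_of(x, 3, seed=7)
        assert np.array_equal(l1, l2) and w1 == w2

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_best_of(rng.normal(size=(4, 2)), 5)


class TestConsensusCluster:
    def test_separated_clouds_give_binary_consensus(self, rng):
        x, truth = two_clouds(rng, n=15)
        res = consensus_cluster(x, 2, iterations=30, seed=0)
        within = truth[:, None] == truth[None, :]
        iu = np.triu_indices(len(truth), k=1)
        cosampled = res.co_sample_counts[iu] > 0
        assert np.all(res.consensus[iu][within[iu] & cosampled] == 1.0)
        assert np.all(res.consensus[iu][~within[iu] & cosampled] == 0.0)

    def test_single_iteration_entries_binary(self, rng):
        x, _ = two_clouds(rng, n=10)
        res = consensus_cluster(x, 2, iterations=1, seed=2)
        iu = np.triu_indices(20, k=1)
        vals = res.consensus[iu][res.co_sample_counts[iu] > 0]
        assert set(np.unique(vals)).issubset({0.0, 1.0})

    def test_matrix_matches_recount_from_logged_assignments(self, rng):
        x = rng.normal(size=(30, 4))
        res = consensus_cluster(x, 3, iterations=25, seed=5)
        n = 30
        co_cl = np.zeros((n, n))
        co_sa = np.zeros((n, n))
        for idx, labels in res.iteration_log:
            for a in range(len(idx)):
                for b in range(len(idx)):
                    co_sa[idx[a], idx[b]] += 1
                    if labels[a] == labels[b]:
                        co_cl[idx[a], idx[b]] += 1
        expected = np.where(co_sa > 0, co_cl / np.maximum(co_sa, 1), 0.0)
        np.fill_diagonal(expected, np.where(np.diag(co_sa) > 0, 1.0, 0.0))
        assert np.allclose(res.consensus, expected, atol=1e-12)

    def test_symmetry_and_range(self, rng):
        x = rng.normal(size=(25, 6))
        res = consensus_cluster(x, 4, iterations=20, seed=9)
        assert np.allclose(res.consensus, res.consensus.T)
        assert res.consensus.min() >= 0.0 and res.consensus.max() <= 1.0

    def test_subsample_smaller_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            consensus_cluster(rng.normal(size=(10, 2)), 9, subsample_fraction=0.5)

    def test_consensus_grows_with_separation(self, rng):
        """Mean within-cluster consensus increases monotonically along a
        separation grid."""
        means = []
        for sep in (0.5, 2.0, 6.0):
            x, truth = two_clouds(rng, n=15, sep=sep)
            res = consensus_cluster(x, 2, iterations=30, seed=11)
            within = truth[:, None] == truth[None, :]
            iu = np.triu_indices(30, k=1)
            mask = within[iu] & (res.co_sample_counts[iu] > 0)
            means.append(res.consensus[iu][mask].mean())
        assert means[0] < means[1] <= means[2]


class TestSelectK:
    def _fake_result(self, k, area):
        return ConsensusResult(
            k=k, consensus=np.eye(2), co_sample_counts=np.ones((2, 2), int),
            co_cluster_counts=np.ones((2, 2), int), cdf_area=area,
            labels=np.zeros(2, int),
        )

    def test_equal_areas_choose_first_k(self):
        res = [self._fake_result(k, 0.5) for k in range(2, 6)]
        sel = select_k(res)
        assert sel.chosen_k == 2
        assert sel.relative_area_changes[1] == 0.0

    def test_plateau_detected(self):
        areas = {2: 0.30, 3: 0.60, 4: 0.62, 5: 0.63}
        sel = select_k([self._fake_result(k, a) for k, a in areas.items()])
        assert sel.chosen_k == 3

    def test_no_plateau_warns_and_returns_max(self):
        areas = {2: 0.2, 3: 0.4, 4: 0.8}
        with pytest.warns(UserWarning):
            sel = select_k([self._fake_result(k, a) for k, a in areas.items()])
        assert sel.chosen_k == 4

    def test_non_contiguous_range_rejected(self):
        res = [self._fake_result(k, 0.5) for k in (2, 4, 5)]
        with pytest.raises(ValueError):
            select_k(res)

    def test_planted_k3_recovered(self):
        """Consensus CDF-area selection recovers a planted K=3."""
        cfg = three_cluster_config(seed=31, n_tumor=150, sep=3.0, noise=0.8)
        expr, _, truth = generate_cohort(cfg)
        x = subset_panel(expr, cfg.panel).values.T
        results = {
            k: consensus_cluster(x, k, iterations=40, seed=100 + k, restarts=5)
            for k in range(2, 7)
        }
        sel = select_k(results)
        assert sel.chosen_k == 3
        ari = adjusted_rand_score(truth.cluster.to_numpy(), results[3].labels)
        assert ari > 0.9


class TestCompleteLinkageOrder:
    def test_forced_merge_order(self):
        # d(a,b)=1, d(a,c)=d(b,c) large: a,b merge first, c sits at an end
        x = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        order = complete_linkage_order(x, z_scale=False)
        assert order.index(2) in (0, 2)
        ab = {order[0], order[1]} if order[0] != 2 else {order[1], order[2]}
        assert ab == {0, 1}

    def test_two_rows(self, rng):
        order = complete_linkage_order(rng.normal(size=(2, 5)), z_scale=False)
        assert sorted(order) == [0, 1]

    def test_merge_heights_match_naive_oracle(self, rng):
        """Linkage heights agree with a brute-force O(n^3) complete-linkage
        agglomeration."""
        from scipy.cluster.hierarchy import linkage

        x = rng.normal(size=(6, 4))
        z = linkage(x, method="complete", metric="euclidean")
        # naive agglomeration
        clusters = {i: [i] for i in range(6)}
        dist = cdist(x, x)
        heights = []
        next_id = 6
        while len(clusters) > 1:
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a >= b:
                        continue
                    h = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                    if best is None or h < best[0]:
                        best = (h, a, b)
            h, a, b = best
            heights.append(h)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        assert np.allclose(np.sort(z[:, 2]), np.sort(heights), atol=1e-10)

    def test_zero_variance_row_flagged(self):
        x = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            complete_linkage_order(x, z_scale=True)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage_order(np.ones((1, 3)))
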