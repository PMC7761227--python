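"""Spearman distance, PAM, consensus clustering, K selection, and IGP."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from histotype.cluster import (
    ConsensusCluster,
    PAM,
    cdf_delta_area,
    consensus_labels,
    igp,
    match_clusters,
    pam,
    pam_objective,
    spearman_distance,
)
from histotype.cluster import _pam_build, _pam_swap


def profile_blobs(n_per=20, n_clusters=3, p=40, noise=0.3, seed=0, profile_seed=None):
    """Clusters with distinct feature *profiles* (rank patterns), the
    structure a row-wise correlation distance can see. ``profile_seed``
    fixes the cluster profiles independently of the noise, so discovery
    and validation cohorts can share the same population structure."""
    prng = np.random.default_rng(seed if profile_seed is None else profile_seed)
    profiles = prng.normal(size=(n_clusters, p))
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [profiles[c] + noise * rng.normal(size=(n_per, p)) for c in range(n_clusters)]
    )
    labels = np.repeat(np.arange(n_clusters), n_per)
    return X, labels


class TestSpearmanDistance:
    def test_identical_rows_zero(self):
        X = np.tile(np.arange(5.0), (3, 1))
        X += np.array([[0.0], [0.0], [0.0]])
        D = spearman_distance(X)
        assert np.allclose(D, 0.0)

    def test_reversed_ranks_two(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        D = spearman_distance(X)
        assert D[0, 1] == pytest.approx(2.0)

    def test_matches_scipy_on_hand_matrix(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(4, 5))
        D = spearman_distance(X)
        for i in range(4):
            for j in range(4):
                rho = spearmanr(X[i], X[j]).statistic
                assert D[i, j] == pytest.approx(1 - rho, abs=1e-12)

    def test_midrank_ties_match_scipy(self):
        X = np.array([[1.0, 1.0, 2.0, 3.0, 3.0], [2.0, 1.0, 1.0, 3.0, 2.0]])
        D = spearman_distance(X)
        rho = spearmanr(X[0], X[1]).statistic
        assert D[0, 1] == pytest.approx(1 - rho, abs=1e-12)

    def test_constant_row_raises_with_name(self):
        import pandas as pd

        F = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["good", "flat"]
        )
        with pytest.raises(ValueError, match="flat"):
            spearman_distance(F)

    def test_symmetry_bounds_diagonal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 20))
        D = spearman_distance(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0 and D.max() <= 2

    def test_invariant_to_feature_permutation_and_common_monotone(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0.1, 5.0, size=(6, 15))
        D = spearman_distance(X)
        perm = rng.permutation(15)
        np.testing.assert_allclose(D, spearman_distance(X[:, perm]), atol=1e-12)
        np.testing.assert_allclose(D, spearman_distance(np.log(X)), atol=1e-12)


class TestPAM:
    def test_separated_1d_points(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])[:, None]
        D = np.abs(pts - pts.T)
        labels, medoids = pam(D, 2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_swap_never_worse_than_build(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            k = int(rng.integers(2, 5))
            pts = rng.normal(size=(n, 3))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            build = _pam_build(D, k)
            final = _pam_swap(D, build)
            assert pam_objective(D, final) <= pam_objective(D, build) + 1e-12

    def test_never_better_than_exhaustive_and_mostly_optimal(self):
        """PAM is a local search: it can never beat brute force, and on
        small instances it attains the optimum in the vast majority of
        cases (matching the canonical implementation's behavior)."""
        from itertools import combinations

        rng = np.random.default_rng(5)
        hits = 0
        trials = 120
        for _ in range(trials):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, min(4, n)))
            pts = rng.normal(size=(n, 2))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            _, med = pam(D, k)
            obj = pam_objective(D, med)
            best = min(pam_objective(D, c) for c in combinations(range(n), k))
            assert obj >= best - 1e-12
            hits += obj <= best + 1e-9
        assert hits / trials >= 0.9

    def test_invalid_k_raises(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            pam(D, 0)
        with pytest.raises(ValueError):
            pam(D, 4)

    def test_estimator_api(self):
        X, truth = profile_blobs(n_per=8, p=30, seed=6)
        est = PAM(n_clusters=3, metric="spearman").fit(X)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, est.labels_) == 1.0
        assert est.inertia_ > 0
        assert len(est.medoid_indices_) == 3
        # sklearn contract
        assert PAM(n_clusters=2).get_params()["n_clusters"] == 2


class TestConsensus:
    def test_single_replicate_binary_entries(self):
        X, _ = profile_blobs(n_per=5, p=20, seed=7)
        cc = ConsensusCluster(k_range=(2, 3, 4), n_resamples=1, random_state=0).fit(X)
        for M in cc.consensus_.values():
            assert set(np.unique(M)) <= {0.0, 1.0}

    def test_planted_blocks_crisp(self):
        X, truth = profile_blobs(n_per=20, p=40, noise=0.25, seed=8)
        cc = ConsensusCluster(k_range=(2, 3, 4), n_resamples=100, random_state=1).fit(X)
        M = cc.consensus_[3]
        within = M[np.ix_(truth == 0, truth == 0)]
        between = M[np.ix_(truth == 0, truth == 1)]
        assert within.mean() >= 0.95
        assert between.mean() <= 0.05
        assert cc.optimal_k_ == 3

    def test_consensus_matrix_invariants(self):
        X, _ = profile_blobs(n_per=7, p=25, seed=9)
        cc = ConsensusCluster(k_range=(2, 3, 4), n_resamples=25, random_state=2).fit(X)
        for M in cc.consensus_.values():
            assert np.allclose(M, M.T)
            assert np.allclose(np.diag(M), 1.0)
            assert M.min() >= 0 and M.max() <= 1

    def test_same_seed_reproducible(self):
        X, _ = profile_blobs(n_per=6, p=20, seed=10)
        a = ConsensusCluster(k_range=(2, 3, 4), n_resamples=20, random_state=3).fit(X)
        b = ConsensusCluster(k_range=(2, 3, 4), n_resamples=20, random_state=3).fit(X)
        for k in a.consensus_:
            np.testing.assert_array_equal(a.consensus_[k], b.consensus_[k])
        np.testing.assert_array_equal(a.labels_, b.labels_)

    def test_cdf_area_nondecreasing_in_k(self):
        X, _ = profile_blobs(n_per=10, p=30, seed=11)
        cc = ConsensusCluster(n_resamples=50, random_state=4).fit(X)
        areas = [cc.cdf_areas_[k] for k in sorted(cc.cdf_areas_)]
        assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))


class TestKSelection:
    def test_delta_area_pure_function_of_matrices(self):
        X, _ = profile_blobs(n_per=8, p=25, seed=12)
        cc = ConsensusCluster(n_resamples=30, random_state=5).fit(X)
        k1, areas1, deltas1 = cdf_delta_area(cc.consensus_, delta_min=0.1)
        k2, areas2, deltas2 = cdf_delta_area(
            {k: M.copy() for k, M in cc.consensus_.items()}, delta_min=0.1
        )
        assert k1 == k2 == cc.optimal_k_
        assert areas1 == areas2

    def test_null_deltas_follow_partition_ladder(self):
        """On structureless data PAM partitions are stable under
        resampling, so CDF areas track the deterministic-partition ladder
        A(K) ~ 1 - 1/K and the deltas its decay; no K carries true-K
        signal. Planted data instead pushes the delta at the true K above
        the ladder and the deltas beyond it below."""
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 60))
        cc = ConsensusCluster(n_resamples=100, random_state=6).fit(X)
        # delta of the deterministic balanced-partition ladder:
        # A(K) = 1 - 1/K  =>  delta(K) = 1 / (K (K - 2))
        ladder = {k: 1 / (k * (k - 2)) for k in (3, 4, 5, 6)}
        for k, expected in ladder.items():
            assert abs(cc.delta_areas_[k] - expected) < 0.05, k

        Xp, _ = profile_blobs(n_per=13, p=60, noise=0.3, seed=14)
        cp = ConsensusCluster(n_resamples=100, random_state=6).fit(Xp)
        assert cp.delta_areas_[3] > 1.2 * ladder[3]
        assert cp.delta_areas_[4] < 0.9 * ladder[4]
        assert cp.optimal_k_ == 3

    def test_needs_three_candidates(self):
        with pytest.raises(ValueError):
            cdf_delta_area({2: np.eye(4), 3: np.eye(4)})

    def test_consensus_labels_partition(self):
        X, truth = profile_blobs(n_per=10, p=30, seed=14)
        cc = ConsensusCluster(n_resamples=40, random_state=7).fit(X)
        labels = consensus_labels(cc.consensus_[3], 3)
        assert sorted(np.unique(labels)) == [1, 2, 3]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0


class TestIGP:
    def test_perfectly_reproduced_clusters(self):
        Xd, ld = profile_blobs(n_per=10, p=30, noise=0.2, seed=15)
        Xv, lv = profile_blobs(n_per=15, p=30, noise=0.2, seed=16, profile_seed=15)
        res = igp(Xd, ld, Xv, n_permutations=200, random_state=0)
        assert all(v == pytest.approx(1.0) for v in res.igp.values())
        assert all(p <= 0.05 for p in res.p_values.values())

    def test_validation_identical_to_discovery(self):
        Xd, ld = profile_blobs(n_per=8, p=30, noise=0.2, seed=17)
        res = igp(Xd, ld, Xd, n_permutations=10, random_state=1)
        np.testing.assert_array_equal(res.val_labels, ld)

    def test_randomized_labels_igp_matches_group_proportion(self):
        """Labels detached from the geometry (assigned uniformly at
        random) make the nearest-neighbor label an independent draw, so
        IGP(g) converges to the group proportion — the premise of the
        permutation null."""
        from histotype.cluster import _spearman_dist_to

        rng = np.random.default_rng(18)
        igps = {0: [], 1: []}
        for _ in range(30):
            Xv = rng.normal(size=(60, 25))
            labels = rng.choice([0, 1], p=[2 / 3, 1 / 3], size=60)
            D = _spearman_dist_to(Xv, Xv)
            np.fill_diagonal(D, np.inf)
            nn = np.argmin(D, axis=1)
            for g in (0, 1):
                members = labels == g
                if members.any():
                    igps[g].append(float((labels[nn[members]] == g).mean()))
        assert abs(np.mean(igps[0]) - 2 / 3) < 0.06
        assert abs(np.mean(igps[1]) - 1 / 3) < 0.06

    def test_small_cluster_raises(self):
        X = np.random.default_rng(19).normal(size=(5, 10))
        with pytest.raises(ValueError):
            igp(X, np.array([0, 0, 0, 0, 1]), X)

    def test_match_clusters_recovers_correspondence(self):
        Xd, ld = profile_blobs(n_per=10, p=30, noise=0.2, seed=20)
        Xv, lv = profile_blobs(n_per=12, p=30, noise=0.2, seed=21, profile_seed=20)
        lv_renamed = (lv + 1) % 3  # permute validation label names
        mapping = match_clusters(Xd, ld, Xv, lv_renamed)
        assert mapping == {1: 0, 2: 1, 0: 2}


class TestSpearmanProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 8), st.integers(3, 12)),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metric_axioms_and_scipy_agreement(self, X):
        # constant rows are rejected, not silently mishandled
        R = X - X.min(axis=1, keepdims=True)
        if np.any(R.max(axis=1) == 0):
            with pytest.raises(ValueError):
                spearman_distance(X)
            return
        D = spearman_distance(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.min() >= 0 and D.max() <= 2.0 + 1e-12
        rho = spearmanr(X[0], X[1]).statistic
        assert D[0, 1] == pytest.approx(1 - rho, abs=1e-9)
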