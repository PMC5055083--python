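"""Tests for pairwise Mahalanobis distances, consensus clustering and the
adaptive branch-pruning tree cut."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import mahalanobis, pdist, squareform
from sklearn.metrics import adjusted_rand_score

import metscreen as ms
from metscreen.consensus import co_cluster_with_reference
from metscreen.treecut import cut_tree_hybrid
from conftest import recovery_screen


def two_blob_matrix(n_per=10, sep=10.0, seed=0, p=4):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, p))
    b = rng.normal(sep, 1, size=(n_per, p))
    return pd.DataFrame(np.vstack([a, b]))


class TestPairwiseMahalanobis:
    def test_identical_rows_have_zero_distance(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]])
        d = ms.pairwise_mahalanobis(X, np.eye(2))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_reduces_to_euclidean(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        assert np.allclose(ms.pairwise_mahalanobis(X, np.eye(3)), pdist(X))

    def test_matches_per_pair_inverse_covariance_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        A = rng.normal(size=(5, 5))
        cov = A @ A.T + 5 * np.eye(5)
        d = squareform(ms.pairwise_mahalanobis(pd.DataFrame(X), cov))
        VI = np.linalg.inv(cov)
        for i in range(20):
            for j in range(i + 1, 20):
                assert d[i, j] == pytest.approx(
                    mahalanobis(X[i], X[j], VI), abs=1e-10
                )

    def test_singular_covariance_is_error(self):
        X = pd.DataFrame(np.random.default_rng(2).normal(size=(6, 3)))
        with pytest.raises(ValueError, match="positive definite"):
            ms.pairwise_mahalanobis(X, np.zeros((3, 3)))


class TestConsensusModel:
    def test_two_separated_blobs_give_block_consensus(self):
        X = two_blob_matrix()
        res = ms.ConsensusClusterModel(X, covariance=np.eye(4)).fit(
            n_iterations=50, seed=0
        )
        c = res.consensus.to_numpy()
        within_a = c[:10, :10][np.triu_indices(10, 1)]
        within_b = c[10:, 10:][np.triu_indices(10, 1)]
        across = c[:10, 10:]
        assert np.nanmin(within_a) > 0.9
        assert np.nanmin(within_b) > 0.9
        assert np.nanmax(across) < 0.1

    def test_single_iteration_no_removal_equals_direct_recomputation(self):
        X = two_blob_matrix(n_per=6, seed=3)
        res = ms.ConsensusClusterModel(X, covariance=np.eye(4)).fit(
            n_iterations=1, removal_range=(0.0, 0.0), n_depths=8, seed=0
        )
        # direct oracle: one Ward tree, 8 height-range cuts, mean co-membership
        from scipy.cluster.hierarchy import fcluster

        d = ms.pairwise_mahalanobis(X, np.eye(4))
        Z = linkage(d, method="ward")
        h = Z[:, 2]
        co = np.zeros((12, 12))
        for q in np.linspace(0.1, 0.8, 8):
            t = h.min() + q * (h.max() - h.min())
            lab = fcluster(Z, t, criterion="distance")
            co += lab[:, None] == lab[None, :]
        assert np.allclose(res.consensus.to_numpy(), co / 8.0)

    def test_fixed_seed_reproducible(self):
        X = two_blob_matrix(seed=4)
        m = ms.ConsensusClusterModel(X, covariance=np.eye(4))
        a = m.fit(n_iterations=20, seed=5)
        b = m.fit(n_iterations=20, seed=5)
        assert np.array_equal(
            a.consensus.to_numpy(), b.consensus.to_numpy(), equal_nan=True
        )

    def test_never_co_retained_pairs_reported_missing_not_zero(self):
        X = two_blob_matrix(n_per=5, seed=6)
        res = ms.ConsensusClusterModel(X, covariance=np.eye(4)).fit(
            n_iterations=1, removal_range=(0.4, 0.4), seed=1
        )
        c = res.consensus.to_numpy()
        dropped = res.co_retained.to_numpy()[np.triu_indices(10, 1)] == 0
        assert dropped.any()
        assert np.isnan(c[np.triu_indices(10, 1)][dropped]).all()
        # and the final-clustering distance treats them as maximally distant
        d = res.distance_matrix()
        assert not np.isnan(d).any()

    def test_monte_carlo_error_shrinks_with_iterations(self):
        X = two_blob_matrix(n_per=8, sep=3.0, seed=7)
        m = ms.ConsensusClusterModel(X, covariance=np.eye(4))

        def offdiag_sd(n_iter, seeds):
            mats = [
                m.fit(n_iterations=n_iter, seed=s).consensus.to_numpy()[
                    np.triu_indices(16, 1)
                ]
                for s in seeds
            ]
            return np.nanstd(np.stack(mats), axis=0).mean()

        sd50 = offdiag_sd(50, range(6))
        sd200 = offdiag_sd(200, range(6, 12))
        ratio = sd50 / sd200
        assert 1.3 < ratio < 3.2  # compatible with sqrt(4) = 2

    def test_invalid_parameters(self):
        X = two_blob_matrix()
        m = ms.ConsensusClusterModel(X, covariance=np.eye(4))
        with pytest.raises(ValueError):
            m.fit(n_iterations=0)
        with pytest.raises(ValueError):
            m.fit(removal_range=(0.0, 0.6))


class TestFinalClusters:
    def consensus_from_blocks(self, sizes):
        n = sum(sizes)
        c = np.zeros((n, n))
        start = 0
        for s in sizes:
            c[start : start + s, start : start + s] = 1.0
            start += s
        return ms.ConsensusResults(
            consensus=pd.DataFrame(c),
            co_retained=pd.DataFrame(np.full((n, n), 10)),
            params={},
        )

    def test_two_perfect_blocks_give_two_clusters(self):
        res = self.consensus_from_blocks([6, 4])
        labels = res.final_clusters()
        assert labels.nunique() == 2
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1

    def test_min_cluster_size_above_largest_leaves_all_unassigned(self):
        res = self.consensus_from_blocks([6, 4, 4])
        labels = res.final_clusters(min_cluster_size=8)
        assert (labels == 0).all()

    def test_three_planted_clusters_recovered(self):
        aris = []
        for seed in range(3):
            screen = recovery_screen(seed)
            normalized, _ = ms.quantify_and_normalize(screen, "linear")
            profile = ms.ScreenProfileModel(normalized).fit(seed=0)
            model = ms.ConsensusClusterModel(
                normalized, covariance=profile.estimate.covariance
            )
            labels = model.fit(n_iterations=100, seed=seed).final_clusters(
                deep_split=2
            )
            truth = screen.truth.cluster_label
            members = truth.index[truth > 0]
            aris.append(adjusted_rand_score(truth[members], labels.reindex(members)))
        assert min(aris) >= 0.9

    def test_labels_invariant_under_strain_permutation(self):
        X = two_blob_matrix(n_per=8, seed=9)
        X.index = [f"s{i}" for i in range(16)]
        res = ms.ConsensusClusterModel(X, covariance=np.eye(4)).fit(
            n_iterations=30, seed=2
        )
        labels = res.final_clusters()
        perm = np.random.default_rng(3).permutation(16)
        Xp = X.iloc[perm]
        resp = ms.ConsensusClusterModel(Xp, covariance=np.eye(4)).fit(
            n_iterations=30, seed=2
        )
        labp = resp.final_clusters()
        # same partition (up to label renaming)
        joined = pd.concat([labels.rename("a"), labp.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0


class TestTreeCutEdgeCases:
    def test_degenerate_equal_heights(self):
        d = np.ones((4, 4)) - np.eye(4)
        Z = linkage(squareform(d, checks=False), method="ward")
        labels = cut_tree_hybrid(Z, d, min_cluster_size=2)
        assert set(labels) <= {0, 1}

    def test_deep_split_out_of_range(self):
        d = np.ones((4, 4)) - np.eye(4)
        Z = linkage(squareform(d, checks=False), method="ward")
        with pytest.raises(ValueError):
            cut_tree_hybrid(Z, d, deep_split=7)


class TestCoClusterWithReference:
    def test_identical_external_profile_maps_to_its_strain(self, clustered_screen):
        res = clustered_screen["results"]
        z = res.z
        ext = pd.DataFrame([z.iloc[5]], index=["external"])
        _, assign = co_cluster_with_reference(z, ext, res.estimate.correlation)
        assert assign.loc["external", "nearest_strain"] == z.index[5]
        assert assign.loc["external", "distance"] == pytest.approx(0.0, abs=1e-10)

    def test_drug_mimic_profile_joins_its_planted_module(self, clustered_screen):
        # a rapamycin-like external profile built as its target module's mean
        # signature plus measurement noise must co-cluster with that module
        res = clustered_screen["results"]
        truth = clustered_screen["screen"].truth.cluster_label
        module = truth.index[truth == 1]
        rng = np.random.default_rng(0)
        mimic = res.z.loc[module].mean(axis=0) + rng.normal(0, 0.5, res.z.shape[1])
        ext = pd.DataFrame([mimic], index=["drug"])
        _, assign = co_cluster_with_reference(res.z, ext, res.estimate.correlation)
        assert assign.loc["drug", "nearest_strain"] in set(module)

    def test_dimension_mismatch_is_error(self, clustered_screen):
        res = clustered_screen["results"]
        ext = pd.DataFrame([[1.0, 2.0]], index=["bad"], columns=["x", "y"])
        with pytest.raises(ValueError, match="do not match"):
            co_cluster_with_reference(res.z, ext, res.estimate.correlation)
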