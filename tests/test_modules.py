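"""Module detection, eigenspecies, membership, trait links, consensus."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from biofilmnet import (
    SyntheticSpec,
    cluster_taxa,
    consensus_modules,
    correlation_matrix,
    cut_modules,
    generate_community,
    module_eigenspecies,
    module_membership,
    module_trait_correlation,
    soft_threshold_adjacency,
    topological_overlap,
)
from biofilmnet.modules import GREY
from tests.conftest import frame


def block_disstom(sizes, within=0.0, between=1.0):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for size in sizes:
        d[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(d, 0.0)
    taxa = [f"t{i}" for i in range(n)]
    return pd.DataFrame(d, index=taxa, columns=taxa)


def network_from_spec(**kwargs):
    matrix, truth = generate_community(SyntheticSpec(**kwargs))
    cor = correlation_matrix(matrix)
    return topological_overlap(soft_threshold_adjacency(cor, 6)), matrix, truth


class TestClusterTaxa:
    def test_blocks_merge_before_cross_block(self):
        diss = block_disstom([4, 4])
        link = cluster_taxa(diss)
        # first 6 merges happen at height 0 (inside blocks), last at 1
        assert np.allclose(link[:6, 2], 0.0)
        assert link[-1, 2] == pytest.approx(1.0)

    def test_three_leaf_average_linkage_heights(self):
        d = np.array([[0, 1.0, 4.0], [1.0, 0, 6.0], [4.0, 6.0, 0]])
        taxa = ["a", "b", "c"]
        link = cluster_taxa(pd.DataFrame(d, index=taxa, columns=taxa))
        # a-b merge at 1; c joins at mean(4, 6) = 5
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(5.0)

    def test_single_taxon_tree(self):
        diss = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        assert cluster_taxa(diss).shape == (0, 4)

    def test_asymmetric_input_rejected(self):
        d = frame([[0, 0.2], [0.4, 0]])
        d.columns = d.index
        with pytest.raises(ValueError, match="symmetric"):
            cluster_taxa(d)


class TestCutModules:
    def test_planted_two_blocks_recovered(self):
        diss = block_disstom([6, 6])
        partition = cut_modules(cluster_taxa(diss), list(diss.index),
                                min_module_size=5)
        truth = [0] * 6 + [1] * 6
        assert adjusted_rand_score(truth, partition.colors) == 1.0
        assert partition.module_colors() == ["turquoise", "blue"]

    def test_identical_taxa_single_module(self):
        diss = block_disstom([8])
        partition = cut_modules(cluster_taxa(diss), list(diss.index))
        assert (partition.colors == "turquoise").all()

    def test_min_size_above_branches_all_grey(self):
        diss = block_disstom([3, 3])
        partition = cut_modules(cluster_taxa(diss), list(diss.index),
                                min_module_size=5)
        assert (partition.colors == GREY).all()

    def test_min_module_size_below_two_rejected(self):
        diss = block_disstom([4])
        with pytest.raises(ValueError, match="min_module_size"):
            cut_modules(cluster_taxa(diss), list(diss.index), min_module_size=1)

    def test_colors_sorted_by_size(self):
        diss = block_disstom([5, 9, 7])
        partition = cut_modules(cluster_taxa(diss), list(diss.index))
        sizes = partition.sizes()
        assert sizes["turquoise"] == 9
        assert sizes["blue"] == 7
        assert sizes["brown"] == 5

    def test_partition_exhaustive_and_exclusive(self, two_module_network,
                                                two_module_community):
        net = two_module_network
        diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
        partition = cut_modules(cluster_taxa(diss), net.taxa)
        assert set(partition.colors.index) == set(net.taxa)
        assert partition.colors.notna().all()

    def test_recovery_ari_on_synthetic_communities(self):
        """Planted modules (w >= 0.7, >= 100 samples) are recovered with
        ARI >= 0.9 on average over seeds."""
        scores = []
        for seed in range(5):
            net, _, truth = network_from_spec(
                n_taxa=25, n_samples=120, module_sizes=(10, 10),
                background_taxa=5, within_module_cor=0.7, noise_sd=0.5,
                seed=seed,
            )
            diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
            partition = cut_modules(cluster_taxa(diss), net.taxa)
            scores.append(
                adjusted_rand_score(
                    truth.labels, partition.colors.loc[truth.labels.index]
                )
            )
        assert np.mean(scores) >= 0.9


class TestEigenspecies:
    def test_identical_profiles_fully_explained(self):
        m = frame(np.vstack([np.arange(6.0), np.arange(6.0)]))
        diss = block_disstom([2])
        partition = cut_modules(cluster_taxa(diss), list(m.index),
                                min_module_size=2)
        eig = module_eigenspecies(m, partition)
        color = partition.module_colors()[0]
        assert eig.variance_explained[color] == pytest.approx(1.0)
        z = (m.iloc[0] - m.iloc[0].mean()) / m.iloc[0].std()
        expected = z / np.linalg.norm(z)
        assert np.allclose(np.abs(eig.profiles[color]), np.abs(expected))

    def test_orthogonal_pair_splits_variance(self):
        m = frame(np.array([[1, -1, 1, -1], [1, 1, -1, -1]], dtype=float))
        diss = block_disstom([2])
        partition = cut_modules(cluster_taxa(diss), list(m.index),
                                min_module_size=2)
        eig = module_eigenspecies(m, partition)
        color = partition.module_colors()[0]
        assert eig.variance_explained[color] == pytest.approx(0.5)

    def test_tracks_latent_profile(self):
        net, matrix, truth = network_from_spec(
            n_taxa=5, n_samples=150, module_sizes=(5,),
            within_module_cor=0.9, noise_sd=0.1, seed=8,
        )
        diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
        # all five taxa form the single planted module: cut above the root
        partition = cut_modules(cluster_taxa(diss), net.taxa, cut_height=1.0)
        eig = module_eigenspecies(matrix, partition)
        color = partition.module_colors()[0]
        r = np.corrcoef(eig.profiles[color],
                        truth.latent_profiles.iloc[0])[0, 1]
        assert abs(r) >= 0.95

    def test_sign_convention_positive_mean_membership(self, two_module_network,
                                                      two_module_community):
        matrix, _ = two_module_community
        net = two_module_network
        diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
        partition = cut_modules(cluster_taxa(diss), net.taxa)
        eig = module_eigenspecies(matrix, partition)
        mm = module_membership(matrix, eig)
        for color in partition.module_colors():
            assert mm.loc[partition.members(color), color].mean() > 0

    def test_top_component_beats_any_single_member(self, two_module_network,
                                                   two_module_community):
        """Variance explained by the eigenspecies is at least that of the
        best single standardized member profile (full-SVD oracle)."""
        matrix, _ = two_module_community
        net = two_module_network
        diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
        partition = cut_modules(cluster_taxa(diss), net.taxa)
        eig = module_eigenspecies(matrix, partition)
        for color in partition.module_colors():
            z = matrix.loc[partition.members(color)].to_numpy()
            z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
            total = (np.linalg.svd(z, compute_uv=False) ** 2).sum()
            for row in z:
                u = row / np.linalg.norm(row)
                explained = ((z @ u) ** 2).sum() / total
                assert eig.variance_explained[color] >= explained - 1e-9


class TestModuleMembership:
    def test_own_module_membership_dominates(self, two_module_network,
                                             two_module_community):
        matrix, truth = two_module_community
        net = two_module_network
        diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
        partition = cut_modules(cluster_taxa(diss), net.taxa)
        eig = module_eigenspecies(matrix, partition)
        mm = module_membership(matrix, eig)
        for color in partition.module_colors():
            for taxon in partition.members(color):
                assert mm.loc[taxon].idxmax() == color

    def test_taxon_equal_to_eigenspecies_has_unit_membership(self):
        m = frame(np.vstack([np.arange(8.0), 2 * np.arange(8.0)]))
        diss = block_disstom([2])
        partition = cut_modules(cluster_taxa(diss), list(m.index),
                                min_module_size=2)
        eig = module_eigenspecies(m, partition)
        mm = module_membership(m, eig)
        assert np.allclose(mm.to_numpy(), 1.0)

    def test_noise_taxa_have_weak_membership(self):
        rng_scores = []
        for seed in range(3):
            net, matrix, truth = network_from_spec(
                n_taxa=15, n_samples=250, module_sizes=(10,),
                background_taxa=5, within_module_cor=0.9, noise_sd=0.1,
                seed=30 + seed,
            )
            diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
            partition = cut_modules(cluster_taxa(diss), net.taxa)
            eig = module_eigenspecies(matrix, partition)
            mm = module_membership(matrix, eig)
            noise_taxa = truth.labels.index[truth.labels == -1]
            rng_scores.append(mm.loc[noise_taxa].abs().to_numpy().mean())
        assert np.mean(rng_scores) < 0.3


class TestTraitCorrelation:
    def test_trait_equal_to_eigenspecies(self, two_module_network,
                                         two_module_community):
        matrix, _ = two_module_community
        net = two_module_network
        diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
        partition = cut_modules(cluster_taxa(diss), net.taxa)
        eig = module_eigenspecies(matrix, partition)
        color = partition.module_colors()[0]
        traits = pd.DataFrame({"self": eig.profiles[color]})
        assoc = module_trait_correlation(eig, traits)
        assert assoc.correlation.loc[color, "self"] == pytest.approx(1.0)
        assert assoc.p_value.loc[color, "self"] < 1e-100

    def test_planted_trait_loads_on_its_module(self, two_module_network,
                                               two_module_community):
        matrix, truth = two_module_community
        net = two_module_network
        diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
        partition = cut_modules(cluster_taxa(diss), net.taxa)
        eig = module_eigenspecies(matrix, partition)
        assoc = module_trait_correlation(eig, truth.trait_matrix)
        # module 0 taxa carry the loading; find its color
        module0_color = partition.colors[truth.labels.index[0]]
        assert assoc.correlation["trait_m0"].abs().idxmax() == module0_color

    def test_null_trait_p_values_uniform(self):
        """A pure-noise trait should be 'significant' in ~5% of modules."""
        hits = total = 0
        for seed in range(40):
            net, matrix, truth = network_from_spec(
                n_taxa=20, n_samples=60, module_sizes=(10, 10),
                within_module_cor=0.8, noise_sd=0.3, seed=200 + seed,
            )
            diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
            partition = cut_modules(cluster_taxa(diss), net.taxa)
            eig = module_eigenspecies(matrix, partition)
            assoc = module_trait_correlation(
                eig, truth.trait_matrix[["trait_noise"]]
            )
            hits += int((assoc.p_value["trait_noise"] < 0.05).sum())
            total += len(assoc.p_value)
        assert 0.0 <= hits / total < 0.15

    def test_too_few_samples_rejected(self):
        m = frame(np.vstack([np.arange(2.0), [5.0, 1.0]]))
        diss = block_disstom([2])
        partition = cut_modules(cluster_taxa(diss), list(m.index),
                                min_module_size=2)
        eig = module_eigenspecies(m, partition)
        traits = pd.DataFrame({"x": [0.1, 0.2]}, index=m.columns)
        with pytest.raises(ValueError, match="3 samples"):
            module_trait_correlation(eig, traits)


class TestConsensusModules:
    @staticmethod
    def _net(matrix, beta=6):
        return topological_overlap(
            soft_threshold_adjacency(correlation_matrix(matrix), beta)
        )

    def test_idempotent_on_identical_copies(self):
        matrix, _ = generate_community(
            SyntheticSpec(n_taxa=20, n_samples=150, module_sizes=(10, 10),
                          seed=1)
        )
        net = self._net(matrix)
        res = consensus_modules([net, self._net(matrix)])
        assert res.found
        diss = pd.DataFrame(net.disstom, index=net.taxa, columns=net.taxa)
        single = cut_modules(cluster_taxa(diss), net.taxa)
        assert res.partition.colors.equals(single.colors)

    def test_disjoint_modules_yield_no_consensus(self):
        a, _ = generate_community(
            SyntheticSpec(n_taxa=20, n_samples=150, module_sizes=(10,),
                          background_taxa=10, seed=3)
        )
        b, _ = generate_community(
            SyntheticSpec(n_taxa=20, n_samples=150, module_sizes=(10,),
                          background_taxa=10, seed=4)
        )
        b = b.iloc[::-1]
        b.index = a.index  # B's module sits on A's background taxa
        res = consensus_modules([self._net(a), self._net(b)])
        assert not res.found
        assert "no consensus" in res.message

    def test_only_shared_module_survives(self):
        a, _ = generate_community(
            SyntheticSpec(n_taxa=30, n_samples=150, module_sizes=(10, 10),
                          background_taxa=10, seed=7)
        )
        b, _ = generate_community(
            SyntheticSpec(n_taxa=30, n_samples=150, module_sizes=(10, 10),
                          background_taxa=10, seed=8)
        )
        shared = a.index[:10]
        b.iloc[0:10] = a.loc[shared].to_numpy()  # shared module
        swap = b.iloc[10:20].copy()
        b.iloc[10:20] = b.iloc[20:30].to_numpy()  # background where A has module 2
        b.iloc[20:30] = swap.to_numpy()  # B-specific module on A's background
        res = consensus_modules([self._net(a), self._net(b)])
        assert res.found
        colors = res.partition.module_colors()
        assert len(colors) == 1
        assert set(res.partition.members(colors[0])) == set(shared)

    def test_mismatched_taxa_rejected(self):
        a, _ = generate_community(
            SyntheticSpec(n_taxa=10, n_samples=50, module_sizes=(10,), seed=1)
        )
        b = a.copy()
        b.index = [f"other_{i}" for i in range(10)]
        with pytest.raises(ValueError, match="disagree"):
            consensus_modules([self._net(a), self._net(b)])

    def test_single_network_rejected(self):
        a, _ = generate_community(
            SyntheticSpec(n_taxa=10, n_samples=50, module_sizes=(10,), seed=1)
        )
        with pytest.raises(ValueError, match="at least 2"):
            consensus_modules([self._net(a)])
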