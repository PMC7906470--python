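import numpy as np
import pandas as pd
import pytest

from clusterbn.data import QUAL, QUANT, MixedDataset
from clusterbn.varclust import (Dendrogram, aggregation_levels,
                                cluster_homogeneity, cluster_variables,
                                correlation_ratio, cut_dendrogram, elbow_k,
                                medoid_representative, pcamix_first_pc,
                                representative_fit_quality, split_group)


def _quant_dataset(arr, names):
    df = pd.DataFrame(arr, columns=names)
    return MixedDataset(df, {c: QUANT for c in names})


class TestPcamix:
    def test_single_quantitative_variable_is_standardized(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        D = _quant_dataset(x[:, None], ["x"])
        rep = pcamix_first_pc(D)
        np.testing.assert_allclose(rep.scores, (x - x.mean()) / x.std(),
                                   atol=1e-12)
        assert rep.homogeneity == pytest.approx(1.0)

    def test_perfectly_correlated_pair_has_homogeneity_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        D = _quant_dataset(np.column_stack([x, -2 * x + 1]), ["u", "v"])
        assert pcamix_first_pc(D).homogeneity == pytest.approx(2.0)

    def test_homogeneity_equals_correlation_matrix_eigenvalue(self):
        """Oracle: largest eigenvalue of the sample correlation matrix."""
        rng = np.random.default_rng(5)
        X = rng.multivariate_normal(
            np.zeros(3), [[1, .8, .5], [.8, 1, .4], [.5, .4, 1]], size=400)
        D = _quant_dataset(X, ["a", "b", "c"])
        rep = pcamix_first_pc(D)
        lam = np.linalg.eigvalsh(np.corrcoef(X.T))[-1]
        assert rep.homogeneity == pytest.approx(lam, abs=1e-10)
        assert representative_fit_quality(rep, D) == pytest.approx(
            rep.homogeneity, abs=1e-8)

    def test_matches_plain_pca_on_quantitative_data(self):
        """All-quantitative PCAmix = PCA of standardized columns (up to sign)."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
        D = _quant_dataset(X, [f"x{i}" for i in range(5)])
        rep = pcamix_first_pc(D)
        Z = (X - X.mean(0)) / X.std(0)
        w, V = np.linalg.eigh(np.corrcoef(X.T))
        pc = Z @ V[:, -1]
        sign = np.sign(pc @ rep.scores)
        np.testing.assert_allclose(rep.scores, sign * pc, atol=1e-8)
        assert rep.homogeneity == pytest.approx(w[-1], abs=1e-8)

    def test_stored_loadings_reproduce_scores(self, mixed_small):
        rep = pcamix_first_pc(mixed_small)
        np.testing.assert_allclose(rep.project(mixed_small), rep.scores,
                                   atol=1e-8)
        assert abs(rep.scores.mean()) < 1e-10

    def test_mixed_homogeneity_identity(self, mixed_small):
        """First eigenvalue = sum of r^2 (quantitative) + eta^2 (qualitative)."""
        rep = pcamix_first_pc(mixed_small)
        assert representative_fit_quality(rep, mixed_small) == pytest.approx(
            rep.homogeneity, abs=1e-8)
        assert 0 <= rep.homogeneity <= len(rep.members)

    def test_single_level_qualitative_rejected(self):
        df = pd.DataFrame({"c": pd.Series(["a"] * 5, dtype=object)})
        D = MixedDataset(df, {"c": QUAL})
        with pytest.raises(ValueError, match="single level"):
            pcamix_first_pc(D)

    def test_zero_variance_quantitative_rejected(self):
        D = _quant_dataset(np.ones((5, 1)), ["x"])
        with pytest.raises(ValueError, match="[Zz]ero-variance"):
            pcamix_first_pc(D)


class TestMedoid:
    def test_singleton_group_is_its_own_medoid(self):
        x = np.array([3.0, 1.0, 2.0, 5.0])
        D = _quant_dataset(x[:, None], ["x"])
        rep = medoid_representative(D)
        np.testing.assert_allclose(rep.scores, (x - x.mean()) / x.std())

    def test_near_duplicates_beat_noise_variable(self):
        rng = np.random.default_rng(2)
        v1 = rng.normal(size=300)
        v2 = v1 + rng.normal(scale=0.1, size=300)
        v3 = rng.normal(size=300)
        D = _quant_dataset(np.column_stack([v1, v2, v3]), ["v1", "v2", "v3"])
        rep = medoid_representative(D)
        med = [ld["var"] for ld in rep.loadings][0]
        assert med in {"v1", "v2"}

    def test_tie_breaks_to_first_column(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        D = _quant_dataset(np.column_stack([x, x]), ["u", "v"])
        rep = medoid_representative(D)
        assert rep.loadings[0]["var"] == "u"


class TestClusterVariables:
    def test_duplicate_pair_merges_first_at_zero_height(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        arr = np.column_stack([rng.normal(size=200), x, rng.normal(size=200), x])
        D = _quant_dataset(arr, ["n1", "d1", "n2", "d2"])
        H = cluster_variables(D)
        first_l, first_r, h = H.merges[0]
        assert {H.leaves[first_l], H.leaves[first_r]} == {"d1", "d2"}
        assert h == pytest.approx(0.0, abs=1e-10)

    def test_merge_count_is_p_minus_one(self, two_block_dataset):
        D = two_block_dataset(seed=1)
        H = cluster_variables(D)
        assert len(H.merges) == D.n_vars - 1

    @pytest.mark.parametrize("seed", range(20))
    def test_two_blocks_recovered_at_k2(self, two_block_dataset, seed):
        D = two_block_dataset(seed=seed)
        g = cut_dendrogram(cluster_variables(D), 2)
        blocks = {frozenset(m) for m in g.groups.values()}
        assert blocks == {frozenset({"a1", "a2", "a3"}),
                          frozenset({"b1", "b2", "b3"})}

    def test_heights_nondecreasing_and_losses_nonnegative(self, two_block_dataset):
        H = cluster_variables(two_block_dataset(seed=3))
        heights = [h for _, _, h in H.merges]
        assert all(h >= -1e-12 for h in heights)
        assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))

    def test_merge_never_gains_homogeneity(self, two_block_dataset):
        """H(A u B) <= H(A) + H(B) for sampled cluster pairs."""
        D = two_block_dataset(seed=9, n=200)
        names = D.var_names
        for a, b in [("a1", "b1"), ("a1", "a2"), ("a2", "b3")]:
            ha = cluster_homogeneity(D, [a])
            hb = cluster_homogeneity(D, [b])
            hu = cluster_homogeneity(D, [a, b])
            assert hu <= ha + hb + 1e-10

    def test_fewer_than_two_variables_rejected(self):
        D = _quant_dataset(np.arange(5.0)[:, None], ["x"])
        with pytest.raises(ValueError):
            cluster_variables(D)

    def test_exclusion_removes_separated_variables(self, two_block_dataset):
        D = two_block_dataset(seed=0)
        H = cluster_variables(D, exclude={"a1"})
        assert "a1" not in H.leaves and len(H.leaves) == 5


class TestCutAndSplit:
    @pytest.fixture
    def tree(self, two_block_dataset):
        D = two_block_dataset(seed=2)
        return cluster_variables(D)

    def test_cut_k1_is_single_group(self, tree):
        g = cut_dendrogram(tree, 1)
        assert len(g.groups) == 1
        assert set(next(iter(g.groups.values()))) == set(tree.leaves)

    def test_cut_at_leaf_count_gives_singletons(self, tree):
        g = cut_dendrogram(tree, tree.n_leaves)
        assert all(len(m) == 1 for m in g.groups.values())

    def test_cut_out_of_range_rejected(self, tree):
        with pytest.raises(ValueError):
            cut_dendrogram(tree, 0)
        with pytest.raises(ValueError):
            cut_dendrogram(tree, tree.n_leaves + 1)

    def test_split_refines_partition_by_one(self, tree):
        g = cut_dendrogram(tree, 2)
        target = next(gid for gid, m in g.groups.items() if len(m) > 1)
        g2 = split_group(tree, g, target)
        assert len(g2.groups) == len(g.groups) + 1
        children = set(g2.groups) - set(g.groups)
        merged = set().union(*(g2.groups[c] for c in children))
        assert merged == set(g.groups[target])

    def test_split_singleton_rejected(self, tree):
        g = cut_dendrogram(tree, tree.n_leaves)
        gid = next(iter(g.groups))
        with pytest.raises(ValueError, match="unsplittable"):
            split_group(tree, g, gid)

    def test_split_pair_gives_singletons(self, tree):
        g = cut_dendrogram(tree, tree.n_leaves - 1)
        pair = next(gid for gid, m in g.groups.items() if len(m) == 2)
        g2 = split_group(tree, g, pair)
        assert all(len(m) == 1 for gid, m in g2.groups.items()
                   if gid not in g.groups)

    def test_cut_and_split_stay_antichain_cuts(self, tree):
        """Any produced grouping maps each group to a dendrogram node whose
        leaf set equals the group."""
        g = cut_dendrogram(tree, 3)
        for _ in range(3):
            splittable = [gid for gid, m in g.groups.items() if len(m) > 1]
            if not splittable:
                break
            g = split_group(tree, g, splittable[0])
            for gid, node in g.dendrogram_nodes.items():
                assert tree.node_leaves(node) == set(g.groups[gid])


class TestAggregationLevels:
    def test_levels_are_reversed_merge_heights(self, two_block_dataset):
        H = cluster_variables(two_block_dataset(seed=5))
        lv = aggregation_levels(H)
        assert list(lv["k"]) == list(range(2, 7))
        np.testing.assert_allclose(lv["height"],
                                   [h for _, _, h in H.merges][::-1])

    def test_two_block_structure_shows_drop_after_k2(self, two_block_dataset):
        H = cluster_variables(two_block_dataset(seed=6))
        lv = aggregation_levels(H).set_index("k")["height"]
        assert lv[2] > 5 * lv[3]
        assert elbow_k(H) == 2

    def test_minimal_tree(self):
        H = Dendrogram(["a", "b"], [(0, 1, 0.4)])
        lv = aggregation_levels(H)
        assert len(lv) == 1 and lv["height"][0] == 0.4


class TestCorrelationRatio:
    def test_between_group_variance_fraction(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        cats = np.array(["a", "a", "b", "b"], dtype=object)
        assert correlation_ratio(cats, y) == pytest.approx(1.0)
        assert correlation_ratio(np.array(["a", "b", "a", "b"], dtype=object),
                                 y) == pytest.approx(0.0)
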