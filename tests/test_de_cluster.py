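"""Unit tests for differential expression and response-group clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from zerogrowth.de_cluster import (
    Dendrogram,
    cut_clusters,
    hierarchical_cluster,
    nb_moment_de,
    pearson_distance,
    to_newick,
)
from zerogrowth.quantify import median_ratio_size_factors
from zerogrowth.syndata import SimulationParams, default_design, simulate_counts

from conftest import make_catalog


def _unit_sf(samples):
    return pd.Series(1.0, index=samples)


# --------------------------------------------------------------------- DE
class TestNbMomentDe:
    def test_identical_groups_lfc_zero_p_one(self):
        counts = pd.DataFrame(
            {"a1": [10, 4], "a2": [12, 6], "b1": [10, 4], "b2": [12, 6]},
            index=["g1", "g2"],
        )
        res = nb_moment_de(counts, _unit_sf(counts.columns), ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(res["log2_fold_change"], 0.0)
        assert (res["p_raw"] > 0.99).all()

    def test_hand_lfc_pseudocounted(self):
        # normalized group means 10 and 80 -> LFC = log2(80.5/10.5)
        counts = pd.DataFrame(
            {"a1": [10], "a2": [10], "b1": [80], "b2": [80]}, index=["g1"]
        )
        res = nb_moment_de(counts, _unit_sf(counts.columns), ["a1", "a2"], ["b1", "b2"])
        assert abs(res["log2_fold_change"].iloc[0] - np.log2(80.5 / 10.5)) < 1e-9

    def test_swapped_groups_negate_lfc(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(0, 100, (30, 6)),
                              columns=[f"s{i}" for i in range(6)])
        sf = _unit_sf(counts.columns)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        fwd = nb_moment_de(counts, sf, a, b)
        rev = nb_moment_de(counts, sf, b, a)
        assert np.allclose(fwd["log2_fold_change"], -rev["log2_fold_change"], atol=1e-12)
        assert np.allclose(fwd["p_raw"], rev["p_raw"], atol=1e-12)

    def test_all_zero_genes_dropped(self):
        counts = pd.DataFrame(
            {"a1": [0, 5], "a2": [0, 6], "b1": [0, 9], "b2": [0, 11]},
            index=["gz", "g1"],
        )
        res = nb_moment_de(counts, _unit_sf(counts.columns), ["a1", "a2"], ["b1", "b2"])
        assert list(res["gene_id"]) == ["g1"]

    def test_zero_group_has_finite_statistics(self):
        counts = pd.DataFrame(
            {"a1": [0], "a2": [0], "a3": [0], "b1": [3], "b2": [5], "b3": [4]},
            index=["g1"],
        )
        res = nb_moment_de(counts, _unit_sf(counts.columns),
                           ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert np.isfinite(res["standard_error"].iloc[0])
        assert res["standard_error"].iloc[0] > 0
        assert 0.0 <= res["p_raw"].iloc[0] <= 1.0

    def test_overlapping_groups_raise(self):
        counts = pd.DataFrame({"a": [1], "b": [1], "c": [1]}, index=["g"])
        with pytest.raises(ValueError, match="disjoint"):
            nb_moment_de(counts, _unit_sf(counts.columns), ["a", "b"], ["b", "c"])

    def test_single_replicate_raises(self):
        counts = pd.DataFrame({"a": [1], "b": [1], "c": [1]}, index=["g"])
        with pytest.raises(ValueError, match="replicates"):
            nb_moment_de(counts, _unit_sf(counts.columns), ["a"], ["b", "c"])

    def test_padj_at_least_praw(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.integers(0, 50, (100, 6)),
                              columns=[f"s{i}" for i in range(6)])
        res = nb_moment_de(counts, _unit_sf(counts.columns),
                           ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()

    def test_power_and_fdr_simulation(self):
        # planted 4-fold genes at phi = 0.05, 3 vs 3, moderately expressed:
        # >= 80% of planted genes recovered at p_adj < 0.05 and FDP among
        # discoveries <= 0.08, averaged over 20 seeds
        fdps, powers = [], []
        for seed in range(20):
            n_planted, n_null = 100, 1000
            cat = make_catalog(
                [1000] * (n_planted + n_null),
                gene_ids=[f"g{i}" for i in range(n_planted + n_null)],
                categories=["ribosomal"] * n_planted + ["other"] * n_null,
            )
            design = default_design(substrates=("none", "lactate"),
                                    sulfates=("plusS",), days=(36,), replicates=3)
            params = SimulationParams(
                n_genes=len(cat), dispersion=0.05, seed=4000 + seed,
                baseline_log_mean=-1.0,
                activity_factor={("lactate", "plusS"): 4.0},
                coupling_exponent={"ribosomal": 1.0, "other": 0.0},
                activity_replicate_sd=0.0,
            )
            cm = simulate_counts(cat, design, params)
            sf = median_ratio_size_factors(cm.counts)
            ga = [s for s in cm.counts.columns if s.startswith("none")]
            gb = [s for s in cm.counts.columns if s.startswith("lactate")]
            res = nb_moment_de(cm.counts, sf, ga, gb)
            sig = (res["p_adj"] < 0.05).to_numpy()
            planted = res["gene_id"].str.slice(1).astype(int) < n_planted
            fdps.append((sig & ~planted).sum() / max(sig.sum(), 1))
            powers.append((sig & planted).sum() / n_planted)
        assert np.mean(fdps) <= 0.08
        assert np.mean(powers) >= 0.80


# --------------------------------------------------------------- distance
class TestPearsonDistance:
    def test_duplicated_gene_distance_zero(self):
        v = pd.DataFrame([[1, 2, 3], [1, 2, 3], [9, 1, 5]],
                         index=["g1", "g1b", "g3"], dtype=float)
        d = pearson_distance(v)
        assert abs(d.loc["g1", "g1b"]) < 1e-12

    def test_anticorrelated_distance_two(self):
        v = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["g1", "g2"], dtype=float)
        d = pearson_distance(v)
        assert abs(d.loc["g1", "g2"] - 2.0) < 1e-12

    def test_three_gene_hand_matrix(self):
        # r(x, y) for rows [1,2,3], [1,3,2], [3,2,1]: 0.5, -1, -0.5
        v = pd.DataFrame([[1, 2, 3], [1, 3, 2], [3, 2, 1]],
                         index=["a", "b", "c"], dtype=float)
        d = pearson_distance(v)
        assert abs(d.loc["a", "b"] - 0.5) < 1e-12
        assert abs(d.loc["a", "c"] - 2.0) < 1e-12
        assert abs(d.loc["b", "c"] - 1.5) < 1e-12
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)
        assert ((d.values >= -1e-12) & (d.values <= 2 + 1e-12)).all()

    def test_constant_row_raises(self):
        v = pd.DataFrame([[1, 1, 1], [1, 2, 3]], index=["g1", "g2"], dtype=float)
        with pytest.raises(ValueError, match="constant"):
            pearson_distance(v)


# --------------------------------------------------------------- linkage
class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_zero(self):
        v = pd.DataFrame([[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 3, 0]],
                         index=["g1", "g2", "g3"], dtype=float)
        dendro = hierarchical_cluster(pearson_distance(v))
        first = dendro.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert abs(first[2]) < 1e-12

    def test_four_point_average_linkage_hand_trace(self):
        # d(g1,g2)=0.1, d(g3,g4)=0.2, cross = 0.9/1.0/1.1/1.2
        # merges: (g1,g2)@0.1, (g3,g4)@0.2, final @ mean(cross)=1.05
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9, 1.0],
             [0.1, 0.0, 1.1, 1.2],
             [0.9, 1.1, 0.0, 0.2],
             [1.0, 1.2, 0.2, 0.0]],
            index=list("abcd"), columns=list("abcd"),
        )
        dendro = hierarchical_cluster(d, linkage="average")
        heights = dendro.linkage[:, 2]
        assert np.allclose(heights, [0.1, 0.2, 1.05], atol=1e-9)
        assert {int(dendro.linkage[0, 0]), int(dendro.linkage[0, 1])} == {0, 1}
        assert {int(dendro.linkage[1, 0]), int(dendro.linkage[1, 1])} == {2, 3}

    def test_label_permutation_isomorphic(self):
        rng = np.random.default_rng(9)
        v = pd.DataFrame(rng.normal(size=(6, 8)), index=[f"g{i}" for i in range(6)])
        d = pearson_distance(v)
        perm = ["g3", "g0", "g5", "g1", "g4", "g2"]
        d2 = d.loc[perm, perm]
        h1 = np.sort(hierarchical_cluster(d).linkage[:, 2])
        h2 = np.sort(hierarchical_cluster(d2).linkage[:, 2])
        assert np.allclose(h1, h2, atol=1e-12)

    def test_average_linkage_heights_nondecreasing(self):
        rng = np.random.default_rng(10)
        v = pd.DataFrame(rng.normal(size=(15, 10)), index=[f"g{i}" for i in range(15)])
        dendro = hierarchical_cluster(pearson_distance(v))
        assert (np.diff(dendro.linkage[:, 2]) >= -1e-12).all()

    def test_asymmetric_input_raises(self):
        d = pd.DataFrame([[0.0, 0.5], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(d)

    def test_nan_distance_raises(self):
        d = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]],
                         index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="NaN"):
            hierarchical_cluster(d)


# --------------------------------------------------------------- cutting
class TestCutClusters:
    def _dendro(self, n=6, seed=11):
        rng = np.random.default_rng(seed)
        v = pd.DataFrame(rng.normal(size=(n, 8)), index=[f"g{i}" for i in range(n)])
        return hierarchical_cluster(pearson_distance(v))

    def test_k_equals_n_singletons(self):
        dendro = self._dendro(6)
        cl = cut_clusters(dendro, k=6)
        assert cl["cluster_id"].nunique() == 6
        assert (cl["linkage_height"] == 0.0).all()

    def test_k_one_single_cluster(self):
        dendro = self._dendro(6)
        cl = cut_clusters(dendro, k=1)
        assert cl["cluster_id"].nunique() == 1
        assert np.allclose(cl["linkage_height"], dendro.linkage[-1, 2])

    def test_two_block_structure_recovered_exactly(self):
        # two planted correlation blocks -> k=2 cut recovers the partition
        rng = np.random.default_rng(12)
        n_per, n_samples = 10, 30
        sig_a = rng.normal(size=n_samples)
        sig_b = rng.normal(size=n_samples)
        rows, ids = [], []
        for i in range(n_per):
            rows.append(sig_a + 0.15 * rng.normal(size=n_samples))
            ids.append(f"a{i}")
        for i in range(n_per):
            rows.append(sig_b + 0.15 * rng.normal(size=n_samples))
            ids.append(f"b{i}")
        v = pd.DataFrame(rows, index=ids)
        cl = cut_clusters(hierarchical_cluster(pearson_distance(v)), k=2)
        groups = cl.set_index("gene_id")["cluster_id"]
        assert groups[[f"a{i}" for i in range(n_per)]].nunique() == 1
        assert groups[[f"b{i}" for i in range(n_per)]].nunique() == 1
        assert groups["a0"] != groups["b0"]

    def test_k_out_of_range_raises(self):
        with pytest.raises(ValueError):
            cut_clusters(self._dendro(4), k=5)

    def test_exactly_one_of_k_or_height(self):
        dendro = self._dendro(4)
        with pytest.raises(ValueError):
            cut_clusters(dendro)
        with pytest.raises(ValueError):
            cut_clusters(dendro, k=2, height=0.5)

    def test_height_cut_matches_fcluster(self):
        dendro = self._dendro(8, seed=13)
        h = float(np.median(dendro.linkage[:, 2]))
        cl = cut_clusters(dendro, height=h)
        ref = hierarchy.fcluster(dendro.linkage, t=h, criterion="distance")
        # same partition up to relabeling
        ours = cl["cluster_id"].to_numpy()
        mapping = {}
        for a, b in zip(ours, ref):
            mapping.setdefault(a, b)
            assert mapping[a] == b


# ---------------------------------------------------------------- newick
class TestToNewick:
    def test_round_trip_leaf_set(self):
        dendro = TestCutClusters()._dendro(5, seed=14)
        nwk = to_newick(dendro)
        assert nwk.endswith(";")
        for label in dendro.labels:
            assert label in nwk

    def test_branch_lengths_nonnegative(self):
        import re
        dendro = TestCutClusters()._dendro(7, seed=15)
        nwk = to_newick(dendro)
        lengths = [float(x) for x in re.findall(r":([0-9.eE+-]+)", nwk)]
        assert all(x >= 0 for x in lengths)
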