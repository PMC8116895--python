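"""Aggregation, fold changes, ANOVA/Dunnett, PCA and heatmap ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliamp import expression as ex
from gliamp import synthetic_data as sd


@pytest.fixture(scope="module")
def noiseless(family):
    des = sd.default_expression_design(family.truth, seed=0, noise_cv=0.0)
    table, meta = sd.simulate_expression(des)
    return des, table, meta


class TestAggregate:
    def test_singleton_group_equals_variant_values(self, family, noiseless):
        _, table, meta = noiseless
        one = table.iloc[[0]]
        agg = ex.aggregate(one, family.truth, meta, ["genome"], [])
        assert agg["abundance"].iloc[0] == pytest.approx(one.sum().sum())

    def test_partition_conserves_grand_total(self, family, noiseless):
        _, table, meta = noiseless
        total = table.sum().sum()
        for keys in (["genome"], ["is_pseudogene"], ["genome", "is_pseudogene"]):
            agg = ex.aggregate(table, family.truth, meta, keys, ["genotype"])
            assert agg["abundance"].sum() == pytest.approx(total, rel=1e-9)

    def test_noiseless_per_genome_aggregate_matches_closed_form(self, family, noiseless):
        des, table, meta = noiseless
        agg = ex.aggregate(table, family.truth, meta, ["genome"], ["genotype", "n_level"])
        truth = family.truth
        dpa_sum = sum(des.dpa_profile.values()) * des.blocks
        for _, row in agg.iterrows():
            expected = 0.0
            for vid in truth[truth.genome == row["genome"]].index:
                x = des.baseline_abundance[vid]
                if vid in des.putative_variants:
                    x *= des.silencing_factor[row["genotype"]]
                if vid in des.responsive_variants and row["n_level"] == "high":
                    x *= des.n_response_factor[row["genotype"]]
                expected += x * dpa_sum
            assert row["abundance"] == pytest.approx(expected, rel=1e-9)

    def test_unannotated_variant_raises_with_ids(self, family, noiseless):
        _, table, meta = noiseless
        bad = table.rename(index={table.index[0]: "mystery"})
        with pytest.raises(ex.DesignError, match="mystery"):
            ex.aggregate(bad, family.truth, meta, ["genome"], [])


class TestFoldChange:
    def test_direct_ratio(self):
        agg = pd.DataFrame(
            {"genome": ["A", "A"], "n_level": ["high", "low"], "abundance": [400.0, 100.0]}
        )
        fc = ex.fold_change(agg)
        assert fc["fold_change"].iloc[0] == pytest.approx(4.0)

    def test_equal_groups_give_unity(self):
        agg = pd.DataFrame(
            {"genome": ["B", "B"], "n_level": ["high", "low"], "abundance": [55.0, 55.0]}
        )
        assert ex.fold_change(agg)["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_noiseless_design_recovers_fourfold_hordein_response(self, family, noiseless):
        """The D-hordein-promoter RNAi line responds fourfold to high N on the
        A and D subgenomes, exactly as designed."""
        des, table, meta = noiseless
        putative = family.truth[~family.truth.is_pseudogene]
        agg = ex.aggregate(
            table.loc[putative.index], family.truth, meta, ["genome"], ["genotype", "n_level"]
        )
        fc = ex.fold_change(agg)
        sub = fc[(fc.genotype == "rnai_hordein_promoter") & fc.genome.isin(["A", "D"])]
        assert np.allclose(sub["fold_change"], 4.0)
        wt = fc[(fc.genotype == "wild_type") & fc.genome.isin(["A", "D"])]
        assert np.allclose(wt["fold_change"], 2.5)
        glia = fc[(fc.genotype == "rnai_gliadin_promoter") & fc.genome.isin(["A", "D"])]
        assert np.allclose(glia["fold_change"], 1.0)


class TestCompareGroups:
    def test_identical_groups_null(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = ex.compare_groups({"a": v, "b": v, "c": v}, control="a", seed=0)
        assert rep.anova_f == pytest.approx(0.0, abs=1e-12)
        assert (rep.comparisons["p_adjusted"] > 0.99).all()

    def test_k1_reduces_to_two_sample_t_test(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        rep = ex.compare_groups({"ctrl": x, "trt": y}, control="ctrl", seed=1)
        t = stats.ttest_ind(y, x)
        assert rep.comparisons["p_adjusted"].iloc[0] == pytest.approx(t.pvalue, abs=0.005)

    def test_assumption_checks_always_reported(self):
        rng = np.random.default_rng(15)
        groups = {g: rng.normal(0, 1, 8) for g in "abc"}
        rep = ex.compare_groups(groups, control="a", seed=2)
        assert set(rep.shapiro) == {"a", "b", "c"}
        assert 0 <= rep.levene[1] <= 1

    def test_familywise_type_i_error_near_nominal(self):
        """Simulated global null: familywise rejection rate ~ alpha = 0.05."""
        rng = np.random.default_rng(16)
        n_rep, k, n = 800, 3, 6
        rejections = 0
        for i in range(n_rep):
            groups = {f"g{j}": rng.normal(0, 1, n) for j in range(k)}
            groups["ctrl"] = rng.normal(0, 1, n)
            rep = ex.compare_groups(groups, control="ctrl", seed=i)
            rejections += bool((rep.comparisons["p_adjusted"] <= 0.05).any())
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * se

    def test_small_group_rejected(self):
        with pytest.raises(ex.DesignError):
            ex.compare_groups({"a": [1.0], "b": [1.0, 2.0]}, control="a")

    def test_calibrated_design_contrast_pattern(self, family):
        """On the default noisy design, high-vs-low N is significant for the
        wild type and not for the gliadin-promoter RNAi line (the silencing
        pattern the design encodes), after removing the known developmental
        trajectory."""
        des = sd.default_expression_design(family.truth, seed=21, noise_cv=0.25)
        table, meta = sd.simulate_expression(des)
        totals = table.sum(axis=0)
        stage = meta["dpa"].map(des.dpa_profile)
        adj = totals / stage

        def pval(gt):
            groups = {
                nl: adj[meta[(meta.genotype == gt) & (meta.n_level == nl)].index].to_numpy()
                for nl in ("low", "high")
            }
            return ex.compare_groups(groups, control="low", seed=3).comparisons["p_adjusted"].iloc[0]

        assert pval("wild_type") <= 0.05
        assert pval("rnai_gliadin_promoter") > 0.05


class TestPca:
    def test_perfectly_correlated_pair_rank_one(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=12)
        X = pd.DataFrame({"x": a, "y": 3 * a + 1})
        res = ex.pca_with_supplementary(X)
        assert res.explained["PC1"] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(18)
        X = pd.DataFrame(rng.normal(size=(15, 5)))
        res = ex.pca_with_supplementary(X)
        assert res.explained.sum() == pytest.approx(1.0)

    def test_supplementary_copy_of_active_matches_its_loading(self):
        rng = np.random.default_rng(19)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        res = ex.pca_with_supplementary(X, supplementary=X[["b"]].rename(columns={"b": "sup"}))
        assert np.allclose(res.supplementary.loc["sup"], res.loadings.loc["b"], atol=1e-9)

    def test_supplementary_does_not_influence_axes(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        sup = pd.DataFrame(rng.normal(size=(10, 2)), columns=["p1", "p2"])
        a = ex.pca_with_supplementary(X)
        b = ex.pca_with_supplementary(X, supplementary=sup)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_explained_matches_correlation_eigenvalues(self):
        """Eigendecomposition oracle on the correlation matrix."""
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(40, 6)) @ np.diag([3, 2, 1, 1, 0.5, 0.2]))
        res = ex.pca_with_supplementary(X)
        corr = np.corrcoef(((X - X.mean()) / X.std(ddof=0)).to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert np.allclose(res.explained.to_numpy(), eig / eig.sum(), atol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame({"a": rng.normal(size=8), "b": rng.normal(size=8), "c": 5.0})
        with pytest.warns(UserWarning, match="constant"):
            res = ex.pca_with_supplementary(X)
        assert res.dropped == ["c"]


class TestHeatmapOrder:
    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(23)
        base = rng.normal(size=10)
        m = pd.DataFrame([base, base, rng.normal(size=10), rng.normal(size=10)],
                         index=["a", "a2", "b", "c"])
        res = ex.heatmap_order(m, cluster_columns=False)
        first_merge = res.row_linkage[0, :2].astype(int)
        assert set(first_merge) == {0, 1}
        assert res.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_merge_last(self):
        rng = np.random.default_rng(24)
        a = rng.normal(size=12)
        m = pd.DataFrame([a, a + rng.normal(0, 0.01, 12), -a], index=["a", "a2", "neg"])
        res = ex.heatmap_order(m, cluster_columns=False)
        assert res.row_linkage[-1, 2] > 1.5  # distance ~2 joins last

    def test_matches_naive_average_linkage_oracle(self):
        """Cophenetic distances equal a hand-rolled O(n^3) UPGMA on the same
        Spearman distance matrix."""
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(25)
        m = pd.DataFrame(rng.normal(size=(9, 14)))
        res = ex.heatmap_order(m, cluster_columns=False)
        d = ex._spearman_distance(m.to_numpy())
        coph = squareform(cophenet(res.row_linkage))
        oracle = _naive_upgma_cophenetic(d)
        assert np.allclose(coph, oracle, atol=1e-9)

    def test_zero_variance_row_warns_distance_one(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "x"])
        with pytest.warns(UserWarning, match="zero-variance"):
            d = ex._spearman_distance(m.to_numpy())
        assert d[0, 1] == pytest.approx(1.0)

    def test_row_scaling_zero_mean_unit_variance(self):
        rng = np.random.default_rng(26)
        m = pd.DataFrame(rng.normal(2, 5, size=(5, 20)))
        res = ex.heatmap_order(m)
        assert np.allclose(res.scaled.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(res.scaled.std(axis=1, ddof=0), 1.0, atol=1e-12)


def _naive_upgma_cophenetic(d: np.ndarray) -> np.ndarray:
    """Independent average-linkage oracle returning cophenetic distances."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        merged = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        new = max(max(clusters, default=-1), a, b) + 1
        for c in list(clusters):
            members = clusters[c]
            pairs = [d[i, j] for i in merged for j in members]
            key = (min(c, new), max(c, new))
            dist[key] = float(np.mean(pairs))
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        clusters[new] = merged
    return coph
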