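import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import wormwell as ww

from conftest import brute_force_holm, brute_force_welch


class TestWelchTTest:
    def test_identical_groups(self):
        t, df, p = ww.welch_t_test([3, 5, 7], [3, 5, 7])
        assert t == 0 and p == 1

    def test_equal_variance_case(self):
        t, df, p = ww.welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0)
        assert df == pytest.approx(8.0)
        to, dfo, po = brute_force_welch([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert p == pytest.approx(po, abs=1e-6)

    def test_separated_constants(self):
        t, df, p = ww.welch_t_test([0, 0, 0], [10, 10, 10])
        assert p == 0 and t == -np.inf

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ww.welch_t_test([1], [1, 2])

    def test_matches_formula_oracle_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(3, 12))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), rng.integers(3, 12))
            t, df, p = ww.welch_t_test(a, b)
            to, dfo, po = brute_force_welch(a, b)
            assert abs(t - to) < 1e-9 and abs(df - dfo) < 1e-9 and abs(p - po) < 1e-9


class TestMultipleTestCorrect:
    def test_single_p_unchanged(self):
        for method in ("bonferroni", "holm"):
            p_adj, rej = ww.multiple_test_correct([0.04], method)
            assert p_adj[0] == pytest.approx(0.04) and rej[0]

    def test_holm_worked_example(self):
        p_adj, rej = ww.multiple_test_correct([0.01, 0.02, 0.03], "holm")
        np.testing.assert_allclose(p_adj, [0.03, 0.04, 0.04])
        assert rej.all()

    def test_all_ones_no_rejections(self):
        _, rej = ww.multiple_test_correct([1.0] * 5, "bonferroni")
        assert not rej.any()

    def test_holm_matches_definition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            p_adj, _ = ww.multiple_test_correct(p, "holm")
            np.testing.assert_allclose(p_adj, brute_force_holm(p), atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_holm_rejections_contain_bonferroni_rejections(self, p):
        _, rej_b = ww.multiple_test_correct(p, "bonferroni")
        _, rej_h = ww.multiple_test_correct(p, "holm")
        assert (rej_b <= rej_h).all()  # step-down dominance


class TestCallHits:
    def test_single_gene_single_control(self):
        df = pd.DataFrame({
            "gene": ["control"] * 3 + ["kat-1"] * 3,
            "strain": "eri-1",
            "replicate": [1, 2, 3, 1, 2, 3],
            "value": [10.0, 11.0, 9.0, 30.0, 31.0, 29.0],
        })
        hits = ww.call_hits(ww.ScreenTable(df))
        assert len(hits) == 1
        row = hits.iloc[0]
        assert row["p_bonferroni"] == pytest.approx(row["p_raw"])
        assert row["fold_change"] == pytest.approx(3.0)
        assert row["significant"]

    def test_missing_control_raises(self):
        df = pd.DataFrame({"gene": ["g1"] * 3, "strain": "N2",
                           "replicate": [1, 2, 3], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="no 'control'"):
            ww.ScreenTable(df)

    def test_planted_hits_power_matches_noncentral_t(self):
        # empirical Bonferroni recovery vs the noncentral-t prediction, over
        # many strains so each family brings an independent control sample
        n_genes, n_strains, effect_sds, noise_sd = 30, 20, 3.0, 0.2
        hits_per_strain = {f"gene{g:04d}": float(np.exp(effect_sds * noise_sd))
                           for g in range(10)}
        spec = ww.ScreenSimSpec(
            n_genes=n_genes, strains=tuple(f"s{i}" for i in range(n_strains)),
            effects=hits_per_strain, noise_sd=noise_sd, seed=0,
        )
        recovered = planted = fp_families = 0
        n_seeds = 5
        for seed in range(n_seeds):
            table, truth = ww.generate_screen_table(spec, seed=seed)
            hits = ww.call_hits(table, alpha=0.05, method="bonferroni", log_scale=True)
            m = hits.merge(truth, on=["gene", "strain"])
            recovered += int(m.loc[m["is_hit"], "significant"].sum())
            planted += int(m["is_hit"].sum())
            fp_families += int(
                m[~m["is_hit"]].groupby("strain")["significant"].any().sum()
            )
        n_t = n_c = spec.n_replicates
        se2 = 1 / n_t + 1 / n_c
        ncp = effect_sds / np.sqrt(se2)
        dof = 2 * n_t - 2
        tcrit = sps.t.isf(0.05 / n_genes / 2, dof)
        predicted = sps.nct.sf(tcrit, dof, ncp) + sps.nct.cdf(-tcrit, dof, ncp)
        se = np.sqrt(predicted * (1 - predicted) / planted)
        # shared controls correlate the 10 tests within each strain family
        assert abs(recovered / planted - predicted) < 4 * se * np.sqrt(10)
        # family-wise error control at alpha, within binomial tolerance
        n_families = n_seeds * n_strains
        assert fp_families / n_families <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_families)

    def test_fold_change_direction(self):
        spec = ww.ScreenSimSpec(n_genes=3, effects={"gene0000": 2.0, "gene0001": 0.5},
                                noise_sd=0.01, seed=1)
        table, _ = ww.generate_screen_table(spec)
        hits = ww.call_hits(table).set_index("gene")
        assert hits.loc["gene0000", "fold_change"] == pytest.approx(2.0, rel=0.05)
        assert hits.loc["gene0001", "fold_change"] == pytest.approx(0.5, rel=0.05)

    def test_holm_p_never_exceeds_bonferroni(self):
        table, _ = ww.generate_screen_table(ww.ScreenSimSpec(n_genes=50, seed=2))
        hits = ww.call_hits(table)
        assert (hits["p_holm"] <= hits["p_bonferroni"] + 1e-12).all()
        assert (hits["p_raw"] <= hits["p_holm"] + 1e-12).all()


class TestAnovaBonferroni:
    def test_identical_groups(self):
        F, p, pairs = ww.anova_bonferroni([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert p > 0.9

    def test_two_groups_F_equals_t_squared(self):
        a, b = [1.0, 2.0, 4.0, 5.0], [3.0, 6.0, 7.0, 9.0]
        F, p, pairs = ww.anova_bonferroni([a, b])
        t = pairs.iloc[0]["t"]
        assert F == pytest.approx(t**2)
        assert p == pytest.approx(pairs.iloc[0]["p_raw"])

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(12)
        detected = 0
        for _ in range(10):
            g1 = rng.normal(0, 1, 8)
            g2 = rng.normal(0, 1, 8)
            g3 = rng.normal(5, 1, 8)
            _, _, pairs = ww.anova_bonferroni([g1, g2, g3])
            row = pairs[(pairs["i"] == 0) & (pairs["j"] == 2)].iloc[0]
            detected += row["p_adj"] < 0.05
        assert detected == 10

    def test_constant_groups_all_identical(self):
        F, p, pairs = ww.anova_bonferroni([[2, 2, 2], [2, 2, 2]])
        assert F == 0 and p == 1
        assert pairs.iloc[0]["p_adj"] == 1


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [1.0, 4.0, 16.0], "b": [1.0, 4.0, 16.0]})
        out = ww.log2_quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), np.log2(m.to_numpy()))

    def test_permuted_columns_share_sorted_values(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(1, 100, 50)
        m = pd.DataFrame({"a": a, "b": rng.permutation(a)})
        out = ww.log2_quantile_normalize(m)
        np.testing.assert_allclose(np.sort(out["a"]), np.sort(out["b"]))

    def test_worked_three_by_two(self):
        m = pd.DataFrame([[1, 2], [4, 8], [16, 4]], dtype=float)
        out = ww.log2_quantile_normalize(m)
        # log2 cols: [0,2,4] and [1,3,2]; sorted-row means [0.5, 2, 3.5]
        np.testing.assert_allclose(out.to_numpy(), [[0.5, 0.5], [2.0, 3.5], [3.5, 2.0]])

    def test_column_identity_property(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.uniform(0.5, 500, (40, 5)))
        out = ww.log2_quantile_normalize(m)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 5):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_nonpositive_cell_named(self):
        m = pd.DataFrame({"a": [1.0, -2.0], "b": [3.0, 4.0]})
        with pytest.raises(ValueError, match="non-positive"):
            ww.log2_quantile_normalize(m)


class TestKmeansSelectK:
    def test_three_separated_blobs(self):
        from sklearn.metrics import adjusted_rand_score

        m, labels = ww.generate_clustered_profiles(
            n_genes=60, n_conditions=5, k=3, separation=10, noise_sd=1, seed=2
        )
        res = ww.kmeans_select_k(m, range(1, 9), seed=2)
        assert res.k_selected == 3
        assert adjusted_rand_score(labels, res.assignments) == 1.0

    def test_single_blob_flags_no_local_minimum(self):
        rng = np.random.default_rng(20)
        m = pd.DataFrame(rng.normal(0, 1, (50, 4)))
        res = ww.kmeans_select_k(m, range(1, 8), seed=0)
        assert res.no_local_minimum

    def test_wss_non_increasing(self):
        m, _ = ww.generate_clustered_profiles(seed=3)
        res = ww.kmeans_select_k(m, range(1, 13), seed=3)
        wss = [res.wss_by_k[k] for k in sorted(res.wss_by_k)]
        assert all(a >= b - 1e-6 for a, b in zip(wss, wss[1:]))
        assert res.assignments.min() >= 1 and res.assignments.max() <= res.k_selected

    def test_reproducible_for_fixed_seed(self):
        m, _ = ww.generate_clustered_profiles(seed=4)
        r1 = ww.kmeans_select_k(m, range(1, 13), seed=7)
        r2 = ww.kmeans_select_k(m, range(1, 13), seed=7)
        assert r1.k_selected == r2.k_selected
        np.testing.assert_array_equal(r1.assignments, r2.assignments)

    def test_k_range_exceeding_rows_raises(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError, match="exceeds row count"):
            ww.kmeans_select_k(m, range(1, 10))


class TestHierarchicalClusterColumns:
    def test_duplicate_columns_adjacent(self):
        rng = np.random.default_rng(21)
        base = rng.normal(size=20)
        m = pd.DataFrame({"x": base, "y": rng.normal(size=20) + 30,
                          "x2": base, "z": rng.normal(size=20) - 30})
        order, _ = ww.hierarchical_cluster_columns(m)
        ix, ix2 = order.index("x"), order.index("x2")
        assert abs(ix - ix2) == 1

    def test_three_column_linkage_oracle(self):
        # distances: d(a,b)=1, d(a,c)=d(b,c)~10 -> a,b merge first
        m = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 0.0], "c": [10.0, 0.0]})
        order, Z = ww.hierarchical_cluster_columns(m)
        assert set(order[:2]) == {"a", "b"} or set(order[1:]) == {"a", "b"}
        assert Z[0, 2] == pytest.approx(1.0)  # first merge at distance 1
        assert Z[1, 2] == pytest.approx(10.0)  # complete linkage: max(9, 10)

    def test_two_columns_keep_input_order(self):
        m = pd.DataFrame({"a": [0.0, 1.0], "b": [5.0, 5.0]})
        order, _ = ww.hierarchical_cluster_columns(m)
        assert order == ["a", "b"]


class TestScaleAndPca:
    def test_zscore_columns(self):
        rng = np.random.default_rng(22)
        m = pd.DataFrame(rng.normal(5, 3, (30, 4)))
        out = ww.scale_rows_for_heatmap(m)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_affine_invariance(self):
        x = pd.DataFrame({"c": [1.0, 2.0, 5.0, 9.0]})
        y = 3.0 * x + 11.0
        np.testing.assert_allclose(
            ww.scale_rows_for_heatmap(x).to_numpy(), ww.scale_rows_for_heatmap(y).to_numpy()
        )

    def test_worked_column(self):
        x = pd.DataFrame({"c": [2.0, 4.0, 6.0, 8.0]})
        # mean 5, sd (ddof=1) = sqrt(20/3)
        expect = (np.array([2, 4, 6, 8]) - 5) / np.sqrt(20 / 3)
        np.testing.assert_allclose(ww.scale_rows_for_heatmap(x)["c"], expect)

    def test_zero_variance_column_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            ww.scale_rows_for_heatmap(pd.DataFrame({"c": [1.0, 1.0, 1.0]}))

    def test_planar_data_fully_captured(self):
        rng = np.random.default_rng(23)
        basis = rng.normal(size=(2, 6))
        coeff = rng.normal(size=(40, 2))
        m = pd.DataFrame(coeff @ basis)
        coords, _ = ww.pca_clusters(m)
        recon_var = np.var(coords, axis=0).sum()
        total_var = np.var(m.to_numpy() - m.to_numpy().mean(0), axis=0).sum()
        assert recon_var == pytest.approx(total_var, rel=1e-9)

    def test_two_planted_clusters_separate(self):
        rng = np.random.default_rng(24)
        sep = 8.0
        a = rng.normal(0, 1, (25, 5))
        b = rng.normal(0, 1, (25, 5))
        b[:, 0] += sep
        m = pd.DataFrame(np.vstack([a, b]))
        labels = np.array([1] * 25 + [2] * 25)
        _, separation = ww.pca_clusters(m, labels)
        assert separation >= sep / 2

    def test_constant_matrix_raises(self):
        with pytest.raises(ValueError, match="zero total variance"):
            ww.pca_clusters(pd.DataFrame(np.ones((5, 3))))


class TestDdctFoldChange:
    def test_textbook_doubling(self):
        assert ww.ddct_fold_change(1, 2, 3, 3, 2.0, 2.0) == pytest.approx(2.0)

    def test_identity(self):
        assert ww.ddct_fold_change(5, 5, 7, 7, 2.0, 2.0) == pytest.approx(1.0)

    def test_efficiency_corrected(self):
        # 1.9^2 / 2.0^1 = 1.805
        assert ww.ddct_fold_change(0, 2, 0, 1, 1.9, 2.0) == pytest.approx(1.805)

    def test_efficiency_range_enforced(self):
        with pytest.raises(ValueError):
            ww.ddct_fold_change(0, 1, 0, 1, 2.5, 2.0)
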