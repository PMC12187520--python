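"""Count normalization, the DE test, category calls, coverage/correlation
summaries, and clustering."""

import numpy as np
import pandas as pd
import pytest

from ntchrom.expression import (
    call_h3k4me3_categories,
    call_h3k27me3_categories,
    differential_expression,
    gene_set_overlap,
    genebody_coverage_fraction,
    genebody_expression_correlation,
    group_expression_test,
    kmeans_genebody_clusters,
    normalize_counts,
)
from ntchrom.genome import Interval
from ntchrom.simulate import planted_cluster_profiles


def bh_reference(p):
    """Quadratic-time Benjamini-Hochberg step-up: p_adj_i = min over j with
    p_j >= p_i of m * p_j / rank_j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for k in range(m - 1, -1, -1):
        i = order[k]
        running_min = min(running_min, m * p[i] / (k + 1))
        adj[i] = running_min
    return adj


class TestNormalizeCounts:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        sf, norm = normalize_counts(counts)
        np.testing.assert_allclose(sf, 1.0)
        np.testing.assert_allclose(norm, counts)

    def test_doubled_column_factor_two(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf, _ = normalize_counts(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_median_of_ratios_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.integers(1, 500, (30, 4)), columns=list("abcd"))
        sf, _ = normalize_counts(counts)
        mat = counts.to_numpy(float)
        geo = np.exp(np.mean(np.log(mat), axis=1))
        for j, col in enumerate("abcd"):
            assert sf[col] == pytest.approx(np.median(mat[:, j] / geo))

    def test_fallback_warns_without_all_nonzero_gene(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.warns(UserWarning, match="total-count"):
            normalize_counts(counts)


class TestDifferentialExpression:
    def test_identical_groups_zero_fc_and_p_one(self):
        counts = pd.DataFrame(np.tile([[10], [100], [50]], (1, 3)), columns=list("abc"))
        de = differential_expression(counts, counts.copy())
        np.testing.assert_allclose(de["log2fc"], 0.0)
        np.testing.assert_allclose(de["p_value"], 1.0)

    def test_planted_fc8_power(self):
        # 50 planted FC=8 genes among 500 (normalization must see a mostly
        # unchanged background), dispersion 0.01, 3 vs 3 replicates
        rng = np.random.default_rng(0)
        size = 100.0
        mu_a = np.r_[np.full(50, 8000.0), np.full(450, 1000.0)]
        mu_b = np.full(500, 1000.0)
        a = pd.DataFrame(rng.negative_binomial(size, size / (size + mu_a[:, None]), (500, 3)))
        b = pd.DataFrame(rng.negative_binomial(size, size / (size + mu_b[:, None]), (500, 3)))
        de = differential_expression(a, b)
        assert (de["p_adj"].iloc[:50] < 0.01).mean() >= 0.90
        assert de["log2fc"].iloc[:50].median() == pytest.approx(3.0, abs=0.15)

    def test_bh_textbook_example_via_padj(self):
        # p = (0.01, 0.02, 0.03, 0.04), m = 4 -> all adjusted to 0.04
        np.testing.assert_allclose(bh_reference([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(100))
    def test_padj_matches_reference_step_up(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        a = pd.DataFrame(rng.integers(1, 400, (n, 3)))
        b = pd.DataFrame(rng.integers(1, 400, (n, 3)))
        de = differential_expression(a, b)
        np.testing.assert_allclose(de["p_adj"], bh_reference(de["p_value"]), rtol=1e-10)

    def test_padj_dominates_p(self):
        rng = np.random.default_rng(3)
        a = pd.DataFrame(rng.integers(1, 400, (40, 3)))
        b = pd.DataFrame(rng.integers(1, 400, (40, 3)))
        de = differential_expression(a, b)
        assert (de["p_adj"] >= de["p_value"] - 1e-12).all()

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"a": [1, 2]})
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(counts, counts)


def _de_frame(log2fc, p_adj):
    return pd.DataFrame(
        {"base_mean": 100.0, "log2fc": log2fc, "p_value": p_adj, "p_adj": p_adj},
        index=[f"g{i}" for i in range(len(log2fc))],
    )


class TestCategoryCalls:
    def test_ob_rule(self):
        de = _de_frame([3.0], [1e-4])
        wnt = pd.Series([6000.0], index=de.index)
        wnf = pd.Series([2000.0], index=de.index)
        out = call_h3k4me3_categories(de, wnt, wnf)
        assert out["category"].tolist() == ["obH3K4me3"]

    def test_equal_widths_not_called(self):
        de = _de_frame([3.0], [1e-4])
        w = pd.Series([2000.0], index=de.index)
        out = call_h3k4me3_categories(de, w, w.copy())
        assert out["category"].tolist() == ["none"]

    def test_us_rule_and_exclusivity(self):
        de = _de_frame([-3.0, 3.0], [1e-4, 1e-4])
        wnt = pd.Series([400.0, 8000.0], index=de.index)
        wnf = pd.Series([6000.0, 400.0], index=de.index)
        out = call_h3k4me3_categories(de, wnt, wnf)
        assert out["category"].tolist() == ["usH3K4me3", "obH3K4me3"]
        assert not ((out["category"] == "obH3K4me3") & (out["category"] == "usH3K4me3")).any()

    def test_ue_rule(self):
        de = _de_frame([-3.0], [1e-5])
        out = call_h3k27me3_categories(de, pd.Series([2.0], index=de.index), pd.Series([0.0], index=de.index))
        assert out["category"].tolist() == ["ueH3K27me3"]

    def test_zero_k27_delta_never_called(self):
        de = _de_frame([-5.0, 5.0], [1e-9, 1e-9])
        k = pd.Series([1.0, 1.0], index=de.index)
        out = call_h3k27me3_categories(de, k, k.copy())
        assert (out["category"] == "none").all()

    def test_od_rule(self):
        de = _de_frame([3.0], [1e-5])
        out = call_h3k27me3_categories(de, pd.Series([0.0], index=de.index), pd.Series([2.0], index=de.index))
        assert out["category"].tolist() == ["odH3K27me3"]

    @pytest.mark.parametrize("seed", range(20))
    def test_ob_us_and_ue_od_disjoint_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        de = _de_frame(rng.normal(0, 3, n), rng.random(n) ** 3)
        wnt = pd.Series(rng.integers(0, 9000, n).astype(float), index=de.index)
        wnf = pd.Series(rng.integers(0, 9000, n).astype(float), index=de.index)
        k4 = call_h3k4me3_categories(de, wnt, wnf)
        k27 = call_h3k27me3_categories(de, wnt / 1000, wnf / 1000)
        assert not ((k4["category"] == "obH3K4me3") & (k4["category"] == "usH3K4me3")).any()
        # sign of log2fc alone separates ob/us and ue/od
        assert set(k4.loc[de["log2fc"] > 0, "category"]) <= {"obH3K4me3", "none"}
        assert set(k27.loc[de["log2fc"] > 0, "category"]) <= {"odH3K27me3", "none"}


class TestGeneSetOverlap:
    def test_in_paper_arithmetic(self):
        a = {f"g{i}" for i in range(415)}
        b = {f"g{i}" for i in range(260)} | {f"x{i}" for i in range(500)}
        n_a, n_b, n_int, pct = gene_set_overlap(a, b)
        assert (n_a, n_int, pct) == (415, 260, 62.65)

    def test_disjoint_zero(self):
        assert gene_set_overlap({"a"}, {"b"})[3] == 0.0

    def test_subset_hundred(self):
        assert gene_set_overlap({"a", "b"}, {"a", "b", "c"})[3] == 100.0

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError):
            gene_set_overlap(set(), {"a"})


class TestGenebodyCoverage:
    bodies = [Interval("c", 1000, 2000), Interval("c", 5000, 6000)]

    def test_full_coverage(self):
        assert genebody_coverage_fraction([Interval("c", 0, 10_000)], self.bodies) == 1.0

    def test_no_coverage(self):
        assert genebody_coverage_fraction([Interval("c", 3000, 4000)], self.bodies) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_bp_mask_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def rand_ivs(k):
            out = []
            for _ in range(k):
                s = int(rng.integers(0, 9000))
                out.append(Interval("c", s, s + int(rng.integers(1, 900))))
            return out

        domains, bodies = rand_ivs(6), rand_ivs(4)
        dom_mask = np.zeros(10_000, bool)
        body_mask = np.zeros(10_000, bool)
        for iv in domains:
            dom_mask[iv.start : iv.end] = True
        for iv in bodies:
            body_mask[iv.start : iv.end] = True
        oracle = (dom_mask & body_mask).sum() / body_mask.sum()
        assert genebody_coverage_fraction(domains, bodies) == pytest.approx(oracle, rel=1e-12)


class TestGenebodyExpressionCorrelation:
    def test_perfect_positive_and_negative(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert genebody_expression_correlation(x, x * 2 + 1) == pytest.approx(1.0)
        assert genebody_expression_correlation(x, -x) == pytest.approx(-1.0)

    def test_fixture_matches_hand_pearson(self):
        x = pd.Series([1.0, 4.0, 2.0, 8.0, 5.0], index=list("abcde"))
        y = pd.Series([2.0, 3.0, 1.0, 9.0, 4.0], index=list("abcde"))
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert genebody_expression_correlation(x, y) == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_is_nan(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert np.isnan(genebody_expression_correlation(x, y))


class TestKmeansClusters:
    def test_planted_clusters_recovered_exactly(self):
        profiles, labels = planted_cluster_profiles(n_genes=120, k=3, seed=0)
        from sklearn.metrics import adjusted_rand_score

        called = kmeans_genebody_clusters(profiles, k=3, seed=0)
        assert adjusted_rand_score(labels, called) == 1.0

    def test_k_one_single_label(self):
        profiles, _ = planted_cluster_profiles(n_genes=10, k=2, seed=1)
        assert set(kmeans_genebody_clusters(profiles, k=1, seed=0)) == {0}

    def test_duplicate_rows_share_cluster(self):
        mat = pd.DataFrame([[1.0, 5.0, 1.0]] * 3 + [[9.0, 0.0, 4.0]] * 3, index=list("abcdef"))
        labels = kmeans_genebody_clusters(mat, k=2, seed=0)
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]

    def test_deterministic_relabeling(self):
        profiles, _ = planted_cluster_profiles(n_genes=60, k=3, seed=2)
        l1 = kmeans_genebody_clusters(profiles, k=3, seed=0)
        l2 = kmeans_genebody_clusters(profiles, k=3, seed=0)
        assert (l1 == l2).all()

    def test_k_exceeding_genes_rejected(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["a"])
        with pytest.raises(ValueError):
            kmeans_genebody_clusters(mat, k=2)


class TestGroupExpressionTest:
    def test_identical_vectors(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        mean_a, mean_b, p = group_expression_test({"a", "b", "c"}, x, x.copy())
        assert mean_a == mean_b == pytest.approx(2.0)
        assert p == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        idx = [f"g{i}" for i in range(50)]
        a = pd.Series(rng.normal(10, 0.5, 50), index=idx)
        b = pd.Series(rng.normal(2, 0.5, 50), index=idx)
        _, _, p = group_expression_test(set(idx), a, b)
        assert p < 1e-6

    def test_four_gene_fixture_matches_textbook_t(self):
        from scipy import stats

        a = pd.Series([3.0, 5.0, 4.0, 6.0], index=list("abcd"))
        b = pd.Series([2.0, 1.0, 3.0, 2.0], index=list("abcd"))
        va, vb = a.var(ddof=1), b.var(ddof=1)
        sp = np.sqrt(((3 * va) + (3 * vb)) / 6)  # pooled over n1+n2-2 = 6 df
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(0.5))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=6)
        _, _, p = group_expression_test(set("abcd"), a, b)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_tiny_set_rejected(self):
        x = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            group_expression_test({"a"}, x, x)
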