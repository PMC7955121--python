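import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from persister_rx import markers, simulate
from persister_rx.io import ConfigError, ExpressionMatrix


def _matrix_with_nfeatures(nfeats, n_genes=10):
    """One cell per requested detected-gene count."""
    vals = np.zeros((n_genes, len(nfeats)))
    for j, k in enumerate(nfeats):
        vals[:k, j] = 1
    return ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)], [f"c{j}" for j in range(len(nfeats))], vals
    )


class TestFilterCells:
    def test_threshold_arithmetic(self):
        m = _matrix_with_nfeatures([2, 5, 9], n_genes=10)
        kept = markers.filter_cells(m, 3, 8)
        assert kept.obs_ids == ["c1"]
        assert kept.gene_ids == m.gene_ids  # gene universe unchanged

    def test_identity_range(self, tiny_counts):
        kept = markers.filter_cells(tiny_counts, 0, 10**9)
        assert kept.obs_ids == tiny_counts.obs_ids

    def test_survivors_match_columnwise_nonzero_oracle(self):
        cfg = simulate.ScrnaSimConfig(n_genes=300, cluster_sizes=[40, 40], seed=8)
        m, _, _ = simulate.simulate_scrna(cfg)
        lo, hi = 100, 200
        kept = markers.filter_cells(m, lo, hi)
        nnz = (m.dense() > 0).sum(axis=0)
        assert kept.n_obs == int(((nnz >= lo) & (nnz <= hi)).sum())

    def test_bad_range_and_empty_result(self, tiny_counts):
        with pytest.raises(ConfigError, match="min_genes"):
            markers.filter_cells(tiny_counts, 5, 2)
        with pytest.raises(ConfigError, match="no cells"):
            markers.filter_cells(tiny_counts, 100, 200)


class TestLogNormalize:
    def test_formula(self):
        vals = np.array([[100.0], [9900.0]])
        m = ExpressionMatrix(["A", "B"], ["c1"], vals)
        out = markers.lognormalize(m, scale_factor=1e4)
        assert out.dense()[0, 0] == pytest.approx(np.log(101))

    def test_zeros_stay_zero_and_columns_sum_to_scale(self, tiny_counts):
        out = markers.lognormalize(tiny_counts, scale_factor=1e4).dense()
        assert (out[tiny_counts.dense() == 0] == 0).all()
        col_sums = np.expm1(out).sum(axis=0)
        assert np.allclose(col_sums, 1e4)

    def test_monotone_within_cell(self):
        vals = np.array([[1.0], [2.0], [5.0], [50.0]])
        m = ExpressionMatrix(list("ABCD"), ["c1"], vals)
        out = markers.lognormalize(m).dense().ravel()
        assert (np.diff(out) > 0).all()

    def test_zero_total_cell_rejected(self):
        m = ExpressionMatrix(["A"], ["c1", "c2"], np.array([[1.0, 0.0]]))
        with pytest.raises(ConfigError, match="filter_cells"):
            markers.lognormalize(m)


def _lognorm_from_values(vals, clusters):
    n_genes, n_cells = vals.shape
    m = ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)], [f"c{j}" for j in range(n_cells)],
        np.asarray(vals, dtype=float), layer="lognorm",
    )
    ann = pd.DataFrame({"obs_id": m.obs_ids, "cluster": clusters})
    return m, ann


class TestFindMarkers:
    def test_wilcoxon_matches_exact_enumeration(self):
        """Small tie-free groups: reported p equals full enumeration of the
        rank-sum null distribution."""
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=(4, 12))
        x[0, :6] += 3.0  # make gene 0 a clear marker so it passes the filters
        clusters = ["a"] * 6 + ["b"] * 6
        m, ann = _lognorm_from_values(np.abs(x), clusters)
        out = markers.find_markers(m, ann, min_pct=0.0, min_log2fc=0.0, alpha=1.1)
        row = out[(out.gene == "g0") & (out.cluster == "a")].iloc[0]

        xi, xo = np.abs(x)[0, :6], np.abs(x)[0, 6:]
        u_obs = sum(a > b for a in xi for b in xo)
        pooled = np.concatenate([xi, xo])
        us = [
            sum(a > b for a in pooled[list(c)] for b in np.delete(pooled, list(c)))
            for c in itertools.combinations(range(12), 6)
        ]
        us = np.array(us)
        p_exact = min(1.0, 2 * min((us >= u_obs).mean(), (us <= u_obs).mean()))
        assert row.p == pytest.approx(p_exact, abs=1e-12)

    def test_bonferroni_is_direct_multiplication(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(1, 1, size=(20, 40))
        x[0, :20] *= 5
        m, ann = _lognorm_from_values(x, ["a"] * 20 + ["b"] * 20)
        out = markers.find_markers(m, ann, min_pct=0.0, min_log2fc=0.0, alpha=1.1)
        n_tests = 20 * 2
        assert np.allclose(out.p_adj, np.minimum(out.p * n_tests, 1.0))

    def test_label_symmetric(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(1, 1, size=(30, 60))
        x[:5, :30] *= 4
        labels = ["a"] * 30 + ["b"] * 30
        m, ann1 = _lognorm_from_values(x, labels)
        _, ann2 = _lognorm_from_values(x, ["b" if l == "a" else "a" for l in labels])
        out1 = markers.find_markers(m, ann1, min_pct=0.0, min_log2fc=0.0, alpha=1.1)
        out2 = markers.find_markers(m, ann2, min_pct=0.0, min_log2fc=0.0, alpha=1.1)
        sw = out2.copy()
        sw["cluster"] = sw["cluster"].map({"a": "b", "b": "a"})
        key = ["gene", "cluster"]
        merged = out1.merge(sw, on=key, suffixes=("_1", "_2"))
        assert len(merged) == len(out1)
        assert np.allclose(merged.p_1, merged.p_2)
        assert np.allclose(merged.log2fc_1, merged.log2fc_2)

    def test_unexpressed_gene_never_a_marker(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(1, 1, size=(10, 30))
        x[7] = 0.0
        m, ann = _lognorm_from_values(x, ["a"] * 15 + ["b"] * 15)
        out = markers.find_markers(m, ann, min_pct=0.01, min_log2fc=0.0, alpha=1.1)
        assert "g7" not in set(out.gene)

    def test_small_cluster_skipped(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(1, 1, size=(10, 23))
        m, ann = _lognorm_from_values(x, ["a"] * 2 + ["b"] * 10 + ["c"] * 11)
        out = markers.find_markers(m, ann, min_pct=0.0, min_log2fc=0.0, alpha=1.1)
        assert "a" not in set(out.cluster)

    def test_null_data_rarely_flagged(self):
        """Identical distributions: Bonferroni at 0.05 flags (almost) nothing."""
        cfg = simulate.ScrnaSimConfig(n_genes=500, cluster_sizes=[80, 80], seed=17)
        m, ann, _ = simulate.simulate_scrna(cfg)
        out = markers.find_markers(markers.lognormalize(m), ann)
        assert len(out) / 500 <= 0.05


class TestModuleScore:
    def test_self_subtraction_is_zero(self):
        rng = np.random.default_rng(6)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(8)], [f"c{j}" for j in range(5)],
            rng.gamma(1, 1, size=(8, 5)), layer="lognorm",
        )
        s = markers.module_score(m, m.gene_ids, n_bins=1, n_ctrl=100, seed=0)
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_shifted_cells_score_higher(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(1, 1, size=(60, 40))
        gene_set = [f"g{i}" for i in range(5)]
        x[:5, :20] += 2.0
        m = ExpressionMatrix(
            [f"g{i}" for i in range(60)], [f"c{j}" for j in range(40)], x, layer="lognorm"
        )
        s = markers.module_score(m, gene_set, n_bins=10, n_ctrl=20, seed=1)
        assert s.iloc[:20].mean() > s.iloc[20:].mean()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        m = ExpressionMatrix(
            [f"g{i}" for i in range(40)], [f"c{j}" for j in range(10)],
            rng.gamma(1, 1, size=(40, 10)), layer="lognorm",
        )
        s1 = markers.module_score(m, ["g0", "g1"], n_bins=4, seed=3)
        s2 = markers.module_score(m, ["g0", "g1"], n_bins=4, seed=3)
        assert (s1 == s2).all()

    def test_empty_effective_set_rejected(self):
        m = ExpressionMatrix(
            [f"g{i}" for i in range(30)], ["c1"], np.ones((30, 1)), layer="lognorm"
        )
        with pytest.raises(ConfigError):
            markers.module_score(m, ["nope"], n_bins=2)


class TestDotplot:
    def test_formulas(self):
        vals = np.array([[0.0, 2.0, 4.0, 6.0, 6.0, 6.0]])
        m = ExpressionMatrix(["g"], [f"c{j}" for j in range(6)], vals, layer="lognorm")
        ann = pd.DataFrame({"obs_id": m.obs_ids, "cluster": ["a"] * 3 + ["b"] * 3})
        out = markers.dotplot_stats(m, ann, ["g"], ["a", "b"])
        a = out[out.group == "a"].iloc[0]
        b = out[out.group == "b"].iloc[0]
        assert a.avg_exp == pytest.approx(2.0)
        assert a.pct_exp == pytest.approx(2 / 3)
        assert a.avg_exp_scaled == pytest.approx(2 / 8)
        assert b.avg_exp_scaled == pytest.approx(6 / 8)

    def test_absent_gene_all_zero(self):
        vals = np.zeros((1, 4))
        m = ExpressionMatrix(["g"], [f"c{j}" for j in range(4)], vals, layer="lognorm")
        ann = pd.DataFrame({"obs_id": m.obs_ids, "cluster": ["a", "a", "b", "b"]})
        out = markers.dotplot_stats(m, ann, ["g"], ["a", "b"])
        assert (out[["avg_exp", "pct_exp", "avg_exp_scaled"]].to_numpy() == 0).all()

    def test_unknown_group_rejected(self, tiny_counts):
        ann = pd.DataFrame({"obs_id": tiny_counts.obs_ids, "cluster": ["a"] * 4})
        with pytest.raises(ConfigError, match="unknown group"):
            markers.dotplot_stats(tiny_counts, ann, ["A"], ["a", "zz"])


class TestSilhouette:
    def test_distant_point_masses(self):
        emb = np.array([[0.0, 0.0]] * 5 + [[100.0, 0.0]] * 5)
        emb += np.random.default_rng(0).normal(0, 0.01, emb.shape)
        ann = pd.DataFrame({"obs_id": [f"c{i}" for i in range(10)],
                            "cluster": ["a"] * 5 + ["b"] * 5})
        rep = markers.silhouette(emb, ann)
        assert rep["mean_width"] > 0.99

    def test_coincident_points_width_zero(self):
        emb = np.zeros((6, 2))
        ann = pd.DataFrame({"obs_id": [f"c{i}" for i in range(6)],
                            "cluster": ["a"] * 3 + ["b"] * 3})
        rep = markers.silhouette(emb, ann)
        assert np.allclose(rep["per_cell_width"], 0.0)

    def test_matches_brute_force_on_toy_set(self):
        emb = np.array([[0, 0], [0, 1], [1, 0], [5, 5], [5, 6], [6, 5]], dtype=float)
        labels = ["a", "a", "a", "b", "b", "b"]
        ann = pd.DataFrame({"obs_id": [f"c{i}" for i in range(6)], "cluster": labels})
        rep = markers.silhouette(emb, ann)
        # direct O(n^2) formula
        d = np.sqrt(((emb[:, None] - emb[None]) ** 2).sum(-1))
        expected = []
        for i in range(6):
            own = [j for j in range(6) if labels[j] == labels[i] and j != i]
            other = [j for j in range(6) if labels[j] != labels[i]]
            a = np.mean(d[i, own])
            b = np.mean(d[i, other])
            expected.append((b - a) / max(a, b))
        assert np.allclose(rep["per_cell_width"], expected)
        assert rep["mean_width"] == pytest.approx(np.mean(expected))
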