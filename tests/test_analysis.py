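"""Normalization, PCA, clustering, markers, DE, pseudobulk contracts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from conftest import make_norm
from gliakit import analysis
from gliakit.analysis import (
    annotate_clusters,
    cluster_cells,
    differential_expression,
    find_markers_all,
    lognormalize,
    pca_embed,
    pseudobulk,
    pseudobulk_pca,
    subpopulation_proportions,
)
from gliakit.containers import CountMatrix


class TestLognormalize:
    def test_zero_count_maps_to_zero_and_scale(self):
        counts = np.array([[0, 10], [10000 - 10, 0], [10, 10]])
        m = CountMatrix(counts, ["a", "b", "c"], ["c1", "c2"])
        norm = lognormalize(m, 1e4)
        assert norm.values[0, 0] == 0.0
        # cell total 10000, count 10 -> ln(1 + 1e4*10/1e4) = ln(11)
        assert norm.values[2, 0] == pytest.approx(math.log(11))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (20, 15)) + 1
        m = CountMatrix(counts, [f"g{i}" for i in range(20)],
                        [f"c{i}" for i in range(15)])
        norm = lognormalize(m, 123.0)
        for i in range(20):
            for j in range(15):
                expected = math.log1p(123.0 * counts[i, j] / counts[:, j].sum())
                assert norm.values[i, j] == pytest.approx(expected)

    def test_zero_total_cell_rejected(self):
        counts = np.array([[1, 0], [1, 0]])
        m = CountMatrix(counts, ["a", "b"], ["c1", "c2"])
        with pytest.raises(ValueError, match="zero-total"):
            lognormalize(m)


class TestPcaEmbed:
    def test_separates_planted_populations(self, clean_sim):
        m, truth = clean_sim
        emb = pca_embed(lognormalize(m), n_pcs=10)
        labels = truth.cells["cell_type"].to_numpy()
        assert silhouette_score(emb.to_numpy(), labels) > 0

    def test_variance_non_increasing(self, clean_sim):
        m, _ = clean_sim
        emb = pca_embed(lognormalize(m), n_pcs=8).to_numpy()
        var = emb.var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_duplicated_cells_same_directions(self):
        rng = np.random.default_rng(1)
        values = rng.gamma(2, 1, (50, 40))
        norm = make_norm(values)
        dup = make_norm(
            np.hstack([values, values]),
            barcodes=[f"c{i}" for i in range(80)],
        )
        e1 = pca_embed(norm, n_pcs=3, n_hvg=50).to_numpy()
        e2 = pca_embed(dup, n_pcs=3, n_hvg=50).to_numpy()[:40]
        for k in range(3):
            r = np.corrcoef(e1[:, k], e2[:, k])[0, 1]
            assert abs(r) > 0.99  # identical up to sign

    def test_n_pcs_bound(self):
        norm = make_norm(np.random.default_rng(2).random((5, 4)))
        with pytest.raises(ValueError, match="n_pcs"):
            pca_embed(norm, n_pcs=4)


class TestClusterCells:
    def test_two_planted_types_two_clusters(self):
        rng = np.random.default_rng(3)
        emb = np.vstack(
            [rng.normal(0, 0.3, (60, 5)), rng.normal(3, 0.3, (60, 5))]
        )
        df = pd.DataFrame(emb, index=[f"c{i}" for i in range(120)])
        res = cluster_cells(df, resolution=0.5, seed=0)
        assert res.n_clusters == 2
        truth = np.repeat([0, 1], 60)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_planted_populations_recovered(self, subpop_sim):
        """Three glial types plus the SOD1-only state: ARI >= 0.9 against
        the full planted partition."""
        m, truth = subpop_sim
        emb = pca_embed(lognormalize(m), n_pcs=16)
        res = cluster_cells(emb, resolution=0.2, seed=0)
        labels = np.where(
            truth.cells["subpop"] == "none",
            truth.cells["cell_type"],
            truth.cells["subpop"],
        )
        ari = adjusted_rand_score(labels, res.labels)
        assert ari >= 0.9

    def test_cell_order_invariance_up_to_relabel(self):
        rng = np.random.default_rng(4)
        emb = np.vstack(
            [rng.normal(0, 0.3, (50, 4)), rng.normal(4, 0.3, (50, 4))]
        )
        df = pd.DataFrame(emb, index=[f"c{i}" for i in range(100)])
        perm = rng.permutation(100)
        df_p = df.iloc[perm]
        r1 = cluster_cells(df, resolution=0.5, seed=0)
        r2 = cluster_cells(df_p, resolution=0.5, seed=0)
        aligned = r2.labels.loc[df.index]
        assert adjusted_rand_score(r1.labels, aligned) == 1.0

    def test_labels_contiguous_from_one(self, clean_sim):
        m, _ = clean_sim
        emb = pca_embed(lognormalize(m), n_pcs=6)
        res = cluster_cells(emb, resolution=0.5, seed=1)
        assert sorted(res.labels.unique()) == list(range(1, res.n_clusters + 1))

    def test_too_few_cells_rejected(self):
        df = pd.DataFrame(np.random.default_rng(5).random((10, 3)))
        with pytest.raises(ValueError):
            cluster_cells(df, k_neighbors=20)


def exact_wilcoxon_p(x, y):
    """Exhaustive permutation two-sided p for the rank-sum statistic."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    stats = np.array(stats)
    return float(np.mean(np.abs(stats - mu) >= abs(obs - mu) - 1e-12))


class TestFindMarkers:
    def test_planted_marker_found(self, subpop_sim):
        m, truth = subpop_sim
        norm = lognormalize(m)
        clusters = pd.Series(
            pd.factorize(
                np.where(
                    truth.cells["subpop"] == "none",
                    truth.cells["cell_type"],
                    truth.cells["subpop"],
                )
            )[0] + 1,
            index=norm.barcodes,
        )
        table = find_markers_all(norm, clusters)
        # find the cluster holding the activated microglia
        sub_mask = (truth.cells["subpop"] == "activated_microglia").to_numpy()
        sub_cluster = clusters[sub_mask].mode()[0]
        markers = set(table.loc[table["cluster"] == sub_cluster, "gene"])
        assert {"Apoe", "Cst7", "Lpl", "Itgax"} <= markers

    def test_identically_distributed_gene_excluded(self):
        rng = np.random.default_rng(6)
        values = rng.gamma(2, 1, (20, 60))
        norm = make_norm(values)
        clusters = pd.Series(
            np.repeat([1, 2], 30), index=norm.barcodes
        )
        table = find_markers_all(norm, clusters, min_pct=0.1, min_log2fc=0.25)
        # no gene truly differs; markers table should be (near) empty and
        # nothing significant
        assert (table["p_adj"] < 0.05).sum() == 0

    def test_wilcoxon_p_matches_exact_permutation_oracle(self):
        x = np.array([1.2, 3.4, 0.5, 2.2])
        y = np.array([4.1, 5.9, 6.3, 7.0])
        from scipy.stats import mannwhitneyu

        p_scipy = mannwhitneyu(
            x[None, :], y[None, :], axis=1, alternative="two-sided"
        ).pvalue[0]
        assert p_scipy == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-9)

    def test_cluster_below_three_cells_rejected(self):
        values = np.random.default_rng(7).random((5, 10))
        norm = make_norm(values)
        clusters = pd.Series([1] * 8 + [2] * 2, index=norm.barcodes)
        with pytest.raises(ValueError, match="fewer than 3"):
            find_markers_all(norm, clusters)


class TestDifferentialExpression:
    def test_self_comparison_yields_no_flags(self, clean_sim):
        m, _ = clean_sim
        norm = lognormalize(m)
        mask = np.zeros(norm.n_cells, bool)
        mask[:50] = True
        de = differential_expression(norm, mask, mask)
        assert not de["significant"].any()
        np.testing.assert_allclose(de["log2FC"], 0.0, atol=1e-12)

    def test_welch_t_matches_closed_form(self):
        # {1,2,3} vs {4,5,6}: t = -3 / sqrt(2/3), df = 4
        values = np.array([[1.0, 2, 3, 4, 5, 6], [1, 1, 2, 1, 1, 2]])
        norm = make_norm(values)
        a = np.array([True] * 3 + [False] * 3)
        de = differential_expression(norm, a, ~a, min_cells_detected=0)
        t_expected = -3 / math.sqrt(2 / 3)
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t_expected), 4)
        row = de.set_index("gene").loc["g0"]
        assert row["p"] == pytest.approx(p_expected, rel=1e-9)

    def test_planted_effect_recovered(self, clean_sim):
        m, truth = clean_sim
        norm = lognormalize(m)
        meta = m.cell_meta
        micro = (truth.cells["cell_type"] == "microglia").to_numpy()
        a = (meta["condition"] == "SOD1").to_numpy() & micro
        b = (meta["condition"] == "CTRL").to_numpy() & micro
        de = differential_expression(norm, a, b)
        flagged = set(de.loc[de["significant"], "gene"])
        planted = set(truth.de_genes["late_microglia_response"])
        assert len(planted & flagged) >= 28  # near-complete recovery
        assert len(flagged - planted) <= 1  # Bonferroni keeps nulls out

    def test_degenerate_genes_get_p_one(self):
        values = np.zeros((2, 8))
        values[1] = [1, 2, 1, 2, 5, 6, 5, 6]
        norm = make_norm(values)
        a = np.array([True] * 4 + [False] * 4)
        de = differential_expression(norm, a, ~a, min_cells_detected=0)
        row = de.set_index("gene").loc["g0"]
        assert row["degenerate"] and row["p"] == 1.0

    def test_small_groups_rejected(self):
        norm = make_norm(np.ones((3, 6)))
        a = np.array([True, True, False, False, False, False])
        with pytest.raises(ValueError, match="at least 3"):
            differential_expression(norm, a, ~a)


class TestPseudobulk:
    def test_single_group_equals_row_sums(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(4, (10, 20))
        meta = pd.DataFrame(
            {"condition": "CTRL", "age": "1M", "sex": "female"},
            index=[f"c{i}" for i in range(20)],
        )
        m = CountMatrix(counts, [f"g{i}" for i in range(10)],
                        [f"c{i}" for i in range(20)], meta)
        pb = pseudobulk(m)
        assert pb.shape[1] == 1
        np.testing.assert_array_equal(pb.iloc[:, 0], counts.sum(axis=1))

    def test_full_design_conserves_totals(self, clean_sim):
        m, _ = clean_sim
        pb = pseudobulk(m)
        assert pb.shape[1] <= 16
        assert pb.to_numpy().sum() == m.counts.sum()

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(2, (6, 30))
        meta = pd.DataFrame(
            {
                "condition": rng.choice(["CTRL", "SOD1"], 30),
                "age": rng.choice(["1M", "4M"], 30),
                "sex": rng.choice(["female", "male"], 30),
            },
            index=[f"c{i}" for i in range(30)],
        )
        m = CountMatrix(counts, [f"g{i}" for i in range(6)],
                        [f"c{i}" for i in range(30)], meta)
        pb = pseudobulk(m)
        for key in pb.columns:
            members = np.where(
                (meta["condition"] == key[0])
                & (meta["age"] == key[1])
                & (meta["sex"] == key[2])
            )[0]
            np.testing.assert_array_equal(
                pb[key].to_numpy(), counts[:, members].sum(axis=1)
            )

    def test_missing_key_rejected(self):
        m = CountMatrix(np.ones((2, 2), int), ["a", "b"], ["c1", "c2"])
        with pytest.raises(KeyError):
            pseudobulk(m)


class TestPseudobulkPca:
    def test_identical_columns_zero_scores(self):
        pb = pd.DataFrame(
            np.tile(np.arange(1, 11)[:, None], (1, 4)),
            columns=pd.MultiIndex.from_tuples(
                [("CTRL", "1M", "f"), ("CTRL", "1M", "m"),
                 ("SOD1", "1M", "f"), ("SOD1", "1M", "m")]
            ),
        )
        scores, _, _ = pseudobulk_pca(pb, n_pcs=2)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-9)

    def test_planted_shift_separates_and_loads_on_planted_genes(self, clean_sim):
        m, truth = clean_sim
        pb = pseudobulk(m)
        scores, loadings, _ = pseudobulk_pca(pb)
        cols = list(pb.columns)
        sod = [i for i, c in enumerate(cols) if c[0] == "SOD1"]
        ctl = [i for i, c in enumerate(cols) if c[0] == "CTRL"]
        planted = truth.de_genes["late_microglia_response"]
        separated = False
        for pc in scores.columns:
            s = scores[pc].to_numpy()
            margin = max(s[sod].min() - s[ctl].max(), s[ctl].min() - s[sod].max())
            if margin > 0:
                top = set(
                    loadings[pc].abs().sort_values(ascending=False).index[:30]
                )
                if len(top & set(planted)) >= 20:
                    separated = True
                    break
        assert separated

    def test_too_few_samples_rejected(self):
        pb = pd.DataFrame(np.ones((5, 2)))
        with pytest.raises(ValueError):
            pseudobulk_pca(pb)


class TestAnnotateClusters:
    def test_planted_types_labeled(self, clean_sim):
        m, truth = clean_sim
        norm = lognormalize(m)
        clusters = pd.Series(
            pd.factorize(truth.cells["cell_type"])[0] + 1, index=norm.barcodes
        )
        types = annotate_clusters(
            norm,
            clusters,
            {
                "astrocyte": ["Aqp4", "Aldh1l1", "Gjb6"],
                "microglia": ["Cx3cr1", "Aif1"],
                "oligodendrocyte": ["Mobp", "Apod"],
            },
        )
        truth_map = (
            truth.cells.groupby(clusters.to_numpy())["cell_type"]
            .agg(lambda s: s.mode()[0])
            .to_dict()
        )
        for cl, label in types.items():
            assert label == truth_map[cl]

    def test_boundary_strictness_at_80pct(self):
        # 79% expressing -> ambiguous; 80% -> labeled
        n = 100
        values = np.zeros((1, n))
        values[0, :79] = 1.0
        norm = make_norm(values, genes=["Mk"])
        clusters = pd.Series(np.ones(n, int), index=norm.barcodes)
        got = annotate_clusters(norm, clusters, {"t": ["Mk"]})
        assert got.loc[1] == "ambiguous"
        values[0, 79] = 1.0
        norm80 = make_norm(values, genes=["Mk"])
        got80 = annotate_clusters(norm80, clusters, {"t": ["Mk"]})
        assert got80.loc[1] == "t"

    def test_double_match_reported_ambiguous(self):
        values = np.ones((2, 10))
        norm = make_norm(values, genes=["A", "B"])
        clusters = pd.Series(np.ones(10, int), index=norm.barcodes)
        got = annotate_clusters(norm, clusters, {"t1": ["A"], "t2": ["B"]})
        assert got.loc[1] == "ambiguous"

    def test_absent_marker_rejected(self):
        norm = make_norm(np.ones((1, 4)), genes=["A"])
        clusters = pd.Series(np.ones(4, int), index=norm.barcodes)
        with pytest.raises(KeyError):
            annotate_clusters(norm, clusters, {"t": ["Missing"]})


class TestSubpopulationProportions:
    def test_single_cluster_all_ones(self):
        clusters = pd.Series([1, 1, 1, 1], index=list("abcd"))
        meta = pd.DataFrame(
            {"condition": ["CTRL", "CTRL", "SOD1", "SOD1"]}, index=list("abcd")
        )
        props = subpopulation_proportions(clusters, meta)
        np.testing.assert_allclose(props.to_numpy(), 1.0)

    def test_condition_exclusive_cluster_zero_in_ctrl(self, subpop_sim):
        m, truth = subpop_sim
        labels = np.where(
            truth.cells["subpop"] == "none",
            truth.cells["cell_type"],
            truth.cells["subpop"],
        )
        clusters = pd.Series(pd.factorize(labels)[0] + 1, index=m.barcodes)
        sub_cluster = clusters[(labels == "activated_microglia")].iloc[0]
        props = subpopulation_proportions(clusters, m.cell_meta)
        assert props.loc[sub_cluster, "CTRL"] == 0.0
        assert props.loc[sub_cluster, "SOD1"] > 0.0

    def test_fractions_recover_counts(self, clean_sim):
        m, truth = clean_sim
        clusters = pd.Series(
            pd.factorize(truth.cells["cell_type"])[0] + 1, index=m.barcodes
        )
        props = subpopulation_proportions(clusters, m.cell_meta)
        sizes = m.cell_meta.groupby("condition").size()
        for cond in props.columns:
            counts = props[cond] * sizes[cond]
            np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
            assert props[cond].sum() == pytest.approx(1.0)
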