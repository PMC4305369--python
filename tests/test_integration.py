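"""Gene collapsing, virtual-array harmonization, ANOVA, PCA, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.cluster import hierarchy

import stemsig as ss

from conftest import make_matrix


class TestCollapseProbesToGenes:
    def test_mean_rule(self):
        m = make_matrix([[2, 4], [4, 6]], ["s1", "s2"], ["g1", "g2"],
                        index=["p1", "p2"])
        ann = ss.AnnotationTable(symbols={"p1": "GENE1", "p2": "GENE1"})
        out = ss.collapse_probes_to_genes(m, ann)
        assert out.level == "gene"
        np.testing.assert_allclose(out.values.loc["GENE1"], [3.0, 5.0])

    def test_unannotated_dropped_disjoint_kept(self):
        m = make_matrix([[1, 1], [2, 2], [3, 3]], ["s1", "s2"], ["g1", "g2"],
                        index=["p1", "p2", "p3"])
        ann = ss.AnnotationTable(symbols={"p1": "A", "p2": "B"})
        out = ss.collapse_probes_to_genes(m, ann)
        assert list(out.values.index) == ["A", "B"]

    def test_no_annotated_probe_rejected(self):
        m = make_matrix([[1, 1]], ["s1", "s2"], ["g1", "g2"], index=["p1"])
        with pytest.raises(ValueError, match="annotation"):
            ss.collapse_probes_to_genes(m, ss.AnnotationTable(symbols={"q9": "A"}))


def gene_matrix(rng, genes, samples, groups, shift=0.0):
    vals = rng.normal(8, 1, (len(genes), len(samples))) + shift
    return make_matrix(vals, samples, groups, index=genes, level="gene")


class TestBuildVirtualArray:
    def test_constant_batch_removed(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(300)]
        d1 = gene_matrix(rng, genes, ["a1", "a2", "b1", "b2"],
                         ["x", "x", "y", "y"])
        d2 = ss.ExpressionMatrix(d1.values + 5.0, d1.design, level="gene")
        integ = ss.build_virtual_array([d1, d2], ["one", "two"])
        c1 = integ.samples_of_dataset("one")
        c2 = integ.samples_of_dataset("two")
        med_diff = (integ.values[c1].median(axis=1)
                    - integ.values[c2].median(axis=1))
        np.testing.assert_allclose(med_diff, 0.0, atol=1e-9)

    def test_intersection_size(self):
        rng = np.random.default_rng(1)
        shared = [f"G{i}" for i in range(500)]
        d1 = gene_matrix(rng, shared + ["X1", "X2"],
                         ["a1", "a2"], ["x", "x"])
        d2 = gene_matrix(rng, shared + ["Y1"],
                         ["b1", "b2"], ["y", "y"])
        integ = ss.build_virtual_array([d1, d2])
        assert integ.values.shape[0] == 500

    def test_empty_intersection_rejected(self):
        rng = np.random.default_rng(2)
        d1 = gene_matrix(rng, ["A"], ["a1", "a2"], ["x", "x"])
        d2 = gene_matrix(rng, ["B"], ["b1", "b2"], ["y", "y"])
        with pytest.raises(ValueError, match="common symbol"):
            ss.build_virtual_array([d1, d2])

    def test_tree_topology_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(200)]
        samples = ["a1", "a2", "b1", "b2"]
        groups = ["x", "x", "y", "y"]
        vals = rng.normal(8, 1, (200, 4))
        vals[:40, 2:] += 3.0
        d1 = make_matrix(vals, samples, groups, index=genes, level="gene")
        d2 = make_matrix(vals + rng.normal(0, 0.2, vals.shape), samples, groups,
                         index=genes, level="gene")
        trees = []
        for shift in (0.0, 7.5):
            shifted = ss.ExpressionMatrix(d2.values + shift, d2.design,
                                          level="gene")
            integ = ss.build_virtual_array([d1, shifted], ["one", "two"])
            tree = ss.hierarchical_tree(integ.values)
            trees.append(tree.to_newick())
        assert trees[0] == trees[1]


class TestAnovaRank:
    def test_no_signal_case(self):
        vals = make_matrix([[1, 1, 1, 1]], ["a1", "a2", "b1", "b2"],
                           ["x", "x", "y", "y"], index=["G1"])
        ranked = ss.anova_rank(vals.values, vals.design.assignments)
        assert ranked.loc["G1", "F"] == 0.0
        assert ranked.loc["G1", "p"] == 1.0

    def test_hand_example(self):
        vals = make_matrix([[1, 2, 3, 4, 5, 6]],
                           ["a1", "a2", "a3", "b1", "b2", "b3"],
                           ["x", "x", "x", "y", "y", "y"], index=["G1"])
        ranked = ss.anova_rank(vals.values, vals.design.assignments)
        assert ranked.loc["G1", "F"] == pytest.approx(13.5, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(15, 9))
        samples = [f"s{i}" for i in range(9)]
        groups = ["x"] * 3 + ["y"] * 3 + ["z"] * 3
        m = make_matrix(vals, samples, groups, index=[f"G{i}" for i in range(15)])
        ranked = ss.anova_rank(m.values, m.design.assignments)
        F_ref, p_ref = stats.f_oneway(vals[:, :3], vals[:, 3:6], vals[:, 6:],
                                      axis=1)
        np.testing.assert_allclose(ranked["F"].loc[[f"G{i}" for i in range(15)]],
                                   F_ref, atol=1e-10)
        np.testing.assert_allclose(ranked["p"].loc[[f"G{i}" for i in range(15)]],
                                   p_ref, atol=1e-10)

    def test_planted_gene_ranks_first(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 0.2, (50, 6))
        vals[7, 3:] += 5.0
        m = make_matrix(vals, [f"s{i}" for i in range(6)],
                        ["x"] * 3 + ["y"] * 3, index=[f"G{i}" for i in range(50)])
        ranked = ss.anova_rank(m.values, m.design.assignments)
        assert ranked.index[0] == "G7"
        assert ss.top_n(ranked, 5)[0] == "G7"

    def test_single_sample_group_rejected(self):
        m = make_matrix([[1, 2, 3]], ["a1", "a2", "b1"], ["x", "x", "y"],
                        index=["G1"])
        with pytest.raises(ValueError, match="'y'"):
            ss.anova_rank(m.values, m.design.assignments)


class TestPcaScores:
    def test_identical_samples_identical_scores(self):
        m = make_matrix([[1, 1], [2, 2], [3, 3]], ["s1", "s2"], ["g1", "g1"])
        res = ss.pca_scores(m.values, m.design)
        np.testing.assert_allclose(res.scores.loc["s1"], res.scores.loc["s2"],
                                   atol=1e-12)

    def test_hand_two_feature_example(self):
        vals = np.array([[0, 0, 10, 10], [0, 2, 0, 2]], dtype=float)
        m = make_matrix(vals, ["s1", "s2", "s3", "s4"],
                        ["left", "left", "right", "right"])
        res = ss.pca_scores(m.values, m.design)
        pc1 = res.scores["PC1"].to_numpy()
        assert pc1[0] == pytest.approx(pc1[1], abs=1e-9)
        assert abs(pc1[2] - pc1[0]) == pytest.approx(10.0, abs=1e-9)
        np.testing.assert_allclose(
            res.barycenters.loc["left", "PC1"], (pc1[0] + pc1[1]) / 2
        )

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(30, 5)), [f"s{i}" for i in range(5)],
                        ["g1"] * 2 + ["g2"] * 3)
        res = ss.pca_scores(m.values, m.design)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_reproduce_pairwise_distances(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(40, 6)), [f"s{i}" for i in range(6)],
                        ["g1"] * 3 + ["g2"] * 3)
        res = ss.pca_scores(m.values, m.design)
        X = m.values.to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        d_data = np.linalg.norm(Xc[:, :, None] - Xc[:, None, :], axis=0)
        S = res.scores.to_numpy()
        d_scores = np.linalg.norm(S[:, None, :] - S[None, :, :], axis=2)
        np.testing.assert_allclose(d_scores, d_data, atol=1e-8)

    def test_constant_matrix_zero_scores(self):
        m = make_matrix(np.full((10, 3), 4.0), ["s1", "s2", "s3"],
                        ["g1", "g1", "g2"])
        res = ss.pca_scores(m.values, m.design)
        np.testing.assert_array_equal(res.scores.to_numpy(), 0.0)


class TestHierarchicalTree:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(7)
        col = rng.normal(size=30)
        m = make_matrix(np.column_stack([col, col, col + 3]),
                        ["s1", "s2", "s3"], ["g1", "g1", "g2"])
        tree = ss.hierarchical_tree(m.values, distance="euclidean")
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_merge_count(self, preprocessed):
        tree = ss.hierarchical_tree(preprocessed.values.iloc[:200])
        assert tree.linkage.shape[0] == preprocessed.n_samples - 1

    def test_two_block_design_splits_at_root(self):
        rng = np.random.default_rng(8)
        base = rng.normal(8, 1, 120)
        cols = {}
        for s in ["stemA", "stemB", "stemC"]:
            v = base.copy(); v[:30] += 4
            cols[s] = v + rng.normal(0, 0.2, 120)
        for s in ["somA", "somB", "somC"]:
            cols[s] = base + rng.normal(0, 0.2, 120)
        m = make_matrix(np.column_stack(list(cols.values())), list(cols),
                        ["stem"] * 3 + ["som"] * 3)
        tree = ss.hierarchical_tree(m.values)
        left, right = tree.root_split()
        assert {frozenset(left), frozenset(right)} == {
            frozenset({"stemA", "stemB", "stemC"}),
            frozenset({"somA", "somB", "somC"}),
        }

    def test_newick_parses_and_labels_complete(self, preprocessed):
        tree = ss.hierarchical_tree(preprocessed.values.iloc[:100])
        nwk = tree.to_newick()
        import io
        from Bio import Phylo
        parsed = Phylo.read(io.StringIO(nwk), "newick")
        leaves = {t.name for t in parsed.get_terminals()}
        assert leaves == set(preprocessed.values.columns)

    def test_zero_variance_sample_rejected(self):
        m = make_matrix(np.column_stack([np.arange(10.0), np.full(10, 2.0)]),
                        ["ok", "flat"], ["g1", "g2"])
        with pytest.raises(ValueError, match="flat"):
            ss.hierarchical_tree(m.values, distance="correlation")

    def test_cophenetic_matches_scipy(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(25, 5)), [f"s{i}" for i in range(5)],
                        ["g1"] * 2 + ["g2"] * 3)
        tree = ss.hierarchical_tree(m.values, distance="euclidean")
        coph = tree.cophenetic()
        assert coph.shape == (5, 5)
        assert np.allclose(coph.to_numpy(), coph.to_numpy().T)


def test_end_to_end_companion_attaches_to_stem_clade(small_cfg, small_experiment,
                                                     preprocessed):
    _, annotation, design, truth = small_experiment
    genes = ss.collapse_probes_to_genes(preprocessed, annotation)
    companion, _, _ = ss.generate_companion_dataset(small_cfg, truth,
                                                    shared_symbol_count=300)
    integ = ss.build_virtual_array([genes, companion], ["chick", "mouse"])
    ranked = ss.anova_rank(integ.values, integ.sample_meta["group"])
    tree = ss.hierarchical_tree(integ.values.loc[ss.top_n(ranked, 200)])
    coph = tree.cophenetic()
    meta = integ.sample_meta
    mes = meta.index[meta["group"] == "mES"]
    ces = meta.index[meta["group"] == "cES"]
    som = meta.index[meta["group"].isin(["CEF", "BM2"])]
    assert coph.loc[mes, ces].to_numpy().mean() < coph.loc[mes, som].to_numpy().mean()
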