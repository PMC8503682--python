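"""Distribution summaries, PCA conventions, variable genes, HCA oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from genovault import eda
from genovault.eda import (
    EdaError,
    count_distribution_summary,
    heatmap_matrix,
    hierarchical_cluster,
    pca,
    top_variable_genes,
)
from genovault.expression import CountMatrix


def matrix(values, samples=None, genes=None, groups=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    genes = genes or [f"G{i + 1}" for i in range(values.shape[0])]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=samples),
                       groups or {})


class TestDistributionSummary:
    def test_linear_interpolation_quartiles(self):
        m = matrix(np.array([[1], [2], [3], [4], [5]]))
        s = count_distribution_summary(m)["S1"]
        assert (s["q1"], s["median"], s["q3"]) == (2, 3, 4)
        assert (s["min"], s["max"]) == (1, 5)

    def test_constant_column_zero_width_box(self):
        m = matrix(np.full((10, 1), 7.0))
        s = count_distribution_summary(m)["S1"]
        assert s["q1"] == s["median"] == s["q3"] == 7.0
        dens = np.array(s["density"])
        grid = np.array(s["density_grid"])
        assert dens.max() > 100  # a spike
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.poisson(40, size=(200, 3)))
        for s in count_distribution_summary(m).values():
            integral = np.trapezoid(np.array(s["density"]),
                                    np.array(s["density_grid"]))
            assert integral == pytest.approx(1.0, abs=1e-3)

    def test_empty_matrix_rejected(self):
        with pytest.raises(EdaError):
            count_distribution_summary(
                CountMatrix(pd.DataFrame(np.empty((0, 2)),
                                         columns=["a", "b"]))
            )


class TestPca:
    def test_rank_one_data_puts_all_variance_on_pc1(self):
        base = np.array([1.0, 2.0, 4.0, 8.0])
        counts = np.outer(np.array([3.0, 1.0, 2.0]), base)
        m = matrix(2 ** counts - 1)  # log2(x+1) recovers the rank-1 matrix
        res = pca(m)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        m = matrix(rng.poisson(30, size=(40, 6)))
        res = pca(m)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicating_genes_preserves_variance_profile(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(30, size=(30, 5)).astype(float)
        res1 = pca(matrix(counts))
        res2 = pca(matrix(np.vstack([counts, counts]),
                          genes=[f"G{i}" for i in range(60)]))
        assert res2.variance_explained[:4] == pytest.approx(
            res1.variance_explained[:4], abs=1e-9
        )

    def test_full_scores_are_an_isometry_of_centered_data(self):
        rng = np.random.default_rng(3)
        m = matrix(rng.poisson(20, size=(25, 6)))
        res = pca(m)
        X = eda.log_transform(m).to_numpy().T
        Xc = X - X.mean(axis=0)
        S = res.scores.to_numpy()
        for i, j in itertools.combinations(range(6), 2):
            d_orig = np.linalg.norm(Xc[i] - Xc[j])
            d_score = np.linalg.norm(S[i] - S[j])
            assert d_score == pytest.approx(d_orig, abs=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(4)
        m = matrix(rng.poisson(20, size=(25, 5)))
        res = pca(m)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(EdaError):
            pca(matrix([[1], [2]]))

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(5)
        m = matrix(rng.poisson(30, size=(12, 5)))
        res = pca(m)
        X = eda.log_transform(m).to_numpy().T
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
        frac = eigvals / eigvals.sum()
        assert res.variance_explained == pytest.approx(frac[:len(
            res.variance_explained)], abs=1e-8)


class TestTopVariableGenes:
    def test_constant_gene_ranks_last(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(30, size=(10, 4)).astype(float)
        counts[3] = 50.0
        m = matrix(counts)
        order = top_variable_genes(m, 10)
        assert order[-1] == "G4"

    def test_full_n_is_a_permutation(self):
        rng = np.random.default_rng(7)
        m = matrix(rng.poisson(30, size=(15, 3)))
        assert sorted(top_variable_genes(m, 15)) == sorted(m.gene_ids)

    def test_matches_brute_force_variance_sort(self):
        rng = np.random.default_rng(8)
        m = matrix(rng.poisson(30, size=(30, 5)))
        logm = np.log2(m.data + 1)
        var = logm.var(axis=1, ddof=1)
        oracle = sorted(m.gene_ids, key=lambda g: (-var[g], g))[:10]
        assert top_variable_genes(m, 10) == oracle

    def test_nonpositive_n_rejected(self):
        with pytest.raises(EdaError):
            top_variable_genes(matrix([[1, 2]]), 0)


def brute_force_average_linkage(points):
    """O(n³) agglomeration oracle; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(points))}
    D = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(points)) for j in range(len(points)) if i < j
    }
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = min(
            (
                (np.mean([D[tuple(sorted((a, b)))]
                          for a in clusters[ci] for b in clusters[cj]]),
                 ci, cj)
                for ci in clusters for cj in clusters if ci < cj
            ),
            key=lambda t: t[0],
        )
        h, ci, cj = best
        heights.append(h)
        clusters[next_id] = clusters.pop(ci) + clusters.pop(cj)
        next_id += 1
    return sorted(heights)


class TestHca:
    def test_two_items_single_merge_at_distance(self):
        df = pd.DataFrame([[0.0], [3.0]], index=["a", "b"])
        tree = hierarchical_cluster(df, axis="genes")
        assert tree.merge_height == pytest.approx(3.0)
        assert sorted(tree.leaves()) == ["a", "b"]

    def test_planted_tissue_structure_merges_t2_t3_first(self, study):
        from genovault import expression

        raw = expression.matrix_from_db(study["db"])
        norm = expression.normalize_counts(raw, expression.size_factors(raw))
        group_mean = pd.DataFrame({
            t: eda.log_transform(norm)[norm.samples_in_group(t)].mean(axis=1)
            for t in ("T1", "T2", "T3")
        })
        tree = hierarchical_cluster(group_mean, axis="samples")
        # root separates T1 from the (T2, T3) pair
        sides = [sorted(c.leaves()) for c in tree.children]
        assert ["T2", "T3"] in sides and ["T1"] in sides

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(8, 3)))
        tree = hierarchical_cluster(df, axis="genes")

        def check(node, bound):
            if node.is_leaf:
                return
            assert node.merge_height <= bound + 1e-12
            for c in node.children:
                check(c, node.merge_height)

        check(tree, np.inf)

    def test_matches_brute_force_agglomeration_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            pts = rng.normal(size=(9, 4))
            df = pd.DataFrame(pts, index=[f"x{i}" for i in range(9)])
            tree = hierarchical_cluster(df, axis="genes")
            got = sorted(tree.merge_heights())
            assert got == pytest.approx(brute_force_average_linkage(pts),
                                        abs=1e-9)


class TestHeatmap:
    def test_rows_are_z_scaled_and_match_top_genes(self, study):
        from genovault import expression

        raw = expression.matrix_from_db(study["db"])
        norm = expression.normalize_counts(raw, expression.size_factors(raw))
        heat = heatmap_matrix(norm, ["T1", "T2", "T3"], n_top=20)
        M = heat["matrix"]
        assert sorted(M.index) == sorted(top_variable_genes(norm, 20))
        assert M.mean(axis=1).to_numpy() == pytest.approx(
            np.zeros(20), abs=1e-9
        )
        assert M.std(axis=1, ddof=0).to_numpy() == pytest.approx(
            np.ones(20), abs=1e-9
        )

    def test_n_top_exceeding_genes_rejected(self):
        m = matrix([[1, 2], [3, 4]], groups={"S1": "a", "S2": "a"})
        with pytest.raises(EdaError):
            heatmap_matrix(m, ["a"], n_top=5)
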