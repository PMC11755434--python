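import math

import numpy as np
import pandas as pd
import pytest

from emstate import (
    CellMetadata,
    CollapsedProfile,
    ExpressionMatrix,
    ValidationError,
    cluster_labels,
    correlation_matrix,
    default_panels,
    kmeans_objective,
    pca_kmeans_gradient,
    score_cells,
)


def _profiles(X, labels, gene_ids=None):
    gene_ids = gene_ids or [f"G{i}" for i in range(X.shape[1])]
    return [CollapsedProfile(
        group_id=l, n_cells=1, gene_ids=gene_ids, expression=row,
        mean_mes=0.0, mean_epith=0.0, mes_epith_ratio=0.0)
        for l, row in zip(labels, X)]


def pearson_oracle(x, y):
    """Textbook Pearson correlation, plain double loop."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def upgma_oracle(dist):
    """Hand-rolled average linkage: returns sorted merge heights.

    Clusters are merged at the unweighted mean pairwise distance between
    their members (UPGMA).
    """
    clusters = {i: [i] for i in range(dist.shape[0])}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestCorrelationMatrix:
    def test_identical_profiles_correlate_to_one(self):
        row = np.array([1.0, 2.0, 3.0, 4.0])
        result = correlation_matrix(_profiles(np.stack([row, row]), ["a", "b"]))
        np.testing.assert_allclose(result.matrix, np.ones((2, 2)), atol=1e-12)

    def test_negated_profile_correlates_to_minus_one(self):
        row = np.array([1.0, 2.0, 3.0, 4.0])
        neg = row.mean() * 2 - row  # reflection about the mean
        result = correlation_matrix(_profiles(np.stack([row, neg]), ["a", "b"]))
        assert result.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.random((3, 4))
        result = correlation_matrix(_profiles(X, ["a", "b", "c"]))
        for i in range(3):
            for j in range(3):
                expected = 1.0 if i == j else pearson_oracle(X[i], X[j])
                assert result.matrix[i, j] == pytest.approx(expected,
                                                            abs=1e-12)

    def test_constant_profile_flagged_zero(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        result = correlation_matrix(_profiles(X, ["flat", "var"]))
        assert result.constant_profiles == ["flat"]
        assert result.matrix[0, 1] == 0.0
        assert result.matrix[0, 0] == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.random((2, 6))
        base = correlation_matrix(_profiles(X, ["a", "b"]))
        X2 = X.copy()
        X2[0] = 3.5 * X2[0] + 2.0
        scaled = correlation_matrix(_profiles(X2, ["a", "b"]))
        assert scaled.matrix[0, 1] == pytest.approx(base.matrix[0, 1],
                                                    abs=1e-12)

    def test_fewer_than_two_profiles_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            correlation_matrix(_profiles(np.ones((1, 3)), ["a"]))

    def test_panel_only_restriction_consistency(self):
        """panel_only correlation is unchanged by removing non-panel genes."""
        rng = np.random.default_rng(8)
        genes = ["VIM", "FN1", "CDH1", "KRT8", "BG1", "BG2"]
        X = rng.random((3, 6))
        panels = default_panels()
        full = correlation_matrix(_profiles(X, list("abc"), genes),
                                  gene_subset="panel_only", panels=panels)
        stripped = correlation_matrix(
            _profiles(X[:, :4], list("abc"), genes[:4]),
            gene_subset="panel_only", panels=panels)
        np.testing.assert_allclose(full.matrix, stripped.matrix, atol=1e-12)


class TestClusterLabels:
    def test_perfect_pairs_merge_first(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([4.0, 3.0, 2.0, 1.0])
        X = np.stack([a, 2 * a + 1, b, 3 * b])  # two r=1 pairs
        result = correlation_matrix(_profiles(X, ["a1", "a2", "b1", "b2"]))
        order = cluster_labels(result)
        assert {tuple(sorted(order[:2])), tuple(sorted(order[2:]))} == \
            {("a1", "a2"), ("b1", "b2")}
        # first two merges happen at distance 0
        np.testing.assert_allclose(result.linkage[:2, 2], 0.0, atol=1e-12)

    def test_two_profiles_single_merge(self):
        rng = np.random.default_rng(9)
        result = correlation_matrix(_profiles(rng.random((2, 5)), ["a", "b"]))
        assert cluster_labels(result) == ["a", "b"]

    def test_merge_heights_match_upgma_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.random((5, 8))
        result = correlation_matrix(_profiles(X, list("abcde")))
        cluster_labels(result)
        dist = 1.0 - result.matrix
        np.fill_diagonal(dist, 0.0)
        np.testing.assert_allclose(sorted(result.linkage[:, 2]),
                                   upgma_oracle(dist), atol=1e-12)


def _two_cluster_data(seed=0, n=30, sep=100.0, sigma=1.0):
    """Two point clouds separated by sep*sigma on the panel genes."""
    rng = np.random.default_rng(seed)
    genes = ["VIM", "FN1", "CDH1", "KRT8"]
    # epithelial-like cloud: high CDH1/KRT8; mesenchymal-like: high VIM/FN1
    epi = np.abs(rng.normal(0, sigma, (4, n))) + \
        np.array([[0.0], [0.0], [sep * sigma], [sep * sigma]])
    mes = np.abs(rng.normal(0, sigma, (4, n))) + \
        np.array([[sep * sigma], [sep * sigma], [0.0], [0.0]])
    values = np.concatenate([epi, mes], axis=1)
    cells = [f"e{j}" for j in range(n)] + [f"m{j}" for j in range(n)]
    m = ExpressionMatrix(genes, cells, values)
    meta = CellMetadata(pd.DataFrame({
        "cell_id": cells,
        "cell_type": ["EpiType"] * n + ["MesType"] * n}))
    scores = score_cells(m, meta, default_panels())
    return m, meta, scores


class TestPcaKmeansGradient:
    def test_separated_clusters_give_pure_gradients(self):
        m, meta, scores = _two_cluster_data()
        result = pca_kmeans_gradient(m, meta, scores, seed=0)
        assert result.per_type_gradient["EpiType"] == 0.0
        assert result.per_type_gradient["MesType"] == 1.0

    def test_orientation_stable_across_seeds(self):
        m, meta, scores = _two_cluster_data()
        for seed in range(10):
            result = pca_kmeans_gradient(m, meta, scores, seed=seed)
            assert result.per_type_gradient["EpiType"] == 0.0
            assert result.per_type_gradient["MesType"] == 1.0

    def test_split_type_has_intermediate_gradient(self):
        m, meta, scores = _two_cluster_data(n=20)
        mixed = CellMetadata(meta.table.assign(cell_type="Mixed"))
        result = pca_kmeans_gradient(m, mixed, scores, seed=0)
        assert result.per_type_gradient["Mixed"] == pytest.approx(0.5)

    def test_gradient_bounds_and_components_cap(self):
        m, meta, scores = _two_cluster_data(n=3)  # 6 cells, 4 genes
        result = pca_kmeans_gradient(m, meta, scores, n_components=5, seed=0)
        assert result.pca_coords.shape[1] <= 3  # capped at min(4,6)-1
        assert ((result.per_type_gradient >= 0) &
                (result.per_type_gradient <= 1)).all()

    def test_kmeans_beats_random_assignments(self):
        rng = np.random.default_rng(12)
        m, meta, scores = _two_cluster_data(seed=12, n=25, sep=2.0)
        result = pca_kmeans_gradient(m, meta, scores, seed=0)
        coords = result.pca_coords.to_numpy()
        fitted = kmeans_objective(coords, result.per_sample_cluster.to_numpy())
        for _ in range(100):
            random_labels = rng.integers(0, 2, size=coords.shape[0])
            if len(np.unique(random_labels)) < 2:
                continue
            assert fitted <= kmeans_objective(coords, random_labels) + 1e-9

    def test_too_few_genes_rejected(self):
        m = ExpressionMatrix(["VIM"], ["c1", "c2"], np.ones((1, 2)))
        meta = CellMetadata(pd.DataFrame({"cell_id": ["c1", "c2"],
                                          "cell_type": ["A", "A"]}))
        scores = pd.DataFrame({"mean_epith": [0.0, 0.0]},
                              index=pd.Index(["c1", "c2"], name="cell_id"))
        with pytest.raises(ValidationError, match="2 panel genes"):
            pca_kmeans_gradient(m, meta, scores)
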