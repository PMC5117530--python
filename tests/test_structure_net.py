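"""PCA, correlation distances, UPGMA, and the coexpression network."""

import numpy as np
import pandas as pd
import pytest

from stromasig import (coexpression_network, correlation_distance_matrix,
                       export_network, hcluster, pca, read_network_edgelist,
                       read_network_sif)
from stromasig.synthetic import simulate_coexpression_module

from conftest import make_matrix


class TestPca:
    def test_rank_one_matrix_has_all_variance_on_pc1(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=6)
        mat = make_matrix(np.outer(u, v))
        res = pca(mat, "genes-as-variables")
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_cumulative_variance_reaches_one(self, random_matrix):
        res = pca(random_matrix, "genes-as-variables")
        assert res.cumulative_variance[-1] == pytest.approx(1.0)
        assert (np.diff(res.cumulative_variance) >= -1e-12).all()

    def test_matches_covariance_eigendecomposition(self, rng):
        mat = make_matrix(rng.normal(size=(10, 6)))
        res = pca(mat, "genes-as-variables")  # observations = 6 samples
        x = mat.values.T
        cov = np.cov(x, rowvar=False, ddof=1) * (x.shape[0] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0, None)
        expected = eigvals[:res.variance_fraction.size] / eigvals.sum()
        np.testing.assert_allclose(res.variance_fraction, expected, atol=1e-9)

    def test_variance_invariant_to_observation_permutation(self, rng):
        mat = make_matrix(rng.normal(size=(20, 8)))
        res = pca(mat, "genes-as-variables")
        shuffled = make_matrix(mat.values[:, ::-1])
        res2 = pca(shuffled, "genes-as-variables")
        np.testing.assert_allclose(res.variance_fraction,
                                   res2.variance_fraction, atol=1e-9)

    def test_constant_variable_with_scaling_errors(self):
        values = np.ones((3, 5))
        values[1] = np.arange(5)
        values[2] = np.arange(5) ** 2
        mat = make_matrix(values)
        with pytest.raises(ValueError, match="G1"):
            pca(mat, "genes-as-variables", scale=True)

    def test_both_orientations_run(self, random_matrix):
        by_genes = pca(random_matrix, "genes-as-variables")
        by_samples = pca(random_matrix, "samples-as-variables")
        assert by_genes.scores.shape[0] == random_matrix.shape[1]
        assert by_samples.scores.shape[0] == random_matrix.shape[0]


class TestCorrelationDistances:
    def test_duplicated_samples_have_zero_distance(self, rng):
        col = rng.normal(size=20)
        values = np.column_stack([col, col, rng.normal(size=20)])
        mat = make_matrix(values)
        dist = correlation_distance_matrix(mat)
        assert dist.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_with_zero_diagonal(self, random_matrix):
        dist = correlation_distance_matrix(random_matrix)
        np.testing.assert_allclose(dist.values, dist.values.T)
        np.testing.assert_allclose(np.diag(dist.values), 0.0)

    def test_matches_bruteforce_double_loop(self, rng):
        mat = make_matrix(rng.normal(size=(30, 8)))
        dist = correlation_distance_matrix(mat)
        corr = np.corrcoef(mat.values.T)
        for i in range(8):
            for j in range(8):
                expected = np.sqrt(((corr[i] - corr[j]) ** 2).sum())
                assert dist.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_sample_named_in_error(self, rng):
        values = rng.normal(size=(10, 4))
        values[:, 2] = 5.0
        mat = make_matrix(values)
        with pytest.raises(ValueError, match="s3"):
            correlation_distance_matrix(mat)


class TestHcluster:
    @staticmethod
    def _dist(values, labels):
        return pd.DataFrame(values, index=labels, columns=labels)

    def test_hand_computed_upgma_heights(self):
        # d(A,B)=2, d(C,D)=4, cross distances 6,8,7,9:
        # UPGMA merges AB at 2, CD at 4, then both at mean(6,8,7,9)=7.5
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 2, 6, 8],
                      [2, 0, 7, 9],
                      [6, 7, 0, 4],
                      [8, 9, 4, 0]], dtype=float)
        z = hcluster(self._dist(d, labels))
        np.testing.assert_allclose(z[:, 2], [2.0, 4.0, 7.5])
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert {int(z[1, 0]), int(z[1, 1])} == {2, 3}

    def test_well_separated_groups_merge_within_first(self, rng):
        base = rng.normal(size=(40, 2))
        values = np.column_stack([base[:, 0], base[:, 0] + 0.01,
                                  base[:, 1] + 50, base[:, 1] + 50.01])
        mat = make_matrix(values)
        dist = correlation_distance_matrix(mat)
        z = hcluster(dist)
        first_two_merges = [{int(z[i, 0]), int(z[i, 1])} for i in range(2)]
        assert {0, 1} in first_two_merges and {2, 3} in first_two_merges

    def test_permutation_gives_same_tree_heights(self, rng):
        n = 7
        x = rng.normal(size=(n, 5))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(x))
        labels = [f"s{i}" for i in range(n)]
        z1 = hcluster(self._dist(d, labels))
        perm = rng.permutation(n)
        z2 = hcluster(self._dist(d[np.ix_(perm, perm)],
                                 [labels[i] for i in perm]))
        np.testing.assert_allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]),
                                   atol=1e-12)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            hcluster(self._dist(d, ["a", "b"]))


class TestCoexpressionNetwork:
    def test_duplicated_gene_gets_perfect_edge(self, rng):
        row = rng.normal(size=20)
        values = np.vstack([row, row, rng.normal(size=(3, 20))])
        mat = make_matrix(values)
        net = coexpression_network(mat, r_min=0.95)
        assert net.graph.has_edge("G1", "G2")
        assert net.graph.edges["G1", "G2"]["r"] == pytest.approx(1.0)

    def test_independent_noise_yields_almost_no_edges(self):
        total_pairs = edges = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mat = make_matrix(rng.normal(size=(100, 50)))
            net = coexpression_network(mat, r_min=0.95)
            edges += net.n_edges
            total_pairs += 100 * 99 // 2
        assert edges / total_pairs <= 0.001

    def test_planted_module_fully_connected(self):
        mat, module = simulate_coexpression_module(
            n_module=20, n_background=200, n_samples=50, within_r=0.98,
            seed=3)
        net = coexpression_network(mat, r_min=0.95)
        module_pairs = 20 * 19 // 2
        within = sum(1 for a, b, _ in net.edges()
                     if a in set(module) and b in set(module))
        assert within == module_pairs
        cross = net.n_edges - within
        assert cross / max(net.n_edges, 1) < 0.01

    def test_threshold_monotone_containment(self, rng):
        mat, _ = simulate_coexpression_module(n_module=10, n_background=40,
                                              n_samples=30, within_r=0.9,
                                              seed=5)
        edges_strict = set((a, b) for a, b, _ in
                           coexpression_network(mat, r_min=0.9).edges())
        edges_loose = set((a, b) for a, b, _ in
                          coexpression_network(mat, r_min=0.6).edges())
        assert edges_strict <= edges_loose

    def test_gene_and_sample_order_invariance(self, rng):
        mat, _ = simulate_coexpression_module(n_module=8, n_background=30,
                                              n_samples=25, within_r=0.9,
                                              seed=9)
        net = coexpression_network(mat, r_min=0.8)
        perm_g = rng.permutation(mat.shape[0])
        perm_s = rng.permutation(mat.shape[1])
        from stromasig import ExpressionMatrix
        net2 = coexpression_network(
            ExpressionMatrix(mat.data.iloc[perm_g, perm_s]), r_min=0.8)
        assert set((a, b) for a, b, _ in net.edges()) \
            == set((a, b) for a, b, _ in net2.edges())

    def test_invalid_threshold_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            coexpression_network(random_matrix, r_min=1.5)

    def test_absolute_mode_keeps_negative_correlations(self, rng):
        row = rng.normal(size=30)
        values = np.vstack([row, -row, rng.normal(size=(2, 30))])
        mat = make_matrix(values)
        signed = coexpression_network(mat, r_min=0.95)
        assert not signed.graph.has_edge("G1", "G2")
        both = coexpression_network(mat, r_min=0.95, absolute=True)
        assert both.graph.has_edge("G1", "G2")


class TestNetworkExport:
    def test_single_edge_sif_round_trip(self, tmp_path, rng):
        row = rng.normal(size=10)
        mat = make_matrix(np.vstack([row, row]))
        net = coexpression_network(mat, r_min=0.95)
        path = tmp_path / "net.sif"
        export_network(net, path, fmt="sif")
        assert path.read_text() == "G1\tcoexp\tG2\n"
        back = read_network_sif(path)
        assert back.graph.has_edge("G1", "G2")

    def test_edgelist_round_trip_100_edges(self, tmp_path, rng):
        mat, _ = simulate_coexpression_module(n_module=18, n_background=5,
                                              n_samples=40, within_r=0.97,
                                              seed=7)
        net = coexpression_network(mat, r_min=0.9)
        assert net.n_edges >= 100
        path = tmp_path / "net.tsv"
        export_network(net, path, fmt="edgelist")
        back = read_network_edgelist(path)
        assert set(back.graph.edges) == set(net.graph.edges)
        for a, b, r in net.edges():
            assert back.graph.edges[a, b]["r"] == pytest.approx(r, abs=1e-12)

    def test_unknown_format_rejected(self, tmp_path, rng):
        row = rng.normal(size=10)
        net = coexpression_network(make_matrix(np.vstack([row, row])),
                                   r_min=0.9)
        with pytest.raises(ValueError, match="format"):
            export_network(net, tmp_path / "x", fmt="dot")

    def test_node_labels_written(self, tmp_path, rng):
        row = rng.normal(size=10)
        mat = make_matrix(np.vstack([row, row]))
        net = coexpression_network(mat, r_min=0.9,
                                   node_labels={"G1": "CD_marker"})
        path = tmp_path / "net.tsv"
        export_network(net, path, fmt="edgelist")
        nodes = pd.read_csv(f"{path}.nodes.tsv", sep="\t")
        assert nodes.set_index("gene_id").loc["G1", "label"] == "CD_marker"
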