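"""kNN graph construction, Louvain clustering, sub-clustering, heatmap order."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from perturbmap.cluster import (
    ClusterAssignment,
    ClusterParams,
    build_knn_graph,
    louvain_cluster,
    subcluster,
    within_cluster_distances,
)
from perturbmap.reduce import Embedding, ReduceParams
from perturbmap.synthio import SynthConfig, generate_deleteome


def embedding_from(points, ids=None) -> Embedding:
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return Embedding(ids, points, "umap")


class TestKnnGraph:
    def test_collinear_points_path_graph(self):
        emb = embedding_from([[0, 0], [1, 0], [3, 0]])
        graph = build_knn_graph(emb, k=1)
        assert set(graph.edges) == {("s0", "s1"), ("s1", "s2")}

    def test_k_geq_n_minus_one_complete(self):
        emb = embedding_from(np.random.default_rng(0).normal(size=(5, 2)))
        graph = build_knn_graph(emb, k=4)
        assert graph.number_of_edges() == 10

    def test_graph_undirected_symmetric(self):
        emb = embedding_from(np.random.default_rng(1).normal(size=(20, 2)))
        graph = build_knn_graph(emb, k=3)
        adj = nx.to_numpy_array(graph)
        assert np.array_equal(adj, adj.T)

    def test_duplicate_coordinates_deterministic(self):
        points = np.zeros((6, 2))
        emb = embedding_from(points)
        g1 = build_knn_graph(emb, k=2)
        g2 = build_knn_graph(emb, k=2)
        assert set(g1.edges) == set(g2.edges)

    def test_too_few_strains(self):
        emb = embedding_from([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            build_knn_graph(emb, k=2)


def two_cliques(n=5, bridge=False) -> nx.Graph:
    graph = nx.Graph()
    left = [f"a{i}" for i in range(n)]
    right = [f"b{i}" for i in range(n)]
    graph.add_edges_from(itertools.combinations(left, 2))
    graph.add_edges_from(itertools.combinations(right, 2))
    if bridge:
        graph.add_edge(left[0], right[0])
    return graph


class TestLouvain:
    def test_disconnected_cliques_two_clusters(self):
        assignment = louvain_cluster(two_cliques(), resolution=1.0, seed=0)
        labels = assignment.main_labels()
        assert assignment.n_main() == 2
        assert len({labels[f"a{i}"] for i in range(5)}) == 1
        assert len({labels[f"b{i}"] for i in range(5)}) == 1

    def test_single_clique_one_cluster(self):
        graph = nx.complete_graph(6)
        graph = nx.relabel_nodes(graph, {i: f"s{i}" for i in range(6)})
        assignment = louvain_cluster(graph, resolution=1.0, seed=0)
        assert assignment.n_main() == 1

    def test_bridged_cliques_split_beats_merged(self):
        """The 2-community split has higher modularity than 1 block."""
        graph = two_cliques(4, bridge=True)
        split = [{f"a{i}" for i in range(4)}, {f"b{i}" for i in range(4)}]
        merged = [set(graph.nodes)]
        q_split = nx.community.modularity(graph, split)
        q_merged = nx.community.modularity(graph, merged)
        assert q_split > q_merged
        assignment = louvain_cluster(graph, resolution=1.0, seed=0)
        parts = {}
        for strain, label in assignment.main_labels().items():
            parts.setdefault(label, set()).add(strain)
        q_found = nx.community.modularity(graph, list(parts.values()))
        assert q_found >= q_split - 1e-12

    def test_labels_dense_and_size_ordered(self):
        graph = nx.disjoint_union(nx.complete_graph(7), nx.complete_graph(3))
        graph = nx.relabel_nodes(graph, {i: f"s{i}" for i in range(10)})
        assignment = louvain_cluster(graph, resolution=1.0, seed=0)
        sizes = assignment.table.groupby("main_cluster").size()
        assert list(sizes.index) == [0, 1]
        assert sizes[0] >= sizes[1]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            louvain_cluster(nx.Graph(), resolution=1.0, seed=0)


class TestSubcluster:
    def test_small_clusters_unchanged(self, rng):
        _, assignment, X = self._forced_single_cluster(rng)
        params = ClusterParams(subcluster_min_size=10_000)
        out = subcluster(X, assignment, params)
        pd.testing.assert_frame_equal(out.table, assignment.table)

    def test_separates_merged_complexes(self, rng):
        truth_labels, assignment, X = self._forced_single_cluster(rng)
        params = ClusterParams(subcluster_min_size=25, seed=0)
        out = subcluster(X, assignment, params, ReduceParams(seed=0))
        sub = [out.sub_labels()[s] for s in X.strain_ids]
        assert adjusted_rand_score(truth_labels, sub) >= 0.8

    def test_strain_count_conserved(self, rng):
        _, assignment, X = self._forced_single_cluster(rng)
        out = subcluster(X, assignment, ClusterParams(seed=0))
        assert sorted(out.strains) == sorted(assignment.strains)

    @staticmethod
    def _forced_single_cluster(rng):
        """Two planted complexes deliberately merged into one main cluster."""
        config = SynthConfig(
            n_genes=300,
            n_complexes=2,
            complex_size_range=(15, 15),
            n_background_strains=0,
            n_paralog_pairs=0,
            noise_sd=0.3,
            seed=17,
        )
        X, truth = generate_deleteome(config)
        member_of = {s: c for c, m in truth.complexes.items() for s in m}
        truth_labels = [member_of[s] for s in X.strain_ids]
        table = pd.DataFrame(
            {
                "strain": X.strain_ids,
                "main_cluster": 0,
                "sub_cluster": "0",
            }
        )
        return truth_labels, ClusterAssignment(table), X


class TestWithinClusterDistances:
    @staticmethod
    def _assignment(ids, label=1):
        return ClusterAssignment(
            pd.DataFrame(
                {
                    "strain": ids,
                    "main_cluster": label,
                    "sub_cluster": str(label),
                }
            )
        )

    def test_two_member_cluster(self):
        emb = embedding_from([[0, 0], [3, 4]], ids=["a", "b"])
        matrix, order = within_cluster_distances(emb, self._assignment(["a", "b"]), 1)
        assert matrix.shape == (2, 2)
        assert matrix.loc["a", "b"] == pytest.approx(5.0)
        assert np.allclose(np.diag(matrix), 0.0)

    def test_symmetry(self, rng):
        pts = rng.normal(size=(6, 2))
        ids = [f"s{i}" for i in range(6)]
        emb = embedding_from(pts, ids)
        matrix, _ = within_cluster_distances(emb, self._assignment(ids), 1)
        assert np.allclose(matrix.to_numpy(), matrix.to_numpy().T)

    def test_tight_pairs_adjacent_in_leaf_order(self):
        pts = [[0, 0], [0.1, 0], [10, 0], [10.1, 0]]
        ids = ["p1", "p2", "q1", "q2"]
        emb = embedding_from(pts, ids)
        _, order = within_cluster_distances(emb, self._assignment(ids), 1)
        pos = {s: i for i, s in enumerate(order)}
        assert abs(pos["p1"] - pos["p2"]) == 1
        assert abs(pos["q1"] - pos["q2"]) == 1

    def test_singleton_cluster_rejected(self):
        emb = embedding_from([[0, 0], [1, 1]], ids=["a", "b"])
        assignment = ClusterAssignment(
            pd.DataFrame(
                {
                    "strain": ["a", "b"],
                    "main_cluster": [1, 2],
                    "sub_cluster": ["1", "2"],
                }
            )
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            within_cluster_distances(emb, assignment, 1)


def test_pipeline_clusters_are_partition(reference_run):
    """Every strain gets exactly one main label; subs nest in mains."""
    assignment = reference_run["assignment"]
    X = reference_run["X"]
    assert sorted(assignment.strains) == sorted(X.strain_ids)
    for _, row in assignment.table.iterrows():
        assert row.sub_cluster.split(".")[0] == str(row.main_cluster)
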