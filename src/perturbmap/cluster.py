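"""Two-level community detection on embedded strains.

Main clusters come from Louvain modularity optimization on a
k-nearest-neighbor graph built in the 2-D embedding; clusters larger
than a size threshold are re-embedded from the expression matrix
(fresh PCA + UMAP on the subset) and sub-clustered with the same
procedure, giving the two-level structure used to match clusters to
protein complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform

from .dataio import ExpressionMatrix
from .reduce import Embedding, ReduceParams, embed_umap, pca_scores

__all__ = [
    "ClusterParams",
    "ClusterAssignment",
    "build_knn_graph",
    "louvain_cluster",
    "subcluster",
    "within_cluster_distances",
    "read_assignment",
    "write_assignment",
]


@dataclass
class ClusterParams:
    """Community-detection parameters.

    `resolution` is the standard modularity resolution: with the tiny
    default (1e-4) merging is almost always favourable, so communities
    coincide with the connected components of the sparse k=3 kNN
    graph — the granularity regime the reference analysis ran in.
    """

    k_neighbors: int = 3
    resolution: float = 1e-4
    subcluster_min_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")


@dataclass
class ClusterAssignment:
    """Strain → main cluster (int, dense, size-ordered) and sub label.

    Sub labels are strings "main.sub" for strains whose main cluster
    was sub-clustered, and plain "main" otherwise, so sub-clusters
    always nest within mains.
    """

    table: pd.DataFrame  # columns: strain, main_cluster, sub_cluster

    def __post_init__(self) -> None:
        required = {"strain", "main_cluster", "sub_cluster"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"assignment needs columns {sorted(required)}")
        if self.table.strain.duplicated().any():
            raise ValueError("duplicate strain in assignment")
        self.table = self.table.reset_index(drop=True)
        self.table["main_cluster"] = self.table["main_cluster"].astype(int)
        self.table["sub_cluster"] = self.table["sub_cluster"].astype(str)

    @property
    def strains(self) -> list[str]:
        return list(self.table.strain)

    def main_labels(self) -> dict[str, int]:
        return dict(zip(self.table.strain, self.table.main_cluster))

    def sub_labels(self) -> dict[str, str]:
        return dict(zip(self.table.strain, self.table.sub_cluster))

    def members(self, cluster_id: int) -> list[str]:
        mask = self.table.main_cluster == cluster_id
        return list(self.table.strain[mask])

    def n_main(self) -> int:
        return self.table.main_cluster.nunique()

    def n_total(self) -> int:
        """Total cluster count at the finest level (sub where available)."""
        return self.table.sub_cluster.nunique()


def build_knn_graph(embedding: Embedding, k: int) -> nx.Graph:
    """Symmetrized-union kNN graph over strains in embedding space.

    Edge (i, j) exists iff j is among i's k nearest Euclidean
    neighbors or vice versa; edges are unweighted. Distance ties are
    broken by strain order (stable argsort), so duplicate coordinates
    are handled deterministically.
    """
    n = embedding.n_strains
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} strains, got {n}")
    dist = squareform(pdist(embedding.coords))
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")
    graph = nx.Graph()
    graph.add_nodes_from(embedding.strain_ids)
    ids = embedding.strain_ids
    for i in range(n):
        for j in order[i, :k]:
            graph.add_edge(ids[i], ids[int(j)])
    return graph


def louvain_cluster(
    graph: nx.Graph, resolution: float, seed: int
) -> ClusterAssignment:
    """Louvain partition of the strain graph, labels sorted by size.

    Label 0 is the largest community; ties in size are broken by the
    smallest member strain id so labeling is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    communities = louvain_communities(graph, resolution=resolution, seed=seed)
    communities = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    rows = []
    for label, members in enumerate(communities):
        for strain in members:
            rows.append((strain, label, str(label)))
    table = pd.DataFrame(rows, columns=["strain", "main_cluster", "sub_cluster"])
    # restore input node order
    order = {s: i for i, s in enumerate(graph.nodes)}
    table = table.sort_values("strain", key=lambda s: s.map(order))
    return ClusterAssignment(table.reset_index(drop=True))


def subcluster(
    X: ExpressionMatrix,
    assignment: ClusterAssignment,
    cluster_params: ClusterParams,
    reduce_params: ReduceParams | None = None,
) -> ClusterAssignment:
    """Re-cluster each large main cluster from its own expression subset.

    For every main cluster with more than `subcluster_min_size`
    strains, the expression matrix is restricted to its members,
    re-embedded (PCA with up to `n_pcs_sub` components, then UMAP) and
    re-clustered with the same kNN + Louvain procedure; members get
    sub labels "main.sub". Smaller clusters keep sub = main.
    """
    reduce_params = reduce_params or ReduceParams(seed=cluster_params.seed)
    table = assignment.table.copy()
    sub = table.main_cluster.astype(str)
    for cid in sorted(table.main_cluster.unique()):
        members = assignment.members(int(cid))
        if len(members) <= cluster_params.subcluster_min_size:
            continue
        sub_X = X.subset(members)
        n_pcs = min(reduce_params.n_pcs_sub, len(members) - 1, sub_X.n_genes)
        scores = pca_scores(sub_X, n_pcs)
        params = ReduceParams(
            n_pcs_main=n_pcs,
            n_pcs_sub=n_pcs,
            umap_metric=reduce_params.umap_metric,
            n_neighbors=min(reduce_params.n_neighbors, len(members) - 1),
            min_dist=reduce_params.min_dist,
            out_dims=reduce_params.out_dims,
            seed=reduce_params.seed,
        )
        emb = embed_umap(scores, params)
        graph = build_knn_graph(emb, cluster_params.k_neighbors)
        sub_assign = louvain_cluster(
            graph, cluster_params.resolution, cluster_params.seed
        )
        labels = sub_assign.main_labels()
        mask = table.main_cluster == cid
        sub.loc[mask] = [
            f"{cid}.{labels[s]}" for s in table.strain[mask]
        ]
    table["sub_cluster"] = sub
    return ClusterAssignment(table)


def within_cluster_distances(
    embedding: Embedding, assignment: ClusterAssignment, cluster_id: int
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise embedded distances within one cluster, plus a heatmap order.

    Returns the symmetric Euclidean distance matrix among the
    cluster's members (as a labeled DataFrame) and the leaf order of
    average-linkage hierarchical clustering on those distances — the
    row/column order used to render the fine-scale distance heatmap
    of a cluster.
    """
    members = assignment.members(cluster_id)
    if len(members) < 2:
        raise ValueError(f"cluster {cluster_id} has fewer than 2 strains")
    idx = embedding.strain_index()
    coords = embedding.coords[[idx[s] for s in members]]
    condensed = pdist(coords)
    matrix = pd.DataFrame(squareform(condensed), index=members, columns=members)
    linkage = average(condensed)
    leaf_order = [members[i] for i in leaves_list(linkage)]
    return matrix, leaf_order


def write_assignment(assignment: ClusterAssignment, path: str | Path) -> None:
    assignment.table.to_csv(path, sep="\t", index=False)


def read_assignment(path: str | Path) -> ClusterAssignment:
    df = pd.read_csv(
        path, sep="\t", dtype={"strain": str, "sub_cluster": str}
    )
    return ClusterAssignment(df)
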