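"""Per-batch graph clustering: PCA -> shared-nearest-neighbor graph ->
modularity community detection (Leiden).

Each batch is clustered independently so cluster structure is never
contaminated by batch effects; the similarity step afterwards is what links
clusters across batches.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datatypes import ClusterAssignment, ExpressionBatch, ValidationError


PRUNE_SNN = 1.0 / 15.0  # drop SNN edges with Jaccard overlap below this


@dataclass
class ClusterConfig:
    # Defaults mirror the Seurat-style clustering the method builds on
    # (k.param = 30 neighbors, resolution 0.8).
    k: int = 30
    n_pcs: int = 30
    resolution: float = 0.8
    seed: int = 0


def knn_graph(cells: np.ndarray, k: int = 15, n_pcs: int = 30) -> ig.Graph:
    """Build a shared-nearest-neighbor weighted graph of one batch's cells.

    Parameters
    ----------
    cells:
        ``(n_cells, n_features)`` matrix (cells as rows).
    k:
        Number of Euclidean nearest neighbors per cell (excluding itself).
    n_pcs:
        Number of principal components used for the distance computation
        (capped by the data dimensions).

    The graph is the shared-nearest-neighbor (SNN) graph: any two cells
    whose k-neighborhoods (each including the cell itself) overlap are
    connected, weighted by the Jaccard overlap of the neighborhoods, with
    weights below 1/15 pruned.  This is denser than the bare kNN edge set
    and keeps well-connected point clouds from being split by modularity
    optimization.
    """
    X = np.asarray(cells, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of cells {n}")
    n_comp = min(n_pcs, X.shape[1], n - 1)
    if n_comp < X.shape[1]:
        X = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    # membership matrix of the (k+1)-sized neighborhoods (self included)
    rows = np.repeat(np.arange(n), k + 1)
    member = scipy.sparse.csr_matrix(
        (np.ones(n * (k + 1)), (rows, idx.ravel())), shape=(n, n)
    )
    member.data[:] = 1.0
    inter = (member @ member.T).tocoo()
    size = k + 1
    mask = inter.row < inter.col
    counts = inter.data[mask]
    jaccard = counts / (2 * size - counts)
    keep = jaccard >= PRUNE_SNN
    edge_list = list(zip(inter.row[mask][keep], inter.col[mask][keep]))
    g = ig.Graph(n=n, edges=edge_list)
    g.es["weight"] = list(jaccard[keep])
    return g


def modularity_cluster(
    graph: ig.Graph, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden modularity communities; returns 1-based contiguous labels."""
    if graph.vcount() == 0:
        raise ValidationError("cannot cluster an empty graph")
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(partition.membership, dtype=int)
    # relabel communities 1..c in order of first appearance for determinism
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], dtype=int)


def cluster_batches(
    batches: list[ExpressionBatch], config: ClusterConfig | None = None
) -> ClusterAssignment:
    """Cluster every batch independently on its scaled HVG matrix."""
    config = config or ClusterConfig()
    labels = {}
    for b in batches:
        g = knn_graph(b.values.T, k=config.k, n_pcs=config.n_pcs)
        labels[b.batch_id] = modularity_cluster(
            g, resolution=config.resolution, seed=config.seed
        )
    return ClusterAssignment(labels=labels)
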