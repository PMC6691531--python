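"""Evaluation of batch-correction quality on a 2D embedding.

Three complementary metrics, all computed on the same 2D coordinates (a
UMAP of the corrected embedding, or the embedding itself when it is already
two-dimensional):

* ``divergence_score`` — mean kNN-based KL-divergence estimate between the
  SHARED cell populations of every ordered batch pair.  Lower is better:
  shared cell types should be homogeneously mixed after correction.
* ``entropy_score`` — mean local batch-mixing entropy around cells of
  batch-SPECIFIC populations.  Lower is better: a population present in
  only one batch should stay pure, not be absorbed into other batches.
  Undefined (``None``) when every batch carries the same cell types.
* ``silhouette_score`` — mean silhouette coefficient with clusters defined
  by ground-truth cell types.  Higher is better: cell types should remain
  separate.

Shared/distinct populations are determined from ground-truth type labels,
so these metrics are for benchmarking on labeled data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_score as _sk_silhouette
from sklearn.neighbors import NearestNeighbors

from .datatypes import EvalReport, ValidationError


@dataclass
class EvalConfig:
    nn: int = 100          # neighborhood size for the local entropy
    k_div: int = 5         # k for the kNN divergence estimator
    umap_seed: int = 0
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1

    def validate(self) -> None:
        if self.nn < 2:
            raise ValidationError("nn must be >= 2")
        if self.k_div < 1:
            raise ValidationError("k_div must be >= 1")


def umap2d(embedding: np.ndarray, config: EvalConfig | None = None) -> np.ndarray:
    """Project to 2D with UMAP; identity pass-through for 2D input."""
    config = config or EvalConfig()
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("embedding must be a 2D array with >= 2 columns")
    if X.shape[1] == 2:
        return X.copy()
    if X.shape[0] < 10:
        raise ValidationError("need >= 10 cells for a UMAP embedding")
    import umap  # deferred: numba compilation is slow to import

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=config.umap_neighbors,
        min_dist=config.umap_min_dist,
        random_state=config.umap_seed,
    )
    return np.asarray(reducer.fit_transform(X), dtype=float)


def knn_kl_divergence(P: np.ndarray, Q: np.ndarray, k: int = 5) -> float:
    """kNN estimate of KL(P || Q) from samples (Wang-Kulkarni-Verdu form).

    D-hat = (d/n) * sum_i log(nu_k(i) / rho_k(i)) + log(m / (n - 1)),
    where rho_k(i) is the distance from p_i to its k-th nearest neighbor
    within P \\ {p_i} and nu_k(i) the distance to its k-th nearest neighbor
    within Q.  Distances are floored at 1e-12 to survive exact ties.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape[1] != Q.shape[1]:
        raise ValidationError("P and Q must share a dimension")
    n, m, d = P.shape[0], Q.shape[0], P.shape[1]
    if n < k + 1 or m < k + 1:
        raise ValidationError(f"need more than k={k} points in each sample")
    eps = 1e-12
    rho = NearestNeighbors(n_neighbors=k + 1).fit(P).kneighbors(P)[0][:, k]
    nu = NearestNeighbors(n_neighbors=k).fit(Q).kneighbors(P)[0][:, k - 1]
    rho = np.maximum(rho, eps)
    nu = np.maximum(nu, eps)
    return float((d / n) * np.sum(np.log(nu / rho)) + np.log(m / (n - 1)))


def _split_by_batch(batch_labels: np.ndarray) -> dict:
    return {b: np.flatnonzero(batch_labels == b) for b in np.unique(batch_labels)}


def divergence_score(
    coords: np.ndarray,
    batch_labels: np.ndarray,
    type_labels: np.ndarray,
    k: int = 5,
) -> tuple[float, int]:
    """Mean kNN divergence between shared populations of ordered batch pairs."""
    coords = np.asarray(coords, dtype=float)
    batch_labels = np.asarray(batch_labels, dtype=object)
    type_labels = np.asarray(type_labels, dtype=object)
    by_batch = _split_by_batch(batch_labels)
    if len(by_batch) < 2:
        raise ValidationError("divergence_score needs >= 2 batches")
    values = []
    for bi in by_batch:
        for bj in by_batch:
            if bi == bj:
                continue
            types_i = set(type_labels[by_batch[bi]])
            types_j = set(type_labels[by_batch[bj]])
            shared = types_i & types_j
            if not shared:
                continue
            sel_i = by_batch[bi][np.isin(type_labels[by_batch[bi]].astype(str),
                                         [str(t) for t in shared])]
            sel_j = by_batch[bj][np.isin(type_labels[by_batch[bj]].astype(str),
                                         [str(t) for t in shared])]
            values.append(knn_kl_divergence(coords[sel_i], coords[sel_j], k=k))
    if not values:
        raise ValidationError("no shared populations between any pair of batches")
    return float(np.mean(values)), len(values)


def local_entropy(neighbor_batches: np.ndarray) -> float:
    """Shannon entropy (nats) of batch proportions in one neighborhood.

    A neighborhood drawn purely from one batch scores 0; uniform mixing of
    n batches scores log(n).
    """
    neighbor_batches = np.asarray(neighbor_batches)
    if neighbor_batches.size == 0:
        raise ValidationError("empty neighborhood")
    _, counts = np.unique(neighbor_batches, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def entropy_score(
    coords: np.ndarray,
    batch_labels: np.ndarray,
    type_labels: np.ndarray,
    nn: int = 100,
) -> tuple[float | None, int]:
    """Mean local entropy around batch-specific populations.

    For every ordered batch pair (i, j) such that batch i carries cell types
    absent from batch j, the entropy of batch proportions among each such
    cell's ``nn`` nearest neighbors (in the full embedding) is averaged.
    Returns (None, 0) when no batch-specific population exists.
    """
    coords = np.asarray(coords, dtype=float)
    batch_labels = np.asarray(batch_labels, dtype=object)
    type_labels = np.asarray(type_labels, dtype=object)
    by_batch = _split_by_batch(batch_labels)
    n_neighbors = min(nn + 1, coords.shape[0])
    nbrs = NearestNeighbors(n_neighbors=n_neighbors).fit(coords)
    pair_means = []
    entropy_cache: dict[int, float] = {}
    for bi in by_batch:
        for bj in by_batch:
            if bi == bj:
                continue
            types_i = set(type_labels[by_batch[bi]])
            types_j = set(type_labels[by_batch[bj]])
            distinct = types_i - types_j
            if not distinct:
                continue
            cells = by_batch[bi][np.isin(type_labels[by_batch[bi]].astype(str),
                                         [str(t) for t in distinct])]
            vals = []
            for c in cells:
                if c not in entropy_cache:
                    idx = nbrs.kneighbors(coords[c][None, :])[1][0]
                    idx = idx[idx != c][: n_neighbors - 1]
                    entropy_cache[c] = local_entropy(batch_labels[idx])
                vals.append(entropy_cache[c])
            pair_means.append(float(np.mean(vals)))
    if not pair_means:
        return None, 0
    return float(np.mean(pair_means)), len(pair_means)


def silhouette_score(coords: np.ndarray, type_labels: np.ndarray) -> float:
    """Mean silhouette coefficient with clusters = cell types (Euclidean)."""
    coords = np.asarray(coords, dtype=float)
    type_labels = np.asarray(type_labels).astype(str)
    if len(np.unique(type_labels)) < 2:
        raise ValidationError("silhouette_score needs >= 2 cell types")
    return float(_sk_silhouette(coords, type_labels, metric="euclidean"))


def evaluate(
    embedding: np.ndarray,
    batch_labels: np.ndarray,
    type_labels: np.ndarray,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Project to 2D once, then compute all three metrics on the same coords."""
    config = config or EvalConfig()
    config.validate()
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] != len(batch_labels) or embedding.shape[0] != len(
        type_labels
    ):
        raise ValidationError("labels must align with embedding rows")
    coords = umap2d(embedding, config)
    div, n_div = divergence_score(coords, batch_labels, type_labels, k=config.k_div)
    ent, n_ent = entropy_score(coords, batch_labels, type_labels, nn=config.nn)
    sil = silhouette_score(coords, type_labels)
    return EvalReport(
        divergence_score=div,
        entropy_score=ent,
        silhouette_score=sil,
        n_div=n_div,
        n_ent=n_ent,
        config={
            "nn": config.nn,
            "k_div": config.k_div,
            "umap_seed": config.umap_seed,
            "umap_neighbors": config.umap_neighbors,
            "umap_min_dist": config.umap_min_dist,
        },
    )
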