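"""Cross-batch cluster similarity by neighbor-voting AUROC, and its
reduction to the binary alignment mask.

For every pair of batches, cells are linked by a Spearman-correlation
network over the highly variable genes, computed on the log-transformed
expression (per-batch standardization would make the cross-gene ranks
depend on each batch's cell composition, so it is deliberately NOT applied
before correlation).  The network is rank-normalized globally to (0, 1];
a candidate cluster from the other batch "votes" for a cell with the mean
normalized correlation to its members.
The AUROC of a cluster's own cells against the rest of their batch under
those votes is the raw similarity score — high when the two clusters'
cells point at each other.  The raw score tensor is then reduced in three
steps:

1. best-hit filter — for each cluster keep only its top-scoring cluster(s)
   in every other batch;
2. symmetrization — take the elementwise max of the two directions, so a
   cluster split in two by over-clustering can still match both halves;
3. binarization at the threshold ``s_thr`` — scores below threshold vanish,
   which leaves genuinely batch-specific clusters unaligned.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .datatypes import (
    ClusterAssignment,
    ExpressionBatch,
    SimilarityMatrix,
    ValidationError,
)


def _spearman_cross(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Spearman correlation between columns of A and columns of B (genes as rows)."""
    ra = rankdata(A, axis=0)
    rb = rankdata(B, axis=0)
    ra = ra - ra.mean(axis=0, keepdims=True)
    rb = rb - rb.mean(axis=0, keepdims=True)
    na = np.sqrt((ra**2).sum(axis=0))
    nb = np.sqrt((rb**2).sum(axis=0))
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (ra.T @ rb) / np.outer(na, nb)


def _auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUROC of `positives` under `scores`; 1.0 when there are no negatives."""
    if positives.all():
        return 1.0
    if not positives.any():
        raise ValidationError("AUROC needs at least one positive cell")
    return float(roc_auc_score(positives, scores))


def _vote_aurocs(
    corr: np.ndarray,
    source_labels: np.ndarray,
    target_labels: np.ndarray,
    n_source: int,
    n_target: int,
) -> np.ndarray:
    """AUROC[j_source, j_target]: votes from source clusters score target cells.

    ``corr`` is (source cells x target cells), already rank-normalized
    globally over the whole cross-batch network.
    """
    norm = corr
    out = np.zeros((n_source, n_target))
    for js in range(1, n_source + 1):
        members = source_labels == js
        votes = norm[members].mean(axis=0)
        for jt in range(1, n_target + 1):
            out[js - 1, jt - 1] = _auroc(votes, target_labels == jt)
    return out


def metaneighbor_similarity(
    batches: list[ExpressionBatch], assignment: ClusterAssignment
) -> SimilarityMatrix:
    """Raw cross-batch cluster-pair similarity scores.

    Expression should be at the log (or tpm) stage on the HVGs; the
    Spearman network is rank-normalized globally per batch pair before
    voting.  For each batch pair the two voting directions (a scores b's
    cells and vice versa) are averaged into one raw score per cluster pair
    (averaging is protective: a single spuriously hot direction cannot
    align two clusters on its own).  Within-batch entries are fixed at
    zero.  Clusters with fewer than two cells trigger a low-confidence
    warning but are still scored.
    """
    if len(batches) < 2:
        raise ValidationError("similarity needs at least two batches")
    gene_ids = batches[0].gene_ids
    if any(b.gene_ids != gene_ids for b in batches):
        raise ValidationError("batches must share one gene list")
    by_id = {b.batch_id: b for b in batches}
    clusters = assignment.cluster_pairs()
    for bid, labels in assignment.labels.items():
        sizes = np.bincount(labels)[1:]
        if np.any(sizes < 2):
            warnings.warn(
                f"batch {bid} has cluster(s) with < 2 cells; "
                "their similarity scores are low-confidence"
            )
    index = {cl: i for i, cl in enumerate(clusters)}
    M = np.zeros((len(clusters), len(clusters)))

    batch_ids = assignment.batch_ids
    for ai in range(len(batch_ids)):
        for bi in range(ai + 1, len(batch_ids)):
            a, b = batch_ids[ai], batch_ids[bi]
            la, lb = assignment.labels[a], assignment.labels[b]
            ca, cb = assignment.n_clusters(a), assignment.n_clusters(b)
            corr = _spearman_cross(by_id[a].values, by_id[b].values)
            corr = rankdata(corr, axis=None).reshape(corr.shape) / corr.size
            auc_ab = _vote_aurocs(corr, la, lb, ca, cb)   # a votes, b scored
            auc_ba = _vote_aurocs(corr.T, lb, la, cb, ca)  # b votes, a scored
            raw = 0.5 * (auc_ab + auc_ba.T)
            for ja in range(1, ca + 1):
                for jb in range(1, cb + 1):
                    v = raw[ja - 1, jb - 1]
                    M[index[(a, ja)], index[(b, jb)]] = v
                    M[index[(b, jb)], index[(a, ja)]] = v
    return SimilarityMatrix(clusters=clusters, values=M, stage="raw")


def best_hit_filter(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Keep, per source cluster and per other batch, only the maximal score.

    Ties keep every tied maximum.  Operates row-wise, so the result is in
    general no longer symmetric until :func:`symmetrize`.
    """
    if sim.stage != "raw":
        raise ValidationError("best_hit_filter expects a raw similarity matrix")
    M = sim.values.copy()
    batches = [b for b, _ in sim.clusters]
    batch_arr = np.array(batches, dtype=object)
    for i in range(M.shape[0]):
        for other in sorted(set(batches) - {batches[i]}):
            cols = np.flatnonzero(batch_arr == other)
            row = M[i, cols]
            peak = row.max()
            keep = row == peak
            row = np.where(keep, row, 0.0)
            M[i, cols] = row
    return SimilarityMatrix(clusters=sim.clusters, values=M, stage="best-hit")


def symmetrize(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise max of the two directions."""
    if sim.stage != "best-hit":
        raise ValidationError("symmetrize expects a best-hit similarity matrix")
    M = np.maximum(sim.values, sim.values.T)
    return SimilarityMatrix(clusters=sim.clusters, values=M, stage="symmetric")


def binarize(sim: SimilarityMatrix, s_thr: float) -> SimilarityMatrix:
    """Alignment mask: 1 where the symmetric score reaches ``s_thr``."""
    if sim.stage != "symmetric":
        raise ValidationError("binarize expects a symmetric similarity matrix")
    if not 0.0 < s_thr < 1.0:
        raise ValidationError("s_thr must lie in (0, 1)")
    M = (sim.values >= s_thr).astype(float)
    M[sim.within_batch_mask()] = 0.0
    return SimilarityMatrix(
        clusters=sim.clusters, values=M, stage="binary", s_thr=s_thr
    )


def similarity_pipeline(
    batches: list[ExpressionBatch],
    assignment: ClusterAssignment,
    s_thr: float = 0.90,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """raw -> best-hit -> symmetric -> binary; returns (raw, binary mask)."""
    raw = metaneighbor_similarity(batches, assignment)
    mask = binarize(symmetrize(best_hit_filter(raw)), s_thr)
    return raw, mask
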