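"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionBatch`, a genes-by-cells matrix for a
single sequencing batch with an explicit processing-stage tag.  Stages form a
one-way pipeline: ``counts -> tpm -> log -> standardized -> scaled``.  Every
transform validates the stage of its input so that, e.g., the autoencoder can
never be fed un-scaled data by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

STAGES = ("counts", "tpm", "log", "standardized", "scaled")


class ValidationError(ValueError):
    """Raised when an input violates a stage or shape contract."""


@dataclass
class ExpressionBatch:
    """One batch's expression matrix (genes x cells).

    Parameters
    ----------
    batch_id:
        Name of the batch (e.g. ``"Batch1"``).
    gene_ids, cell_ids:
        Ordered identifiers for the rows and columns of ``values``.
    values:
        Dense ``(n_genes, n_cells)`` float array.
    stage:
        One of ``counts``, ``tpm``, ``log``, ``standardized``, ``scaled``.
    cell_type_labels:
        Optional per-cell ground-truth labels, used only for evaluation and
        for the cell-type-removal experiment designs.
    """

    batch_id: str
    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    stage: str
    cell_type_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2D genes x cells matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.stage == "counts":
            if np.any(self.values < 0) or not np.allclose(
                self.values, np.round(self.values)
            ):
                raise ValidationError("counts stage requires nonnegative integers")
        if self.stage == "scaled":
            if self.values.size and (
                self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9
            ):
                raise ValidationError("scaled stage requires values in [0, 1]")
        if self.cell_type_labels is not None:
            self.cell_type_labels = np.asarray(self.cell_type_labels, dtype=object)
            if len(self.cell_type_labels) != len(self.cell_ids):
                raise ValidationError("cell_type_labels length != number of cells")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def with_values(self, values: np.ndarray, stage: str) -> "ExpressionBatch":
        """Copy of this batch with a new matrix and stage tag."""
        return replace(self, values=values, stage=stage)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionBatch":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise ValidationError(f"genes not present in batch: {missing[:5]}...")
        rows = [index[g] for g in gene_ids]
        return replace(self, gene_ids=list(gene_ids), values=self.values[rows])

    def subset_cells(self, mask: np.ndarray) -> "ExpressionBatch":
        mask = np.asarray(mask, dtype=bool)
        cells = [c for c, m in zip(self.cell_ids, mask) if m]
        labels = None
        if self.cell_type_labels is not None:
            labels = self.cell_type_labels[mask]
        return replace(
            self, cell_ids=cells, values=self.values[:, mask], cell_type_labels=labels
        )


@dataclass
class ClusterAssignment:
    """Per-batch cluster labels, one independent clustering per batch.

    Cluster indices are contiguous integers starting at 1 within each batch.
    """

    labels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for batch_id, lab in self.labels.items():
            lab = np.asarray(lab, dtype=int)
            self.labels[batch_id] = lab
            if lab.size == 0:
                raise ValidationError(f"batch {batch_id} has no labeled cells")
            uniq = np.unique(lab)
            if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
                raise ValidationError(
                    f"cluster indices of batch {batch_id} must be 1..c_i, got {uniq}"
                )

    @property
    def batch_ids(self) -> list[str]:
        return list(self.labels)

    def n_clusters(self, batch_id: str) -> int:
        return int(self.labels[batch_id].max())

    @property
    def total_clusters(self) -> int:
        return sum(self.n_clusters(b) for b in self.labels)

    def cluster_pairs(self) -> list[tuple[str, int]]:
        """Global (batch_id, cluster) index list, the axis of SimilarityMatrix."""
        return [
            (b, j)
            for b in self.labels
            for j in range(1, self.n_clusters(b) + 1)
        ]


SIMILARITY_STAGES = ("raw", "best-hit", "symmetric", "binary")


@dataclass
class SimilarityMatrix:
    """Cross-batch cluster-pair similarity scores.

    A square matrix over the global cluster list ``clusters`` (entries in
    ``[0, 1]``), refined in stages: ``raw`` neighbor-voting AUROCs, best-hit
    filtered, symmetrized, and finally binarized at the threshold ``s_thr``
    into the alignment mask consumed by the transfer loss.  Entries between
    clusters of the same batch are identically zero at every stage.
    """

    clusters: list[tuple[str, int]]
    values: np.ndarray
    stage: str
    s_thr: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.clusters)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix shape does not match clusters")
        if self.stage not in SIMILARITY_STAGES:
            raise ValidationError(f"unknown similarity stage {self.stage!r}")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValidationError("similarity scores must lie in [0, 1]")
        within = self.within_batch_mask()
        if np.any(self.values[within] != 0):
            raise ValidationError("within-batch similarity entries must be 0")
        if self.stage in ("symmetric", "binary") and not np.array_equal(
            self.values, self.values.T
        ):
            raise ValidationError(f"stage {self.stage} requires a symmetric matrix")
        if self.stage == "binary" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValidationError("binary stage requires entries in {0, 1}")

    def within_batch_mask(self) -> np.ndarray:
        batches = np.array([b for b, _ in self.clusters], dtype=object)
        return batches[:, None] == batches[None, :]

    def index(self, batch_id: str, cluster: int) -> int:
        return self.clusters.index((batch_id, cluster))

    def aligned_pairs(self) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        """Unordered aligned cluster pairs of a binary mask."""
        if self.stage != "binary":
            raise ValidationError("aligned_pairs requires a binary mask")
        out = []
        n = len(self.clusters)
        for a in range(n):
            for b in range(a + 1, n):
                if self.values[a, b] == 1:
                    out.append((self.clusters[a], self.clusters[b]))
        return out


@dataclass
class EvalReport:
    """The three evaluation metrics plus their batch-pair counts."""

    divergence_score: float
    entropy_score: Optional[float]
    silhouette_score: float
    n_div: int
    n_ent: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "divergence_score": self.divergence_score,
            "entropy_score": self.entropy_score,
            "silhouette_score": self.silhouette_score,
            "n_div": self.n_div,
            "n_ent": self.n_ent,
            "config": self.config,
        }
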