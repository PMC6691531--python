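"""Synthetic multi-batch scRNA-seq data.

Two generator families make every downstream stage testable without real
data:

* :func:`simulate_gaussian` — cell types as bivariate normal clouds in a 2D
  biological subspace, randomly projected into a high-dimensional ambient
  ("gene") space, with gene-specific additive batch offsets and per-entry
  noise.  Continuous, TPM-like, nonnegative.
* :func:`simulate_counts` — a reduced gamma-Poisson count simulator in the
  Splatter mould: gamma gene base means, lognormal per-group DE factors,
  lognormal per-batch batch factors, lognormal library sizes, Poisson counts.

:func:`remove_cell_type` applies the removal experiment designs (dropping a
cell type from one batch) used to stress batch correction under unequal cell
population compositions.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import ExpressionBatch, ValidationError


class ConfigError(ValueError):
    """Raised for invalid simulator configurations."""


def _default_type_means() -> list[np.ndarray]:
    return [np.array(m, dtype=float) for m in ((0, 0), (0, 5), (5, 0), (5, 5))]


@dataclass
class GaussianSimConfig:
    """Configuration of the 2D-Gaussian ambient-projection simulator.

    ``batch_noise_sd`` is the per-entry noise; ``batch_offset_sd`` the scale
    of the gene-specific additive offset shared by all cells of a batch.
    Setting both to zero yields batches drawn from one distribution.
    """

    n_batches: int = 2
    cells_per_batch: int = 2000
    n_types: int = 4
    type_means: list[np.ndarray] = field(default_factory=_default_type_means)
    type_covs: Optional[list[np.ndarray]] = None  # default: identity each
    composition_mode: str = "random"  # "random" (Dirichlet) or "fixed"
    proportions: Optional[Sequence[float]] = None  # used when mode == "fixed"
    ambient_dim: int = 100
    batch_offset_sd: float = 1.0
    batch_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 1 or self.cells_per_batch < 1 or self.n_types < 1:
            raise ConfigError("batches, cells and types must be positive")
        if self.ambient_dim < 2:
            raise ConfigError("ambient_dim must be >= 2")
        if len(self.type_means) != self.n_types:
            raise ConfigError("need one 2D mean per cell type")
        covs = self.covariances()
        for c in covs:
            c = np.asarray(c, dtype=float)
            if c.shape != (2, 2):
                raise ConfigError("covariances must be 2x2")
            try:
                np.linalg.cholesky(c)
            except np.linalg.LinAlgError as exc:
                raise ConfigError("covariance matrix not positive definite") from exc
        if self.composition_mode not in ("random", "fixed"):
            raise ConfigError("composition_mode must be 'random' or 'fixed'")
        if self.composition_mode == "fixed":
            p = np.asarray(
                self.proportions
                if self.proportions is not None
                else np.full(self.n_types, 1.0 / self.n_types)
            )
            if len(p) != self.n_types or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError("fixed proportions must sum to 1 over types")
        if self.batch_noise_sd < 0 or self.batch_offset_sd < 0:
            raise ConfigError("noise scales must be nonnegative")

    def covariances(self) -> list[np.ndarray]:
        if self.type_covs is None:
            return [np.eye(2) for _ in range(self.n_types)]
        return [np.asarray(c, dtype=float) for c in self.type_covs]


@dataclass
class CountSimConfig:
    """Configuration of the reduced gamma-Poisson count simulator.

    Hyperparameter defaults follow common Splatter-style settings: gamma
    base means with mean ``shape/rate``, lognormal DE factors on a
    ``de_prob`` fraction of genes per group, lognormal batch factors on all
    genes, and lognormal library sizes.
    """

    n_batches: int = 2
    cells_per_batch: Sequence[int] = (2000, 1000)
    n_genes: int = 5000
    group_proportions: Sequence[float] = (0.4, 0.3, 0.2, 0.1)
    gene_mean_shape: float = 0.6
    gene_mean_rate: float = 0.3
    libsize_logmean: float = 10.5
    libsize_logsd: float = 0.25
    de_prob: float = 0.1
    de_factor_logsd: float = 0.4
    batch_factor_logsd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 1 or self.n_genes < 1:
            raise ConfigError("need at least one batch and one gene")
        if len(self.cells_per_batch) != self.n_batches:
            raise ConfigError("cells_per_batch must list one count per batch")
        if any(c < 1 for c in self.cells_per_batch):
            raise ConfigError("every batch needs at least one cell")
        p = np.asarray(self.group_proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigError("group_proportions must sum to 1 within 1e-12")
        if np.any(p < 0):
            raise ConfigError("group_proportions must be nonnegative")
        for name in ("gene_mean_shape", "gene_mean_rate", "libsize_logmean",
                     "libsize_logsd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ConfigError("de_prob must lie in [0, 1]")
        if self.de_factor_logsd < 0 or self.batch_factor_logsd < 0:
            raise ConfigError("lognormal scales must be nonnegative")


@dataclass
class SimulatedDataset:
    """Batches plus the ground truth needed by the evaluation metrics."""

    batches: list[ExpressionBatch]
    true_subspace_coords: Optional[dict[str, np.ndarray]] = None
    provenance: Optional[object] = None

    @property
    def batch_ids(self) -> list[str]:
        return [b.batch_id for b in self.batches]

    def batch(self, batch_id: str) -> ExpressionBatch:
        for b in self.batches:
            if b.batch_id == batch_id:
                return b
        raise KeyError(f"no batch named {batch_id!r}")

    @property
    def type_labels(self) -> dict[str, np.ndarray]:
        return {b.batch_id: b.cell_type_labels for b in self.batches}


def _type_counts(rng, n_cells, n_types, mode, proportions):
    if mode == "random":
        props = rng.dirichlet(np.ones(n_types))
    else:
        props = np.asarray(
            proportions if proportions is not None else np.full(n_types, 1.0 / n_types),
            dtype=float,
        )
    return rng.multinomial(n_cells, props)


def simulate_gaussian(config: GaussianSimConfig) -> SimulatedDataset:
    """Simulate TPM-like batches from a 2D biological subspace.

    Each cell type is a bivariate normal in a 2D "biological" plane.  One
    random linear projection (shared by all batches) lifts coordinates into
    ``ambient_dim`` gene-like dimensions; batch effects are gene-specific
    additive normal offsets plus entrywise noise, applied after projection.
    The pooled data are shifted by the global minimum and clipped at zero so
    the result behaves like nonnegative TPM input.  The true 2D coordinates
    are returned for oracle checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    covs = config.covariances()
    projection = rng.normal(size=(2, config.ambient_dim))
    gene_ids = [f"gene{i + 1}" for i in range(config.ambient_dim)]

    raw_batches: list[tuple[str, np.ndarray, np.ndarray, list[str]]] = []
    coords_by_batch: dict[str, np.ndarray] = {}
    for b in range(config.n_batches):
        batch_id = f"Batch{b + 1}"
        counts = _type_counts(
            rng, config.cells_per_batch, config.n_types,
            config.composition_mode, config.proportions,
        )
        coords = np.empty((config.cells_per_batch, 2))
        labels: list[str] = []
        row = 0
        for t, n_t in enumerate(counts):
            if n_t:
                coords[row:row + n_t] = rng.multivariate_normal(
                    np.asarray(config.type_means[t], dtype=float), covs[t], size=n_t
                )
            labels += [f"Type{t + 1}"] * n_t
            row += n_t
        ambient = coords @ projection
        offsets = rng.normal(scale=config.batch_offset_sd or 0.0,
                             size=config.ambient_dim) if config.batch_offset_sd > 0 \
            else np.zeros(config.ambient_dim)
        ambient = ambient + offsets[None, :]
        if config.batch_noise_sd > 0:
            ambient = ambient + rng.normal(
                scale=config.batch_noise_sd, size=ambient.shape
            )
        coords_by_batch[batch_id] = coords
        raw_batches.append((batch_id, ambient, counts, labels))

    global_min = min(arr.min() for _, arr, _, _ in raw_batches)
    shift = -global_min if global_min < 0 else 0.0

    batches = []
    for batch_id, ambient, _, labels in raw_batches:
        values = np.clip(ambient + shift, 0.0, None).T  # genes x cells
        cell_ids = [f"{batch_id}_C{i + 1}" for i in range(values.shape[1])]
        batches.append(
            ExpressionBatch(
                batch_id=batch_id,
                gene_ids=list(gene_ids),
                cell_ids=cell_ids,
                values=values,
                stage="tpm",
                cell_type_labels=np.array(labels, dtype=object),
            )
        )
    return SimulatedDataset(
        batches=batches, true_subspace_coords=coords_by_batch, provenance=config
    )


def simulate_counts(config: CountSimConfig) -> SimulatedDataset:
    """Simulate multi-batch UMI-like counts from a gamma-Poisson hierarchy."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_groups = len(config.group_proportions)
    n_genes = config.n_genes

    base_means = rng.gamma(config.gene_mean_shape, 1.0 / config.gene_mean_rate,
                           size=n_genes)
    # Per-group DE factors on a random de_prob fraction of genes.
    de_factors = np.ones((n_groups, n_genes))
    if config.de_prob > 0 and config.de_factor_logsd > 0:
        for g in range(n_groups):
            is_de = rng.random(n_genes) < config.de_prob
            de_factors[g, is_de] = rng.lognormal(
                0.0, config.de_factor_logsd, size=int(is_de.sum())
            )
    # Per-batch multiplicative batch effect on every gene.
    batch_factors = np.ones((config.n_batches, n_genes))
    if config.batch_factor_logsd > 0:
        batch_factors = rng.lognormal(
            0.0, config.batch_factor_logsd, size=(config.n_batches, n_genes)
        )

    gene_ids = [f"gene{i + 1}" for i in range(n_genes)]
    batches = []
    for b in range(config.n_batches):
        batch_id = f"Batch{b + 1}"
        n_cells = int(config.cells_per_batch[b])
        group_counts = rng.multinomial(n_cells, np.asarray(config.group_proportions))
        labels = np.repeat(
            [f"Type{g + 1}" for g in range(n_groups)], group_counts
        ).astype(object)
        libsizes = rng.lognormal(config.libsize_logmean, config.libsize_logsd,
                                 size=n_cells)
        group_of_cell = np.repeat(np.arange(n_groups), group_counts)
        cell_means = base_means[None, :] * de_factors[group_of_cell, :]
        cell_means = cell_means * batch_factors[b][None, :]
        cell_means = cell_means / cell_means.sum(axis=1, keepdims=True)
        cell_means = cell_means * libsizes[:, None]
        counts = rng.poisson(cell_means).astype(float).T  # genes x cells
        cell_ids = [f"{batch_id}_C{i + 1}" for i in range(n_cells)]
        batches.append(
            ExpressionBatch(
                batch_id=batch_id,
                gene_ids=list(gene_ids),
                cell_ids=cell_ids,
                values=counts,
                stage="counts",
                cell_type_labels=labels,
            )
        )
    return SimulatedDataset(batches=batches, provenance=config)


def remove_cell_type(
    dataset: SimulatedDataset, batch_id: str, type_label: str
) -> SimulatedDataset:
    """Drop every cell of ``type_label`` from one batch, leaving others intact.

    Emits a warning (and returns an equivalent copy) when the type exists in
    the dataset but not in the named batch; raises ``KeyError`` when the
    batch or the type is unknown altogether.
    """
    dataset.batch(batch_id)  # KeyError if the batch is unknown
    all_types: set = set()
    for b in dataset.batches:
        if b.cell_type_labels is None:
            raise ValidationError("remove_cell_type requires cell type labels")
        all_types.update(b.cell_type_labels.tolist())
    if type_label not in all_types:
        raise KeyError(f"cell type {type_label!r} not present in the dataset")

    new_batches = []
    coords = copy.deepcopy(dataset.true_subspace_coords)
    for b in dataset.batches:
        if b.batch_id != batch_id:
            new_batches.append(copy.deepcopy(b))
            continue
        mask = b.cell_type_labels != type_label
        if mask.all():
            warnings.warn(
                f"cell type {type_label!r} absent from batch {batch_id}; "
                "dataset unchanged"
            )
        new_batches.append(b.subset_cells(mask))
        if coords is not None and batch_id in coords:
            coords[batch_id] = coords[batch_id][mask]
    return SimulatedDataset(
        batches=new_batches, true_subspace_coords=coords,
        provenance=dataset.provenance,
    )
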