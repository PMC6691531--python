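"""Preprocessing: library-size normalization, log transform, highly variable
gene selection, per-batch standardization and pooled [0, 1] scaling.

The pipeline turns raw per-batch expression into the matrix that feeds both
clustering and the autoencoder:

    counts --(CPM)--> tpm --(log2(x+1))--> log --(HVG restrict)-->
    --(per-batch z-score)--> standardized --(pooled min-max)--> scaled

Library-size normalization is counts-per-million: UMI and simulated data
carry no gene lengths, and the per-gene standardization downstream makes a
constant length factor irrelevant anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionBatch, ValidationError


@dataclass
class GeneStats:
    """Per-batch per-gene mean and standard deviation used by standardize."""

    batch_id: str
    gene_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray


@dataclass
class PreprocessConfig:
    n_hvg: int = 2000
    n_bins: int = 20
    sd_ddof: int = 1  # sample standard deviation

    def validate(self) -> None:
        if self.n_hvg < 1:
            raise ValidationError("n_hvg must be >= 1")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")


def to_tpm(batch: ExpressionBatch) -> ExpressionBatch:
    """Rescale every cell to one million total counts (CPM)."""
    if batch.stage != "counts":
        raise ValidationError(f"to_tpm expects stage 'counts', got {batch.stage!r}")
    totals = batch.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero cell(s) in batch {batch.batch_id}; "
            "left all-zero"
        )
    safe = np.where(zero, 1.0, totals)
    tpm = batch.values / safe[None, :] * 1e6
    return batch.with_values(tpm, "tpm")


def log_transform(batch: ExpressionBatch) -> ExpressionBatch:
    """G_ij = log2(TPM_ij + 1)."""
    if batch.stage != "tpm":
        raise ValidationError(f"log_transform expects stage 'tpm', got {batch.stage!r}")
    if np.any(batch.values < 0):
        raise ValidationError("negative expression values cannot be log-transformed")
    return batch.with_values(np.log2(batch.values + 1.0), "log")


def _dispersion_zscores(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Z-score of variance/mean dispersion within equal-count mean bins.

    Means and variances are accumulated over SORTED values so the result is
    bit-identical under any permutation of the cells; the equal-count bin
    edges are discontinuous, so even 1-ulp differences in a gene mean could
    otherwise flip its bin and change the selected gene set.
    """
    # contiguous layout: numpy's pairwise summation rounds differently on
    # strided arrays, which would break exact invariance as well
    values = np.ascontiguousarray(values)
    n = values.shape[1]
    mean = np.sort(values, axis=1).mean(axis=1)
    if n > 1:
        sq = np.ascontiguousarray((values - mean[:, None]) ** 2)
        sq.sort(axis=1)
        var = sq.sum(axis=1) / (n - 1)
    else:
        var = np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    df = pd.DataFrame({"mean": mean, "disp": disp})
    # Equal-count bins on the mean; duplicate edges collapse for ties.
    try:
        df["bin"] = pd.qcut(df["mean"], q=min(n_bins, len(df)), duplicates="drop")
    except ValueError:
        df["bin"] = 0  # all means identical
    grouped = df.groupby("bin", observed=True)["disp"]
    centers = grouped.transform("mean")
    spreads = grouped.transform("std").fillna(0.0)
    z = (df["disp"] - centers) / spreads.replace(0.0, np.nan)
    return z.fillna(0.0).to_numpy()


def select_hvg(
    batches: list[ExpressionBatch], config: PreprocessConfig | None = None
) -> list[str]:
    """Rank genes by cross-batch mean dispersion z-score; return the top set.

    Within each batch, genes are binned into ``n_bins`` equal-count bins by
    mean log expression and their variance/mean dispersion is z-scored
    within its bin, so high variability is judged relative to genes of
    comparable expression.  Genes are ranked by the across-batch mean
    z-score; the top ``n_hvg`` genes (present in every batch) are returned.
    """
    config = config or PreprocessConfig()
    config.validate()
    if not batches:
        raise ValidationError("select_hvg needs at least one batch")
    gene_ids = batches[0].gene_ids
    for b in batches:
        if b.stage != "log":
            raise ValidationError("select_hvg expects log-stage batches")
        if b.gene_ids != gene_ids:
            raise ValidationError("all batches must share one gene ID list")
    zs = np.vstack([_dispersion_zscores(b.values, config.n_bins) for b in batches])
    mean_z = zs.mean(axis=0)
    if config.n_hvg >= len(gene_ids):
        if config.n_hvg > len(gene_ids):
            warnings.warn(
                f"n_hvg={config.n_hvg} exceeds {len(gene_ids)} genes; keeping all"
            )
        return list(gene_ids)
    order = np.argsort(-mean_z, kind="stable")[: config.n_hvg]
    return [gene_ids[i] for i in order]


def standardize(
    batch: ExpressionBatch, ddof: int = 1
) -> tuple[ExpressionBatch, GeneStats]:
    """Per-gene z-score within the batch: G' = (G - mean) / sd.

    Uses the sample standard deviation (ddof=1) by default.  Genes with zero
    spread map to all zeros.
    """
    if batch.stage != "log":
        raise ValidationError(f"standardize expects stage 'log', got {batch.stage!r}")
    if batch.n_cells < 2:
        raise ValidationError("standardize needs >= 2 cells per batch")
    mean = batch.values.mean(axis=1)
    sd = batch.values.std(axis=1, ddof=ddof)
    safe_sd = np.where(sd > 0, sd, 1.0)
    standardized = (batch.values - mean[:, None]) / safe_sd[:, None]
    standardized[sd == 0, :] = 0.0
    stats = GeneStats(batch.batch_id, list(batch.gene_ids), mean, sd)
    return batch.with_values(standardized, "standardized"), stats


def minmax_scale(batches: list[ExpressionBatch]) -> list[ExpressionBatch]:
    """Per-gene linear map of the POOLED (all batches) range onto [0, 1].

    Pooling keeps every batch on the same scale so a single autoencoder sees
    comparable inputs.  A gene with zero pooled range maps to all zeros.
    """
    if not batches:
        raise ValidationError("minmax_scale needs at least one batch")
    gene_ids = batches[0].gene_ids
    for b in batches:
        if b.stage != "standardized":
            raise ValidationError("minmax_scale expects standardized batches")
        if b.gene_ids != gene_ids:
            raise ValidationError("all batches must share one gene ID list")
    pooled = np.hstack([b.values for b in batches])
    lo = pooled.min(axis=1)
    hi = pooled.max(axis=1)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = []
    for b in batches:
        scaled = (b.values - lo[:, None]) / safe[:, None]
        scaled[span == 0, :] = 0.0
        out.append(b.with_values(np.clip(scaled, 0.0, 1.0), "scaled"))
    return out


def preprocess_pipeline(
    batches: list[ExpressionBatch], config: PreprocessConfig | None = None
) -> tuple[list[ExpressionBatch], list[str], list[GeneStats]]:
    """counts/tpm input -> scaled HVG matrices + gene list + per-batch stats."""
    config = config or PreprocessConfig()
    config.validate()
    if not batches:
        raise ValidationError("preprocess_pipeline needs at least one batch")
    staged = []
    for b in batches:
        if b.stage == "counts":
            b = to_tpm(b)
        if b.stage != "tpm":
            raise ValidationError(
                f"pipeline expects counts or tpm input, got {b.stage!r}"
            )
        staged.append(log_transform(b))
    hvg = select_hvg(staged, config)
    restricted = [b.subset_genes(hvg) for b in staged]
    standardized, stats = [], []
    for b in restricted:
        sb, st = standardize(b, ddof=config.sd_ddof)
        standardized.append(sb)
        stats.append(st)
    scaled = minmax_scale(standardized)
    return scaled, hvg, stats
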