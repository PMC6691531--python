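"""Readers and writers for the on-disk formats.

Expression matrices travel either as dense CSV/TSV (genes as rows, first
column gene IDs, header row of cell IDs) or as a Matrix Market directory
(``matrix.mtx`` with ``genes.tsv`` / ``barcodes.tsv`` sidecars, genes x
cells).  Labels are TSV with columns cell_id, batch, cell_type; embeddings
are CSV with cell_id, batch, z1..zd; evaluation reports are JSON.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import EvalReport, ExpressionBatch, SimilarityMatrix, ValidationError


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


def _infer_stage(values: np.ndarray) -> str:
    if values.size and np.all(values >= 0) and np.allclose(values, np.round(values)):
        return "counts"
    return "tpm"


def read_expression(path, batch_id=None, stage=None) -> ExpressionBatch:
    """Load one batch from dense CSV/TSV or from an MTX directory.

    ``path`` may be a file (``.csv``/``.tsv``) or a directory containing
    ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``.  Stage is inferred
    (integral nonnegative -> counts, else tpm) unless given explicitly.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path, batch_id, stage)
    if path.suffix.lower() in (".csv", ".tsv", ".txt"):
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        return ExpressionBatch(
            batch_id=batch_id or path.stem,
            gene_ids=[str(g) for g in df.index],
            cell_ids=[str(c) for c in df.columns],
            values=values,
            stage=stage or _infer_stage(values),
        )
    raise FormatError(f"unrecognized expression format: {path}")


def _read_mtx_dir(path: Path, batch_id, stage) -> ExpressionBatch:
    mtx = path / "matrix.mtx"
    genes_f = path / "genes.tsv"
    barcodes_f = path / "barcodes.tsv"
    for f in (mtx, genes_f, barcodes_f):
        if not f.exists():
            raise FormatError(f"missing {f.name} in MTX directory {path}")
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as exc:
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    genes = genes_f.read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g]
    barcodes = [b for b in barcodes_f.read_text().splitlines() if b]
    values = np.asarray(mat.todense(), dtype=float)
    if values.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{mtx}: matrix is {values.shape} but sidecars list "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    return ExpressionBatch(
        batch_id=batch_id or path.name,
        gene_ids=genes,
        cell_ids=barcodes,
        values=values,
        stage=stage or _infer_stage(values),
    )


def write_expression(batch: ExpressionBatch, path, dialect="csv") -> None:
    """Write a batch as dense CSV/TSV or as an MTX directory."""
    path = Path(path)
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        df = pd.DataFrame(batch.values, index=batch.gene_ids, columns=batch.cell_ids)
        _atomic_write(path, df.to_csv(sep=sep))
    elif dialect == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(batch.values)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sparse)
        _atomic_write(path / "genes.tsv", "\n".join(batch.gene_ids) + "\n")
        _atomic_write(path / "barcodes.tsv", "\n".join(batch.cell_ids) + "\n")
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def write_labels(batches, path, cluster_labels=None) -> None:
    """TSV of cell_id, batch, cell_type (and cluster when provided)."""
    rows = []
    for b in batches:
        types = (
            b.cell_type_labels
            if b.cell_type_labels is not None
            else np.full(b.n_cells, "NA", dtype=object)
        )
        clusters = (
            cluster_labels[b.batch_id]
            if cluster_labels is not None
            else np.full(b.n_cells, -1)
        )
        for cid, t, cl in zip(b.cell_ids, types, clusters):
            rows.append((cid, b.batch_id, t, cl))
    df = pd.DataFrame(rows, columns=["cell_id", "batch", "cell_type", "cluster"])
    if cluster_labels is None:
        df = df.drop(columns="cluster")
    _atomic_write(Path(path), df.to_csv(sep="\t", index=False))


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "batch"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: labels TSV needs columns {sorted(required)}")
    return df


def write_embedding(embedding, path) -> None:
    """CSV of cell_id, batch, z1..zd from a CodeEmbedding."""
    rows = []
    for batch_id, Z in embedding.codes.items():
        for cid, z in zip(embedding.cell_ids[batch_id], Z):
            rows.append([cid, batch_id, *z])
    cols = ["cell_id", "batch"] + [f"z{i + 1}" for i in range(embedding.dim)]
    df = pd.DataFrame(rows, columns=cols)
    _atomic_write(Path(path), df.to_csv(index=False))


def read_embedding(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise FormatError(f"{path}: embedding CSV needs a cell_id column")
    return df


def write_similarity(sim: SimilarityMatrix, path) -> None:
    """Long-format CSV: batch_a, cluster_a, batch_b, cluster_b, score, aligned."""
    rows = []
    aligned = sim.values >= (sim.s_thr or np.inf)
    if sim.stage == "binary":
        aligned = sim.values == 1
    for i, (ba, ja) in enumerate(sim.clusters):
        for j, (bb, jb) in enumerate(sim.clusters):
            if ba == bb:
                continue
            rows.append((ba, ja, bb, jb, sim.values[i, j], bool(aligned[i, j])))
    df = pd.DataFrame(
        rows,
        columns=["batch_a", "cluster_a", "batch_b", "cluster_b", "score", "aligned"],
    )
    _atomic_write(Path(path), df.to_csv(index=False))


def write_report(report: EvalReport, path) -> None:
    _atomic_write(Path(path), json.dumps(report.to_dict(), indent=2) + "\n")


def _atomic_write(path: Path, text: str) -> None:
    """Write via a .partial file so interrupted runs never leave torn output."""
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".partial")
    tmp.write_text(text)
    os.replace(tmp, path)
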