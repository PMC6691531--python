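"""MMD-regularized autoencoder for cluster-aware batch correction.

The model is a plain fully connected autoencoder with leaky-ReLU hidden
layers and a leaky-rectifier output (the leak keeps gradient flowing
through the narrow bottleneck, where a hard rectifier can die and let the
MMD term collapse all codes to zero; a sigmoid output is available but
warps the code geometry because the pooled [0, 1] scaling puts every
gene's extremes exactly at the sigmoid's asymptotes).  Training is
mini-batch gradient descent on

    L = L1 + lambda_p * L2,

where L1 is the summed squared reconstruction error of the mini-batch and L2
adds the squared MMD between the bottleneck codes of every pair of clusters
aligned across batches by the binary similarity mask.  lambda_p follows a
sigmoid ramp over epochs so the network first learns a faithful
low-dimensional representation, then aligns matched clusters.

A mini-batch contains ``n_mb`` cells from every cluster of every batch
(B = n_mb * sum_i c_i rows), so each aligned pair always has both blocks
available.  The network and its gradients are implemented directly in numpy
(forward pass, analytic backprop through both loss terms, Adam updates);
gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    ClusterAssignment,
    ExpressionBatch,
    SimilarityMatrix,
    ValidationError,
)
from .mmd import BANDWIDTH_FACTORS, median_heuristic_bandwidths, mmd2_with_grad


@dataclass
class AEConfig:
    """Autoencoder architecture and training hyperparameters.

    ``hidden_sizes`` must have an odd length with the middle entry the
    bottleneck; the default [200, 20, 200] suits count data on ~2000 HVGs,
    while :func:`gaussian_preset` gives the [20, 2, 20] architecture whose
    2-unit code reconstructs a 2D biological plane directly.
    """

    hidden_sizes: Sequence[int] = (200, 20, 200)
    epochs: int = 2000
    learning_rate: float = 1e-3
    n_mb: int = 50
    kernel_bandwidths: Optional[Sequence[float]] = None  # None -> median heuristic
    bandwidth_factors: Sequence[float] = BANDWIDTH_FACTORS
    reconstruction_reduction: str = "sum"  # "sum" (as defined) or "mean"
    output_activation: str = "leaky"  # "leaky" rectifier or "sigmoid"
    seed: int = 0

    def validate(self) -> None:
        h = list(self.hidden_sizes)
        if len(h) % 2 == 0 or not h:
            raise ValidationError("hidden_sizes must have odd length (middle = code)")
        if any(s < 1 for s in h):
            raise ValidationError("hidden sizes must be positive")
        if self.epochs < 1 or self.n_mb < 1:
            raise ValidationError("epochs and n_mb must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.reconstruction_reduction not in ("sum", "mean"):
            raise ValidationError("reconstruction_reduction must be 'sum' or 'mean'")
        if self.output_activation not in ("leaky", "sigmoid"):
            raise ValidationError("output_activation must be 'leaky' or 'sigmoid'")

    @property
    def bottleneck_size(self) -> int:
        h = list(self.hidden_sizes)
        return h[len(h) // 2]


def gaussian_preset(**overrides) -> AEConfig:
    """The narrow 20-2-20 architecture for data from a 2D biological plane."""
    cfg = AEConfig(hidden_sizes=(20, 2, 20), **overrides)
    return cfg


@dataclass
class MiniBatch:
    """One training sample: n_mb cells from every cluster of every batch."""

    X: np.ndarray  # (B, n_genes)
    blocks: dict[tuple[str, int], slice]

    @property
    def B(self) -> int:
        return self.X.shape[0]


@dataclass
class CodeEmbedding:
    """Bottleneck codes of all cells — the batch-corrected output."""

    codes: dict[str, np.ndarray]  # batch_id -> (n_cells, d)
    cell_ids: dict[str, list[str]]

    @property
    def dim(self) -> int:
        return next(iter(self.codes.values())).shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(all codes, matching batch-label vector), batches concatenated."""
        mats, labels = [], []
        for b, Z in self.codes.items():
            mats.append(Z)
            labels.append(np.full(Z.shape[0], b, dtype=object))
        return np.vstack(mats), np.concatenate(labels)


def lambda_schedule(p: int | float, np_total: int) -> float:
    """Sigmoid ramp of the transfer-loss weight: 2/(1+exp(-10 p/np)) - 1."""
    if np_total < 1:
        raise ValidationError("total epochs must be >= 1")
    return 2.0 / (1.0 + math.exp(-10.0 * p / np_total)) - 1.0


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray, reduction="sum") -> float:
    """Summed (or per-cell mean) squared reconstruction error."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValidationError(f"shape mismatch {X.shape} vs {X_hat.shape}")
    total = float(np.sum((X - X_hat) ** 2))
    if reduction == "mean":
        return total / X.shape[0]
    return total


def total_loss(l1: float, l2: float, lambda_p: float) -> float:
    return l1 + lambda_p * l2


def sample_minibatch(
    batches: list[ExpressionBatch],
    assignment: ClusterAssignment,
    n_mb: int,
    rng: np.random.Generator,
) -> MiniBatch:
    """Draw n_mb cells from every cluster of every batch.

    Sampling is uniform without replacement when the cluster holds at least
    n_mb cells, with replacement otherwise.
    """
    rows = []
    blocks: dict[tuple[str, int], slice] = {}
    start = 0
    for batch in batches:
        labels = assignment.labels[batch.batch_id]
        if labels.shape[0] != batch.n_cells:
            raise ValidationError(
                f"assignment for {batch.batch_id} does not match cell count"
            )
        cells = batch.values.T  # cells x genes
        for j in range(1, assignment.n_clusters(batch.batch_id) + 1):
            idx = np.flatnonzero(labels == j)
            if idx.size == 0:
                raise ValidationError(
                    f"cluster {j} of batch {batch.batch_id} is empty"
                )
            chosen = rng.choice(idx, size=n_mb, replace=idx.size < n_mb)
            rows.append(cells[chosen])
            blocks[(batch.batch_id, j)] = slice(start, start + n_mb)
            start += n_mb
    return MiniBatch(X=np.vstack(rows), blocks=blocks)


def transfer_loss(
    code_blocks: dict[tuple[str, int], np.ndarray],
    mask: SimilarityMatrix,
    bandwidths=None,
) -> float:
    """Sum of MMD^2 over unordered aligned cluster pairs (Eq-7-style)."""
    if mask.stage != "binary":
        raise ValidationError("transfer_loss requires a binary similarity mask")
    total = 0.0
    for (a, b) in mask.aligned_pairs():
        if a not in code_blocks or b not in code_blocks:
            raise ValidationError(f"aligned pair {a}-{b} missing a code block")
        from .mmd import mmd2

        total += mmd2(code_blocks[a], code_blocks[b], bandwidths)
    return total


LEAK = 0.1  # leaky-ReLU slope on hidden layers


class _MLP:
    """Fully connected net: leaky ReLU on hidden layers; output layer is a
    leaky rectifier by default (suits nonnegative scaled data without the
    geometric warping a saturating sigmoid imposes near 0/1) or a sigmoid."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 output_activation: str = "leaky"):
        self.sizes = sizes
        self.output_activation = output_activation
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for l, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = l == len(sizes) - 2
            scale = (
                math.sqrt(1.0 / fan_in) if last else math.sqrt(2.0 / fan_in)
            )  # Xavier-ish for sigmoid output, He for ReLU
            self.W.append(rng.normal(scale=scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Return activations [A0=X, A1, ..., AL]."""
        acts = [X]
        A = X
        for l in range(self.n_layers):
            Z = A @ self.W[l] + self.b[l]
            if l == self.n_layers - 1 and self.output_activation == "sigmoid":
                A = 1.0 / (1.0 + np.exp(-Z))
            else:
                A = np.where(Z > 0, Z, LEAK * Z)
            acts.append(A)
        return acts


@dataclass
class TrainedModel:
    """Trained autoencoder: parameters, config, and per-epoch loss history."""

    net: _MLP
    config: AEConfig
    gene_ids: list[str]
    history: list[dict] = field(default_factory=list)

    @property
    def code_layer(self) -> int:
        """Index l such that acts[l + 1] is the bottleneck code."""
        return len(list(self.config.hidden_sizes)) // 2

    def encode(self, X: np.ndarray) -> np.ndarray:
        A = np.asarray(X, dtype=float)
        for l in range(self.code_layer + 1):
            Z = A @ self.net.W[l] + self.net.b[l]
            A = np.where(Z > 0, Z, LEAK * Z)
        return A

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(np.asarray(X, dtype=float))[-1]

    def save(self, path) -> None:
        payload = {
            "config": {
                "hidden_sizes": list(self.config.hidden_sizes),
                "epochs": self.config.epochs,
                "learning_rate": self.config.learning_rate,
                "n_mb": self.config.n_mb,
                "kernel_bandwidths": (
                    list(self.config.kernel_bandwidths)
                    if self.config.kernel_bandwidths is not None
                    else None
                ),
                "bandwidth_factors": list(self.config.bandwidth_factors),
                "reconstruction_reduction": self.config.reconstruction_reduction,
                "output_activation": self.config.output_activation,
                "seed": self.config.seed,
            },
            "gene_ids": self.gene_ids,
            "weights": [w.tolist() for w in self.net.W],
            "biases": [b.tolist() for b in self.net.b],
            "history": self.history,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        config = AEConfig(**payload["config"])
        sizes = [len(payload["weights"][0])] + [
            len(b) for b in payload["biases"]
        ]
        net = _MLP(sizes, np.random.default_rng(0),
                   output_activation=config.output_activation)
        net.W = [np.array(w, dtype=float) for w in payload["weights"]]
        net.b = [np.array(b, dtype=float) for b in payload["biases"]]
        return cls(
            net=net,
            config=config,
            gene_ids=payload["gene_ids"],
            history=payload["history"],
        )


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _iteration_grads(
    net: _MLP,
    mb: MiniBatch,
    mask: SimilarityMatrix,
    lambda_p: float,
    code_layer: int,
    config: AEConfig,
) -> tuple[list[np.ndarray], list[np.ndarray], float, float]:
    """Forward + backward over one mini-batch; returns (gW, gb, L1, L2)."""
    acts = net.forward(mb.X)
    X_hat = acts[-1]
    resid = X_hat - mb.X
    l1 = float(np.sum(resid**2))
    d_out = 2.0 * resid
    if config.reconstruction_reduction == "mean":
        l1 /= mb.B
        d_out = d_out / mb.B

    codes = acts[code_layer + 1]
    d_code = np.zeros_like(codes)
    l2 = 0.0
    pairs = mask.aligned_pairs()
    if pairs and lambda_p != 0.0:
        if config.kernel_bandwidths is not None:
            bw = np.asarray(config.kernel_bandwidths, dtype=float)
        else:
            bw = median_heuristic_bandwidths(
                codes, factors=config.bandwidth_factors
            )
        for (a, b) in pairs:
            Za = codes[mb.blocks[a]]
            Zb = codes[mb.blocks[b]]
            val, gA, gB = mmd2_with_grad(Za, Zb, bw)
            l2 += val
            d_code[mb.blocks[a]] += lambda_p * gA
            d_code[mb.blocks[b]] += lambda_p * gB
    elif pairs:
        # lambda 0: still report L2 for the history without backprop
        from .mmd import mmd2

        if config.kernel_bandwidths is not None:
            bw = np.asarray(config.kernel_bandwidths, dtype=float)
        else:
            bw = median_heuristic_bandwidths(codes, factors=config.bandwidth_factors)
        for (a, b) in pairs:
            l2 += mmd2(codes[mb.blocks[a]], codes[mb.blocks[b]], bw)

    # Manual backward sweep with the transfer gradient injected at the code.
    gW = [np.zeros_like(w) for w in net.W]
    gb = [np.zeros_like(b) for b in net.b]
    dA = d_out
    for l in range(net.n_layers - 1, -1, -1):
        A_out = acts[l + 1]
        if l == net.n_layers - 1 and net.output_activation == "sigmoid":
            dZ = dA * A_out * (1.0 - A_out)
        else:
            dZ = dA * np.where(A_out > 0, 1.0, LEAK)
        gW[l] = acts[l].T @ dZ
        gb[l] = dZ.sum(axis=0)
        if l > 0:
            dA = dZ @ net.W[l].T
            if l - 1 == code_layer:
                dA = dA + d_code
    return gW, gb, l1, l2


def train(
    batches: list[ExpressionBatch],
    assignment: ClusterAssignment,
    mask: SimilarityMatrix,
    config: AEConfig | None = None,
) -> tuple[TrainedModel, CodeEmbedding]:
    """Train the autoencoder and embed every cell through the encoder.

    Each epoch runs ceil(total cells / B) mini-batch iterations so all cells
    are covered in expectation; the transfer weight lambda_p is updated per
    epoch.  All randomness (init + sampling) flows from ``config.seed``.
    """
    config = config or AEConfig()
    config.validate()
    if mask.stage != "binary":
        raise ValidationError("train requires a binary similarity mask")
    for b in batches:
        if b.stage != "scaled":
            raise ValidationError("train expects scaled batches")
    gene_ids = batches[0].gene_ids
    if any(b.gene_ids != gene_ids for b in batches):
        raise ValidationError("batches must share one gene list")

    rng = np.random.default_rng(config.seed)
    n_genes = len(gene_ids)
    sizes = [n_genes] + list(config.hidden_sizes) + [n_genes]
    net = _MLP(sizes, rng, output_activation=config.output_activation)
    model = TrainedModel(net=net, config=config, gene_ids=list(gene_ids))
    code_layer = model.code_layer

    total_cells = sum(b.n_cells for b in batches)
    B = config.n_mb * assignment.total_clusters
    iters = max(1, math.ceil(total_cells / B))
    params = net.W + net.b
    opt = _Adam(params, config.learning_rate)

    for p in range(1, config.epochs + 1):
        lam = lambda_schedule(p, config.epochs)
        l1_sum = l2_sum = 0.0
        for _ in range(iters):
            mb = sample_minibatch(batches, assignment, config.n_mb, rng)
            gW, gb, l1, l2 = _iteration_grads(
                net, mb, mask, lam, code_layer, config
            )
            loss = total_loss(l1, l2, lam)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {p} (L1={l1}, L2={l2}, "
                    f"lambda={lam}); aborting"
                )
            opt.step(params, gW + gb)
            l1_sum += l1
            l2_sum += l2
        model.history.append(
            {
                "epoch": p,
                "L1": l1_sum / iters,
                "L2": l2_sum / iters,
                "lambda": lam,
                "L": total_loss(l1_sum / iters, l2_sum / iters, lam),
            }
        )

    embedding = embed_batches(model, batches)
    return model, embedding


def embed_batches(model: TrainedModel, batches: list[ExpressionBatch]) -> CodeEmbedding:
    codes = {}
    cell_ids = {}
    for b in batches:
        codes[b.batch_id] = embed(model, b)
        cell_ids[b.batch_id] = list(b.cell_ids)
    return CodeEmbedding(codes=codes, cell_ids=cell_ids)


def embed(model: TrainedModel, batch: ExpressionBatch) -> np.ndarray:
    """Deterministic encoder pass for one batch (cells x code-dim)."""
    if batch.gene_ids != model.gene_ids:
        raise ValidationError(
            "batch gene list does not match the genes the model was trained on"
        )
    return model.encode(batch.values.T)
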