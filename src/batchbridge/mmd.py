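"""Maximum mean discrepancy with a multi-bandwidth Gaussian kernel.

The biased (V-statistic) estimator is used throughout:

    MMD^2(A, B) = mean_ij k(a_i, a_j) + mean_ij k(b_i, b_j)
                  - 2 mean_ij k(a_i, b_j),

with k(x, y) = sum_s exp(-||x - y||^2 / (2 s^2)) over a bandwidth list.  The
V-statistic is nonnegative for any positive-definite kernel, which keeps the
transfer loss a proper penalty.  Bandwidths default to the median pairwise
distance of the pooled samples times {1, 2, 4, 8, 16} (median heuristic);
they are treated as constants when differentiating.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ValidationError

BANDWIDTH_FACTORS = (1.0, 2.0, 4.0, 8.0, 16.0)


def median_heuristic_bandwidths(
    *samples: np.ndarray, factors=BANDWIDTH_FACTORS
) -> np.ndarray:
    """Median pairwise distance of the pooled samples, times ``factors``."""
    pooled = np.vstack([np.atleast_2d(s) for s in samples])
    d2 = _sq_dists(pooled, pooled)
    iu = np.triu_indices(len(pooled), k=1)
    if iu[0].size == 0:
        med = 1.0
    else:
        med = float(np.median(np.sqrt(np.maximum(d2[iu], 0.0))))
    if med <= 0:
        med = 1.0
    return med * np.asarray(factors, dtype=float)


def _sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xx = np.einsum("ij,ij->i", X, X)
    yy = np.einsum("ij,ij->i", Y, Y)
    return xx[:, None] + yy[None, :] - 2.0 * (X @ Y.T)


def _kernel(X: np.ndarray, Y: np.ndarray, bandwidths: np.ndarray) -> np.ndarray:
    d2 = np.maximum(_sq_dists(X, Y), 0.0)
    K = np.zeros_like(d2)
    for s in bandwidths:
        K += np.exp(-d2 / (2.0 * s * s))
    return K


def _check(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] < 1 or B.shape[0] < 1:
        raise ValidationError("mmd2 needs at least one row per sample")
    if A.shape[1] != B.shape[1]:
        raise ValidationError(
            f"dimension mismatch: {A.shape[1]} vs {B.shape[1]} columns"
        )
    return A, B


def mmd2(A: np.ndarray, B: np.ndarray, bandwidths=None) -> float:
    """Biased squared MMD between two sample matrices (rows = observations)."""
    A, B = _check(A, B)
    if bandwidths is None:
        bandwidths = median_heuristic_bandwidths(A, B)
    bandwidths = np.asarray(bandwidths, dtype=float)
    val = (
        _kernel(A, A, bandwidths).mean()
        + _kernel(B, B, bandwidths).mean()
        - 2.0 * _kernel(A, B, bandwidths).mean()
    )
    # V-statistic is nonnegative up to rounding error.
    return float(max(val, 0.0))


def mmd2_with_grad(
    A: np.ndarray, B: np.ndarray, bandwidths=None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Squared MMD plus its gradients with respect to both sample matrices.

    For each bandwidth s, d k(x, y) / d x = -k(x, y) (x - y) / s^2; the
    bandwidths themselves (median heuristic) are treated as constants.
    """
    A, B = _check(A, B)
    if bandwidths is None:
        bandwidths = median_heuristic_bandwidths(A, B)
    bandwidths = np.asarray(bandwidths, dtype=float)
    n, m = A.shape[0], B.shape[0]

    d2_aa = np.maximum(_sq_dists(A, A), 0.0)
    d2_bb = np.maximum(_sq_dists(B, B), 0.0)
    d2_ab = np.maximum(_sq_dists(A, B), 0.0)

    val = 0.0
    gA = np.zeros_like(A)
    gB = np.zeros_like(B)
    for s in bandwidths:
        inv = 1.0 / (s * s)
        Kaa = np.exp(-d2_aa * (0.5 * inv))
        Kbb = np.exp(-d2_bb * (0.5 * inv))
        Kab = np.exp(-d2_ab * (0.5 * inv))
        val += Kaa.mean() + Kbb.mean() - 2.0 * Kab.mean()
        # d mean(Kaa) / dA_i = (2/n^2) sum_j Kaa_ij * (-(a_i - a_j)/s^2)
        gA += (-2.0 * inv / (n * n)) * (Kaa.sum(axis=1)[:, None] * A - Kaa @ A)
        gB += (-2.0 * inv / (m * m)) * (Kbb.sum(axis=1)[:, None] * B - Kbb @ B)
        # cross term enters with coefficient -2/(n m)
        gA += (2.0 * inv / (n * m)) * (Kab.sum(axis=1)[:, None] * A - Kab @ B)
        gB += (2.0 * inv / (n * m)) * (Kab.sum(axis=0)[:, None] * B - Kab.T @ A)
    return float(max(val, 0.0)), gA, gB
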