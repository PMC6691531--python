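import numpy as np
import pytest

from batchbridge import ClusterAssignment, ExpressionBatch


def make_cluster_batches(
    n_clusters=3,
    cells_per_cluster=40,
    n_genes=30,
    spread=0.5,
    separation=6.0,
    seed=0,
    duplicate=True,
):
    """Two batches with well-separated clusters in gene space.

    Batch2 is an exact copy of Batch1 when ``duplicate`` is True, so every
    cluster has a perfect counterpart across batches.  Values are shifted
    to be nonnegative and tagged stage='log' (the similarity network's
    expected input stage).
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=separation, size=(n_clusters, n_genes))
    rows = []
    labels = []
    for j, c in enumerate(centers, start=1):
        rows.append(c + rng.normal(scale=spread, size=(cells_per_cluster, n_genes)))
        labels += [j] * cells_per_cluster
    X = np.vstack(rows)
    X = X - X.min()
    labels = np.array(labels)

    def build(batch_id, values):
        return ExpressionBatch(
            batch_id=batch_id,
            gene_ids=[f"g{i}" for i in range(n_genes)],
            cell_ids=[f"{batch_id}_c{i}" for i in range(values.shape[0])],
            values=values.T,
            stage="log",
            cell_type_labels=np.array([f"T{l}" for l in labels], dtype=object),
        )

    b1 = build("Batch1", X)
    if duplicate:
        b2 = build("Batch2", X.copy())
        lab2 = labels.copy()
    else:
        X2 = np.vstack(
            [c + rng.normal(scale=spread, size=(cells_per_cluster, n_genes))
             for c in centers]
        )
        X2 = X2 - X2.min()
        b2 = build("Batch2", np.clip(X2, 0, None))
        lab2 = labels.copy()
    assignment = ClusterAssignment(labels={"Batch1": labels, "Batch2": lab2})
    return [b1, b2], assignment


@pytest.fixture
def three_cluster_pair():
    return make_cluster_batches()
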