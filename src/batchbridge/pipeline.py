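"""End-to-end workflow: simulate/load -> preprocess -> cluster -> similarity
-> train -> evaluate, with every stage's artifact persisted and a manifest
recording all seeds and parameters so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as bio
from .clustering import ClusterConfig, cluster_batches
from .datatypes import ExpressionBatch, ValidationError
from .metrics import EvalConfig, evaluate
from .model import AEConfig, CodeEmbedding, train
from .preprocess import PreprocessConfig, preprocess_pipeline
from .similarity import similarity_pipeline
from .simulate import (
    CountSimConfig,
    GaussianSimConfig,
    simulate_counts,
    simulate_gaussian,
)

logger = logging.getLogger("batchbridge")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; overridable from a YAML file.

    ``s_thr`` defaults to 0.90 (preserves batch-specific subpopulations);
    0.85 trades some of that purity for stronger mixing.  The documented
    working range is 0.85-0.90.
    """

    simulator: Optional[str] = "gaussian"  # "gaussian" | "counts" | None (load)
    input_paths: Optional[list[str]] = None
    remove: list[tuple[str, str]] = field(default_factory=list)
    sim_config: Optional[object] = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)
    s_thr: float = 0.90
    model: AEConfig = field(default_factory=AEConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.s_thr < 1.0:
            raise ValidationError("s_thr must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("simulator", "input_paths", "s_thr", "out_dir", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "remove" in raw:
            cfg.remove = [tuple(r) for r in raw["remove"]]
        for key, klass in (
            ("preprocess", PreprocessConfig),
            ("clustering", ClusterConfig),
            ("model", AEConfig),
            ("evaluation", EvalConfig),
        ):
            if key in raw:
                setattr(cfg, key, klass(**raw[key]))
        if "sim_config" in raw:
            sim_cls = (
                GaussianSimConfig if cfg.simulator == "gaussian" else CountSimConfig
            )
            cfg.sim_config = sim_cls(**raw["sim_config"])
        return cfg


def _spawn_seeds(master: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, derived from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class RunResult:
    embedding: CodeEmbedding
    report: object
    batches_scaled: list[ExpressionBatch]
    manifest: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the five workflow steps, persisting artifacts when out_dir is set."""
    config.validate()
    t0 = time.time()
    seeds = _spawn_seeds(config.seed, 4)
    manifest: dict = {
        "master_seed": config.seed,
        "seeds": {
            "simulate": seeds[0],
            "clustering": seeds[1],
            "training": seeds[2],
            "umap": seeds[3],
        },
        "s_thr": config.s_thr,
        "stages": {},
    }
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # 1. data
    if config.simulator == "gaussian":
        sim_cfg = config.sim_config or GaussianSimConfig()
        sim_cfg.seed = seeds[0]
        dataset = simulate_gaussian(sim_cfg)
    elif config.simulator == "counts":
        sim_cfg = config.sim_config or CountSimConfig()
        sim_cfg.seed = seeds[0]
        dataset = simulate_counts(sim_cfg)
    elif config.input_paths:
        batches = [bio.read_expression(p) for p in config.input_paths]

        class _Loaded:
            pass

        dataset = _Loaded()
        dataset.batches = batches
    else:
        raise ValidationError("need either a simulator or input_paths")
    for batch_id, type_label in config.remove:
        from .simulate import remove_cell_type

        dataset = remove_cell_type(dataset, batch_id, type_label)
    batches = dataset.batches
    manifest["stages"]["data"] = {
        "batches": {b.batch_id: b.n_cells for b in batches}
    }
    logger.info("data: %s", manifest["stages"]["data"])

    # 2. preprocess
    scaled, hvg, _ = preprocess_pipeline(batches, config.preprocess)
    manifest["stages"]["preprocess"] = {"n_hvg": len(hvg)}
    # log-stage HVG matrices for the correlation network (similarity is
    # computed before per-batch standardization, which would distort
    # cross-gene ranks in a composition-dependent way)
    from .preprocess import log_transform, to_tpm

    log_batches = []
    for b in batches:
        lb = to_tpm(b) if b.stage == "counts" else b
        log_batches.append(log_transform(lb).subset_genes(hvg))

    # 3. cluster each batch
    config.clustering.seed = seeds[1]
    assignment = cluster_batches(scaled, config.clustering)
    manifest["stages"]["clustering"] = {
        b: int(assignment.n_clusters(b)) for b in assignment.batch_ids
    }
    logger.info("clusters per batch: %s", manifest["stages"]["clustering"])

    # 4. similarity + mask
    raw, mask = similarity_pipeline(log_batches, assignment, s_thr=config.s_thr)
    manifest["stages"]["similarity"] = {
        "aligned_pairs": len(mask.aligned_pairs())
    }

    # 5. train + embed
    config.model.seed = seeds[2]
    model, embedding = train(scaled, assignment, mask, config.model)

    # 6. evaluate (only when ground-truth type labels exist)
    report = None
    if all(b.cell_type_labels is not None for b in batches):
        Z, batch_labels = embedding.stacked()
        type_labels = np.concatenate(
            [b.cell_type_labels for b in batches]
        )
        config.evaluation.umap_seed = seeds[3]
        report = evaluate(Z, batch_labels, type_labels, config.evaluation)

    manifest["elapsed_s"] = round(time.time() - t0, 2)

    if out:
        bio.write_labels(
            batches, out / "labels.tsv", cluster_labels=assignment.labels
        )
        bio.write_similarity(raw, out / "similarity_raw.csv")
        bio.write_similarity(mask, out / "similarity_mask.csv")
        bio.write_embedding(embedding, out / "embedding.csv")
        model.save(out / "model.json")
        if report is not None:
            bio.write_report(report, out / "report.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return RunResult(
        embedding=embedding,
        report=report,
        batches_scaled=scaled,
        manifest=manifest,
    )
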