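"""End-to-end run orchestration: encode, cluster, split, fit, validate.

A run is described by a configuration mapping (usually read from YAML)
and produces a run directory with a manifest (config + seed + package
version), split files, evaluation tables and optional analysis
reports; the manifest suffices to reproduce the run exactly.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version as pkg_version
from pathlib import Path

from .art2a import ART2aConfig, art2a_cluster, tune_vigilance
from .bcut import DescriptorTable, natural_descriptor_table
from .encoding import encode_dataset, read_dataset_csv
from .pls import PLSConfig
from .split import generate_splits
from .synthetic import BenchmarkSpec, generate_benchmark, sparse_beta
from .validation import (
    DEFAULT_COMPONENT_GRID,
    multi_split_evaluation,
    pc_scan,
    relative_importance,
    training_size_scan,
    y_scramble_test,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "dataset": None,            # path to CSV (id, sequence, potency)
    "descriptor_table": None,   # path to TSV; default = packaged natural table
    "synthetic": None,          # alternative to dataset: dict for BenchmarkSpec
    "test_size": None,          # default: one per multimember cluster
    "n_splits": 30,
    "target_clusters": None,    # tune vigilance toward this multimember count
    "vigilance": 0.9,
    "learning_rate": 0.1,
    "max_epochs": 20,
    "n_components": "all",
    "scale": True,
    "analyses": ["evaluate"],   # evaluate, pcscan, sizescan, scramble, importance
    "component_grid": list(DEFAULT_COMPONENT_GRID),
    "fractions": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    "seed": 0,
}


def load_inputs(config: dict):
    """Resolve the descriptor table and encoded dataset from a config."""
    if config.get("descriptor_table"):
        table = DescriptorTable.from_tsv(config["descriptor_table"])
    else:
        table = natural_descriptor_table()
    if config.get("dataset"):
        records = read_dataset_csv(config["dataset"])
        encoded = encode_dataset(records, table)
    elif config.get("synthetic"):
        synth = dict(config["synthetic"])
        synth.setdefault("seed", config.get("seed", 0))
        if "n_nonzero" in synth:
            synth["beta"] = sparse_beta(
                synth.get("L", 21), synth.pop("n_nonzero"), synth["seed"]
            )
        spec = BenchmarkSpec(**{k: tuple(v) if k == "alphabet" else v for k, v in synth.items()})
        encoded = generate_benchmark(spec, table)
    else:
        raise ValueError("config must provide either 'dataset' or 'synthetic'")
    return table, encoded


def run_workflow(config: dict, outdir) -> Path:
    """Execute the full modeling workflow; returns the run directory."""
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    table, encoded = load_inputs(cfg)
    logger.info("encoded %d siRNAs x %d descriptors", encoded.n_samples, encoded.X.shape[1])

    art_cfg = ART2aConfig(
        vigilance=float(cfg["vigilance"]),
        learning_rate=float(cfg["learning_rate"]),
        max_epochs=int(cfg["max_epochs"]),
        seed=seed,
    )
    if cfg.get("target_clusters"):
        tuned = tune_vigilance(encoded.X, int(cfg["target_clusters"]), art_cfg)
        clustering = tuned.clustering
        art_cfg = ART2aConfig(tuned.vigilance, art_cfg.learning_rate, art_cfg.max_epochs, seed)
    else:
        clustering = art2a_cluster(encoded.X, art_cfg)

    test_size = cfg["test_size"]
    if test_size is None:
        test_size = clustering.n_multimember
    test_size = int(test_size)

    splits = generate_splits(
        encoded, int(cfg["n_splits"]), test_size, clustering=clustering, seed=seed
    )
    for k, split in enumerate(splits):
        split.to_frame(encoded.ids).to_csv(outdir / f"split_{k:02d}.csv", index=False)

    pls_cfg = PLSConfig(n_components=cfg["n_components"], scale=bool(cfg["scale"]))
    analyses = list(cfg["analyses"])
    results_summary: dict = {
        "n_samples": encoded.n_samples,
        "n_descriptors": int(encoded.X.shape[1]),
        "n_clusters": clustering.n_clusters,
        "n_multimember_clusters": clustering.n_multimember,
        "vigilance": art_cfg.vigilance,
        "n_train": len(splits[0].train_idx),
        "n_test": len(splits[0].test_idx),
    }

    models = None
    if "evaluate" in analyses or "importance" in analyses:
        stats, models = multi_split_evaluation(encoded, splits, pls_cfg, return_models=True)
        stats.per_split.to_csv(outdir / "evaluation_per_split.csv", index=False)
        stats.aggregate("r").to_csv(outdir / "evaluation_aggregate_r.csv")
        results_summary["mean_train_r"] = stats.mean("r", "train")
        if test_size:
            results_summary["mean_test_r"] = stats.mean("r", "test")
    if "pcscan" in analyses:
        scan = pc_scan(encoded, splits[0], cfg["component_grid"], scale=bool(cfg["scale"]))
        scan.to_csv(outdir / "component_scan.csv", index=False)
    if "sizescan" in analyses:
        scan = training_size_scan(
            encoded, cfg["fractions"], art_cfg, scale=bool(cfg["scale"]), seed=seed
        )
        scan.to_csv(outdir / "training_size_scan.csv", index=False)
    if "scramble" in analyses:
        report = y_scramble_test(
            encoded, clustering, int(cfg["n_splits"]), test_size, pls_cfg, seed=seed
        )
        report.scrambled.per_split.to_csv(outdir / "scramble_per_split.csv", index=False)
        results_summary["scramble_reduction_pct_test"] = report.reduction_pct_test
        results_summary["scramble_reduction_pct_train"] = report.reduction_pct_train
    if "importance" in analyses:
        imp = relative_importance(models, encoded.sequence_length)
        imp.per_column.rename("importance").to_csv(outdir / "importance_per_column.csv")
        imp.per_position.rename("importance").to_csv(outdir / "importance_per_position.csv")
        imp.per_descriptor.rename("importance").to_csv(outdir / "importance_per_descriptor.csv")

    manifest = {
        "package": "sibcut",
        "version": pkg_version("sibcut"),
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "results": results_summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
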