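"""End-to-end orchestration: read → preprocess → train → assign → report.

A run is fully determined by a :class:`RunConfig` (serializable to a
single YAML file) and its seed.  Every stage logs its row counts and the
run writes a ``manifest.json`` with the seed, a config hash and the
per-stage counts, so identical (config, seed) pairs reproduce identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import consistency, preprocess, simulate, som, viz
from .io_formats import (
    ExpressionDataset,
    GeneCatalog,
    read_expression_table,
    read_gene_catalog,
    write_expression_table,
)
from .preprocess import PreprocessConfig, write_filter_reports
from .som import TrainingConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    dataset_paths: list[str] = field(default_factory=list)
    dataset_dialect: str = "tsv"
    catalog_path: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    outlier_multiplier: float = 1.5
    consistent_threshold: float = 3.0
    opposite_threshold: float | None = None  # default: half the grid diameter
    out_dir: str = "somcoex_run"
    seed: int = 0
    log_level: str = "INFO"
    render: bool = True

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        payload["preprocess"] = PreprocessConfig(**payload.get("preprocess", {}))
        payload["training"] = TrainingConfig(**payload.get("training", {}))
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    datasets: list[ExpressionDataset] | None = None,
    catalog: GeneCatalog | None = None,
) -> Path:
    """Execute the full analysis; returns the artifact directory.

    Datasets and catalog may be passed in memory (e.g. from the synthetic
    generator); otherwise they are read from the configured paths.  Any
    stage failure aborts with a diagnostic naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        if datasets is None:
            datasets = [
                read_expression_table(p, dialect=config.dataset_dialect)
                for p in config.dataset_paths
            ]
        if catalog is None and config.catalog_path:
            catalog = read_gene_catalog(config.catalog_path)
        if not datasets:
            raise ValueError("no input datasets")

        stage = "preprocess"
        processed, reports, counts = [], [], []
        for ds in datasets:
            clean, report, unmatched = preprocess.preprocess_dataset(
                ds, catalog, config.preprocess
            )
            logger.info(
                "%s: %d in, %d unmatched, %d excluded, %d retained",
                ds.database_name, ds.n_genes, len(unmatched),
                report.excluded, report.retained,
            )
            processed.append(clean)
            reports.append(report)
            counts.append(
                {
                    "database": ds.database_name,
                    "genes_in": ds.n_genes,
                    "unmatched": len(unmatched),
                    "excluded": report.excluded,
                    "retained": report.retained,
                }
            )
        write_filter_reports(reports, out_dir / "filter_report.tsv")

        stage = "train"
        models = []
        for i, ds in enumerate(processed):
            cfg = dataclasses.replace(config.training, rng_seed=config.seed + i)
            model = som.train(ds, cfg)
            som.save_model(
                model,
                out_dir / f"model_{ds.database_name}.json",
                out_dir / f"model_{ds.database_name}_weights.tsv",
            )
            models.append(model)

        stage = "assign"
        tables = [
            consistency.assign_bmus(m, ds) for m, ds in zip(models, processed)
        ]

        stage = "report"
        if len(tables) < 4:
            raise ValueError(
                "outlier analysis needs at least 4 databases "
                f"(got {len(tables)}); quartile fences are meaningless below that"
            )
        grid = config.training.grid
        report = consistency.outlier_report(tables, grid, config.outlier_multiplier)
        consistency.write_outlier_report(report, out_dir / "outlier_pairs.tsv")
        consistency.write_outlier_summary(report, out_dir / "outlier_summary.tsv")
        close = consistency.consistent_pairs(tables, grid, config.consistent_threshold)
        far_threshold = (
            config.opposite_threshold
            if config.opposite_threshold is not None
            else grid.diameter() / 2
        )
        far = consistency.opposite_pairs(tables, grid, far_threshold)
        consistency.write_pair_list(close, tables, grid, out_dir / "consistent_pairs.tsv")
        consistency.write_pair_list(far, tables, grid, out_dir / "opposite_pairs.tsv")
        for ds in processed:
            write_expression_table(
                ds, out_dir / f"preprocessed_{ds.database_name}.tsv"
            )

        stage = "render"
        if config.render:
            for model, ds, table in zip(models, processed, tables):
                viz.render_component_planes(
                    model,
                    ds.sample_times,
                    ds.phase_labels,
                    out_dir / f"planes_{ds.database_name}",
                )
                viz.render_gene_map(
                    table, grid, out_path=out_dir / f"gene_map_{ds.database_name}.png"
                )

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "databases": [ds.database_name for ds in datasets],
            "stage_counts": counts,
            "models": [f"model_{ds.database_name}.json" for ds in processed],
            "total_pairs": report.total_pairs,
            "per_database_outlier_counts": report.per_database_outlier_counts,
            "consistent_pairs": len(close),
            "opposite_pairs": len(far),
        }
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out_dir
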