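"""End-to-end pipeline: simulate -> preprocess -> DE -> host correlation ->
clustering -> gene overlap, with per-stage TSV outputs and a JSON summary."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import cluster_enrichment, reorient_merge, spearman_distance, ward_cluster
from .diffexpr import DEConfig, build_de_table, evaluate_de_calls
from .hostcorr import anticorrelation_screen, correlation_screen, host_exon_expression
from .overlap import gene_de, overlap_lists
from .preprocess import call_expressed, preprocess_matrix
from .simulate import (GeneSimConfig, SimConfig, simulate_dataset,
                       simulate_gene_dataset, write_dataset)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    de: DEConfig = field(default_factory=DEConfig)
    gene_sim: GeneSimConfig = field(default_factory=GeneSimConfig)
    k_clusters: int = 3
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.de.validate()
        self.gene_sim.validate()
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls(
            sim=SimConfig(**raw.get("sim", {})),
            de=DEConfig(**raw.get("de", {})),
            gene_sim=GeneSimConfig(**raw.get("gene_sim", {})),
            k_clusters=raw.get("k_clusters", 3),
            alpha=raw.get("alpha", 0.05),
            seed=raw.get("seed", 0),
        )
        # tuples arrive as lists from YAML
        if isinstance(cfg.sim.de_log2fold_range, list):
            cfg.sim.de_log2fold_range = tuple(cfg.sim.de_log2fold_range)
        if isinstance(cfg.sim.region_length_range, list):
            cfg.sim.region_length_range = tuple(cfg.sim.region_length_range)
        if isinstance(cfg.gene_sim.log2fold_range, list):
            cfg.gene_sim.log2fold_range = tuple(cfg.gene_sim.log2fold_range)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on a seeded simulation and write a report directory.

    Returns the summary dictionary (also written as ``summary.json``).  On a
    stage failure the partial outputs are retained next to a ``FAILED``
    marker naming the stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        sim_cfg = config.sim
        if config.seed is not None:
            from dataclasses import replace
            sim_cfg = replace(sim_cfg, seed=config.seed)
        dataset = simulate_dataset(sim_cfg)
        write_dataset(dataset, out / "dataset")

        stage = "preprocess"
        smoothed, tucrs = preprocess_matrix(dataset.intensities, dataset.probes)
        tucrs.values.to_csv(out / "tucr_matrix.tsv", sep="\t",
                            index_label="transcript")
        expressed = call_expressed(tucrs)
        expressed.expressed.to_csv(out / "expressed_flags.tsv", sep="\t",
                                   index_label="transcript")

        stage = "diffexpr"
        de_table = build_de_table(expressed, dataset.regions, config.de)
        de_table.to_csv(out / "de_table.tsv", sep="\t", index=False)
        de_metrics = evaluate_de_calls(de_table, dataset.truth)

        stage = "hostcorr"
        host_expr = host_exon_expression(smoothed, dataset.probe_gene_map)
        host_expr.to_csv(out / "host_expression.tsv", sep="\t", index_label="gene")
        corr_results, corr_summary = correlation_screen(
            tucrs, host_expr, dataset.regions, alpha=config.alpha)
        corr_results.to_csv(out / "hostcorr.tsv", sep="\t", index=False)
        corr_summary.to_csv(out / "hostcorr_summary.tsv", sep="\t", index=False)
        anti = anticorrelation_screen(corr_results)
        anti.to_csv(out / "anticorrelated.tsv", sep="\t", index=False)

        stage = "cluster"
        intragenic = [r for r in dataset.regions if r.is_intragenic]
        reoriented = reorient_merge(tucrs.values, intragenic)
        distance = spearman_distance(reoriented)
        result = ward_cluster(distance, k=config.k_clusters)
        result.labels.to_csv(out / "cluster_labels.tsv", sep="\t",
                             index_label="region")
        pd.DataFrame(result.linkage,
                     columns=["left", "right", "height", "size"]).to_csv(
            out / "linkage.tsv", sep="\t", index=False)
        pd.Series(result.leaf_order, name="region").to_csv(
            out / "dendrogram_order.tsv", sep="\t", index=False)
        annotation_sets = {
            cls: {r.id for r in intragenic if r.region_class == cls}
            for cls in sorted({r.region_class for r in intragenic})
        }
        enrichment = cluster_enrichment(result.labels, annotation_sets)
        enrichment.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)

        stage = "overlap"
        from dataclasses import replace as _replace
        gene_cfg = _replace(config.gene_sim, seed=config.seed)
        kd, atra, _gene_truth = simulate_gene_dataset(gene_cfg)
        kd_calls = gene_de(kd)
        atra_calls = gene_de(atra)
        ov = overlap_lists(kd_calls, atra_calls)
        pd.DataFrame({
            "gene": ov.up_overlap + ov.down_overlap,
            "direction": ["up"] * ov.n_up_overlap + ["down"] * ov.n_down_overlap,
        }).to_csv(out / "overlap_genes.tsv", sep="\t", index=False)

        summary = {
            "version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "n_regions": len(dataset.regions),
            "n_probes": int(len(dataset.probes)),
            "n_transcripts": int(len(tucrs.values)),
            "n_expressed": int(len(expressed.values)),
            "n_de_called": int(len(de_table)),
            "de_recall": de_metrics["recall"],
            "de_fdp": de_metrics["fdp"],
            "hostcorr_summary": corr_summary.to_dict(orient="records"),
            "n_anticorrelated": int(len(anti)),
            "cluster_sizes": {int(c): int((result.labels == c).sum())
                              for c in sorted(result.labels.unique())},
            "overlap": {
                "kd_up": ov.n_a_up, "kd_down": ov.n_a_down,
                "atra_up": ov.n_b_up, "atra_down": ov.n_b_down,
                "up_overlap": ov.n_up_overlap, "down_overlap": ov.n_down_overlap,
            },
            "config": _jsonable(asdict(config)),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
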