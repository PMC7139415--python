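"""End-to-end pipeline: QC -> index matrix -> dependency clustering ->
subgroup condition ranking -> mutation-condition association, with every
intermediate written as TSV."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .dependency import hierarchical_cluster, label_clusters
from .design import enumerate_conditions
from .filters import parse_filter
from .ranking import mutation_condition_screen, rank_conditions
from .screen import DEFAULT_MIN_RATIO, DEFAULT_MIN_SIGNAL, build_index_matrix, qc_filter

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and subgroup definitions for a pipeline run."""

    readouts: str = ""
    annotations: str = ""
    min_signal: float = DEFAULT_MIN_SIGNAL
    min_ratio: float = DEFAULT_MIN_RATIO
    k_clusters: int = 4
    alpha: float = 0.05
    seed: int = 0
    subgroups: dict = field(default_factory=dict)  # name -> filter expression
    genes: list = field(default_factory=list)
    association_restrict: str = ""  # filter expression, empty = all samples

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.min_signal < 0 or self.min_ratio < 0:
            raise ValueError("QC thresholds must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the screen-side pipeline and write all outputs under ``outdir``.

    Returns a small report dict (also written as ``run_log.json``).  Any
    stage failure raises :class:`PipelineError` naming the stage; outputs of
    completed stages are preserved.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(vars(config))
    extra = f"config={chash}"
    report: dict = {"version": __version__, "config_hash": chash, "config": vars(config).copy()}

    catalog = enumerate_conditions()
    io.write_catalog(catalog, outdir / "catalog.tsv", extra=extra)

    try:
        readouts = io.read_readouts(config.readouts)
        annotations = io.read_annotations(config.annotations)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("read_inputs", str(exc)) from exc

    try:
        qc = qc_filter(readouts, config.min_signal, config.min_ratio)
        io.write_tsv(qc, outdir / "qc_report.tsv", extra=extra)
        report["qc_pass_fraction"] = float(qc["qc_pass"].mean())
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("qc", str(exc)) from exc

    try:
        if not qc["qc_pass"].any():
            raise ValueError("no well passed QC; check thresholds and readouts")
        gim = build_index_matrix(readouts, catalog, config.min_signal, config.min_ratio)
        io.write_index_matrix(gim, outdir / "growth", extra=extra)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("index", str(exc)) from exc

    try:
        assignment = hierarchical_cluster(gim, k=config.k_clusters)
        assignment = label_clusters(assignment, gim.index, catalog, alpha=config.alpha)
        clusters = assignment.clusters.to_frame()
        clusters["ef_label"] = assignment.sample_ef_label
        clusters["dependency_delta"] = assignment.deltas
        clusters.index.name = "sample_id"
        io.write_tsv(clusters.reset_index(), outdir / "clusters.tsv", extra=extra)
        io.write_tsv(assignment.merge_tree(), outdir / "merge_tree.tsv", extra=extra)
        report["cluster_sizes"] = assignment.clusters.value_counts().to_dict()
        report["ef_labels"] = assignment.ef_labels
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cluster", str(exc)) from exc

    try:
        for name, expr in config.subgroups.items():
            mask = parse_filter(expr, annotations)
            samples = annotations.index[mask].intersection(gim.index.index)
            if len(samples) == 0:
                logger.warning("subgroup %s is empty; skipped", name)
                continue
            ranking = rank_conditions(gim, samples)
            io.write_tsv(ranking.reset_index(), outdir / f"ranking_{name}.tsv", extra=extra)
            report.setdefault("top_condition", {})[name] = ranking.index[0]
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("rank", str(exc)) from exc

    try:
        if config.genes:
            restrict = None
            if config.association_restrict:
                restrict = annotations.index[parse_filter(config.association_restrict, annotations)]
            assoc = mutation_condition_screen(gim, annotations, list(config.genes), restrict)
            io.write_tsv(assoc, outdir / "associations.tsv", extra=extra)
            if not assoc.empty:
                best = assoc.loc[assoc["p"].idxmin()]
                report["best_association"] = {
                    "gene": best["gene"],
                    "condition_id": best["condition_id"],
                    "p": float(best["p"]),
                }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("associate", str(exc)) from exc

    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
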