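"""End-to-end pipeline orchestration with a declarative configuration.

A :class:`PipelineConfig` (usually loaded from YAML) drives the full
analysis: load or simulate an expression matrix, compute
Jensen-Shannon progression scores, expand metafeatures, assemble the
analysis matrix with marker rows, cluster, score cluster quality,
estimate permutation FDR, and write per-marker reports.  Every run
writes a manifest echoing the configuration plus the derived facts
(q used, cluster counts) so any artifact can be reproduced from the
manifest alone; outputs carry no timestamps and are byte-identical for
a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    read_annotation,
    read_expression,
    write_clusters,
    write_expression,
    write_graph_edgelist,
)
from .evaluation import homogeneity, permutation_fdr, separation
from .graph_clustering import annotated_forest, cluster
from .marker_analysis import find_marker_clusters, rank_members, robust_markers
from .metafeatures import OPERATORS, assemble_analysis_matrix, generate_metafeatures
from .progression import jsd_scores
from .synthetic import null_marker, planted_expression, planted_marker

logger = logging.getLogger(__name__)

REPORT_FLOAT = "%.6f"


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on."""

    out_dir: str
    seed: int
    expression: str | None = None       # path; None -> simulate
    annotation: str | None = None       # path to sample annotations
    simulate: dict = field(default_factory=dict)  # planted_expression kwargs
    marker_blocks: list[int] = field(default_factory=lambda: [0])
    marker_rho: float = 0.9
    ops: list[str] = field(default_factory=list)  # metafeature operators
    block_size: int = 10_000
    control_samples: list[str] = field(default_factory=list)
    severe_samples: list[str] = field(default_factory=list)
    markers: list[str] = field(default_factory=list)
    min_size: int = 3
    q: int | None = None
    c2_policy: str = "pmax"
    fdr_thresholds: list[float] = field(default_factory=lambda: [0.5, 0.6, 0.7, 0.8, 0.9])
    n_perm: int = 0                      # 0 disables the FDR stage
    export_graph: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.expression is not None and not Path(self.expression).exists():
            raise FileNotFoundError(self.expression)
        if self.annotation is not None and not Path(self.annotation).exists():
            raise FileNotFoundError(self.annotation)
        unknown_ops = set(self.ops) - set(OPERATORS)
        if unknown_ops:
            raise ValueError(f"unknown operators: {sorted(unknown_ops)}")


def _write_marker_table(markers: pd.DataFrame, path: Path) -> None:
    markers.sort_index().to_csv(path, sep="\t", float_format=REPORT_FLOAT,
                                index_label="sample_id")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns the manifest dict.

    On any stage failure a ``FAILED`` marker file naming the stage is
    left in the output directory and the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "setup"
    manifest: dict = {
        "tool": "mstknn",
        "version": __version__,
        "config": dataclasses.asdict(config),
    }
    try:
        # --- input -------------------------------------------------------
        stage = "input"
        marker_table = pd.DataFrame()
        if config.expression is not None:
            X = read_expression(config.expression)
        else:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            ds = planted_expression(**sim)
            X = ds.X
            for k in config.marker_blocks:
                planted_marker(ds, k, rho_target=config.marker_rho,
                               seed=config.seed + 1 + k)
            null_marker(ds, seed=config.seed + 101)
            marker_table = pd.DataFrame(ds.markers, index=X.columns)
            write_expression(X, out / "expression.tsv")
            manifest["simulated"] = ds.params

        if config.annotation is not None:
            ann = read_annotation(config.annotation)
            cols = [c for c in ("mmse", "nft", "braak") if c in ann.columns]
            marker_table = ann.loc[[s for s in X.columns if s in ann.index], cols]

        # --- progression scores -----------------------------------------
        if config.control_samples and config.severe_samples:
            stage = "jsd"
            jsd = jsd_scores(X, config.control_samples, config.severe_samples)
            marker_table = pd.concat([marker_table, jsd], axis=1)
        if not marker_table.empty:
            _write_marker_table(marker_table, out / "markers.tsv")
        if config.markers:
            missing = [m for m in config.markers if m not in marker_table.columns]
            if missing:
                raise ValueError(f"requested markers not available: {missing}")
            marker_table = marker_table[config.markers]

        # --- metafeatures + assembly ------------------------------------
        stage = "metafeatures"
        meta = (
            generate_metafeatures(X, config.ops, config.block_size)
            if config.ops else None
        )
        analysis = assemble_analysis_matrix(
            X, meta, marker_table if not marker_table.empty else None
        )
        manifest["n_features"] = int(analysis.shape[0])
        manifest["n_samples"] = int(analysis.shape[1])

        # --- clustering ---------------------------------------------------
        stage = "cluster"
        result = cluster(
            analysis, min_size=config.min_size, q=config.q,
            c2_policy=config.c2_policy,
        )
        write_clusters(result, out / "clusters.tsv")
        manifest["n_clusters"] = result.n_clusters
        manifest["split_log"] = [list(entry) for entry in result.split_log]
        if config.export_graph:
            forest, q_used = annotated_forest(analysis, q=config.q)
            write_graph_edgelist(forest, out / "forest.tsv")
            manifest["q_used"] = q_used

        # --- evaluation ---------------------------------------------------
        stage = "evaluate"
        quality = {"h_avg": homogeneity(analysis, result)}
        if result.n_clusters >= 2:
            quality["s_avg"] = separation(analysis, result)
        quality["n_clusters"] = result.n_clusters
        (out / "quality.json").write_text(json.dumps(quality, indent=2, sort_keys=True) + "\n")
        manifest["quality"] = quality

        # --- FDR ----------------------------------------------------------
        if config.n_perm > 0 and not marker_table.empty:
            stage = "fdr"
            pool = meta if meta is not None else X
            for name in marker_table.columns:
                table = permutation_fdr(
                    pool, marker_table[name].to_numpy(),
                    thresholds=config.fdr_thresholds,
                    n_perm=config.n_perm, seed=config.seed,
                )
                table.to_csv(out / f"fdr_{name}.tsv", sep="\t", index=False,
                             float_format=REPORT_FLOAT)

        # --- marker reports ----------------------------------------------
        if not marker_table.empty:
            stage = "report"
            clusters_by_marker = find_marker_clusters(
                result, list(marker_table.columns)
            )
            reports = []
            for name, members in clusters_by_marker.items():
                report = rank_members(
                    members, analysis, marker_table[name].to_numpy(), marker_id=name
                )
                reports.append(report)
                report.to_frame().to_csv(
                    out / f"report_{name}.tsv", sep="\t", index=False,
                    float_format=REPORT_FLOAT,
                )
            if len(reports) >= 2:
                robust = robust_markers(reports)
                with open(out / "robust_markers.tsv", "w") as fh:
                    fh.write("probe_id\tmarkers\n")
                    for probe in sorted(robust):
                        fh.write(f"{probe}\t{','.join(sorted(robust[probe]))}\n")
                manifest["n_robust_probes"] = len(robust)

        stage = "manifest"
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
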