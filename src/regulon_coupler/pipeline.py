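"""End-to-end orchestration: simulate -> build-panel -> screen -> regulators -> ratio.

A :class:`PipelineConfig` (optionally loaded from a YAML file) carries every
stage's parameters; :func:`run_all` executes the stages in dependency order,
persists each intermediate artifact, and writes one machine-readable JSON
report with every count, statistic and decision flag of the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import (
    ValidationError,
    read_annotation,
    read_binding_manifest,
    read_expression_matrix,
    read_gene_list,
    read_ortholog_map,
)
from .panel import PanelConfig, TargetPanel, average_replicates, build_panel, top_k_genes
from .regulators import RegulatorSet, compare_regulators, ratio_score, ratio_target_correlation
from .screen import run_screen
from .simulate import COREPRESSOR_GENES, TF_GENE, SyntheticConfig, write_fixture

logger = logging.getLogger("regulon_coupler")

__all__ = ["PipelineConfig", "run_all", "run_panel_stage", "run_screen_stage"]


@dataclass
class PipelineConfig:
    """Single source of truth for a full pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 0
    tf_gene: str = TF_GENE
    fdr_level: float = 0.01
    panel: PanelConfig = field(default_factory=PanelConfig)
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    receptors: tuple[str, ...] = (TF_GENE,)
    corepressors: tuple[str, ...] = COREPRESSOR_GENES
    ratio_targets: tuple[str, ...] = ()
    denominator: str = "tested"

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "panel" in kwargs:
            kwargs["panel"] = PanelConfig(**kwargs["panel"])
        if "simulate" in kwargs:
            kwargs["simulate"] = SyntheticConfig.from_dict(kwargs["simulate"])
        for key in ("receptors", "corepressors", "ratio_targets"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulate"] = self.simulate.to_dict()
        return d


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_panel_stage(
    manifest_path: str,
    orthologs_path: str,
    expression_path: str,
    canonical_path: str,
    cfg: PanelConfig,
) -> TargetPanel:
    """Load panel inputs from files and build the consensus target panel."""
    tables = read_binding_manifest(manifest_path)
    averaged = average_replicates(tables)
    lists = [top_k_genes(t, cfg.top_k) for t in averaged]
    species = [t.species for t in averaged]
    orthologs = read_ortholog_map(orthologs_path)
    expr = read_expression_matrix(expression_path)
    canonical = read_gene_list(canonical_path, label="canonical")
    return build_panel(lists, species, orthologs, expr, canonical, cfg)


def run_screen_stage(
    expression_path: str,
    annotation_path: str,
    tf_gene: str,
    panel_symbols,
    fdr_level: float,
    denominator: str = "tested",
):
    expr = read_expression_matrix(expression_path)
    ann = read_annotation(annotation_path)
    return run_screen(expr, ann, tf_gene, panel_symbols, fdr_level, denominator)


def run_all(cfg: PipelineConfig) -> dict:
    """Run the full synthetic analysis; returns (and writes) the run report."""
    t0 = time.time()
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {"config": cfg.to_dict(), "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        report["stages"][name] = {"started_s": round(time.time() - t0, 3)}
        return report["stages"][name]

    # 1. simulate
    st = stage("simulate")
    sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    paths = write_fixture(sim_cfg, cfg.outdir)
    st["outputs"] = {k: _file_hash(v) for k, v in paths.items()}

    # 2. panel
    st = stage("panel")
    panel = run_panel_stage(
        paths["manifest"], paths["orthologs"], paths["expression"],
        paths["canonical"], cfg.panel,
    )
    panel_path = os.path.join(cfg.outdir, "panel.tsv")
    panel.final_frame().to_csv(panel_path, sep="\t")
    panel.provenance.to_csv(os.path.join(cfg.outdir, "panel_provenance.tsv"), sep="\t")
    st["counts"] = panel.counts
    st["outputs"] = {"panel": _file_hash(panel_path)}

    # 3. screen
    st = stage("screen")
    result = run_screen_stage(
        paths["expression"], paths["annotation"], cfg.tf_gene,
        list(panel), cfg.fdr_level, cfg.denominator,
    )
    screen_path = os.path.join(cfg.outdir, "screen.tsv")
    result.records.to_csv(screen_path, sep="\t", index=False)
    st["summary"] = result.summary()
    st["outputs"] = {"screen": _file_hash(screen_path)}

    # 4. regulators
    st = stage("regulators")
    expr = read_expression_matrix(paths["expression"])
    ann = read_annotation(paths["annotation"])
    regs = RegulatorSet(receptors=cfg.receptors, corepressors=cfg.corepressors)
    reg_table = compare_regulators(expr, ann, regs)
    reg_path = os.path.join(cfg.outdir, "regulators.tsv")
    reg_table.to_csv(reg_path, sep="\t", index=False)
    st["rows"] = json.loads(reg_table.to_json(orient="records"))
    st["outputs"] = {"regulators": _file_hash(reg_path)}

    # 5. ratio
    st = stage("ratio")
    targets = cfg.ratio_targets or tuple(list(panel)[:2])
    rows = []
    for corepressor in cfg.corepressors:
        profile = ratio_score(expr, cfg.tf_gene, corepressor)
        for target in targets:
            per = ratio_target_correlation(profile, expr, target, ann)
            for cohort, row in per.iterrows():
                rows.append(
                    dict(receptor=cfg.tf_gene, corepressor=corepressor,
                         target=target, cohort=cohort,
                         r=row["r"], p=row["p"], n_used=int(row["n_used"]))
                )
    ratio_table = pd.DataFrame(rows)
    ratio_path = os.path.join(cfg.outdir, "ratio.tsv")
    ratio_table.to_csv(ratio_path, sep="\t", index=False)
    st["rows"] = json.loads(ratio_table.to_json(orient="records"))
    st["outputs"] = {"ratio": _file_hash(ratio_path)}

    report["wall_time_s"] = round(time.time() - t0, 3)
    report_path = os.path.join(cfg.outdir, "report.json")
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
    logger.info("report written to %s", report_path)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
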