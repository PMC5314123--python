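"""End-to-end orchestration: simulate -> call -> genes -> intersect -> report.

A run is specified by a :class:`RunConfig` — either a simulation config or a
directory of previously written study tables — and produces per-stage TSVs
plus a deterministic JSON report (identical config + seed => byte-identical
report).
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io
from .config import StudyConfig
from .cross_species import build_funnel, funnel_report
from .errors import PipelineError
from .gene_calls import classify_genes, map_probes_to_genes, summarize_dataset
from .probe_stats import call_dataset
from .simulate import generate_study, evaluate_recovery, SyntheticTruth

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    simulation: StudyConfig | None = None
    input_dir: str | None = None
    out_dir: str
    fdr_threshold: float = Field(default=0.2, gt=0, le=1)
    test: Literal["welch", "wilcoxon"] = "welch"
    core_ids: list[str] | None = None
    extension_ids: list[str] | None = None
    seed: int | None = None  # overrides simulation.seed when set

    @model_validator(mode="after")
    def _check_source(self) -> "RunConfig":
        if self.simulation is None and self.input_dir is None:
            raise ValueError("simulation/input_dir: provide one of the two")
        return self


def _package_version() -> str:
    try:
        return version("crossmeth")
    except PackageNotFoundError:  # pragma: no cover - editable quirk
        return "unknown"


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the (already written) report dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "crossmeth_version": _package_version(),
        "config": config.model_dump(mode="json"),
        "config_hash": config_hash(config),
        "fdr_threshold": config.fdr_threshold,
        "test": config.test,
    }

    # ------------------------------------------------ simulate or load ----
    truth: SyntheticTruth | None = None
    orthologs = None
    if config.simulation is not None:
        sim_cfg = config.simulation
        if config.seed is not None:
            sim_cfg = sim_cfg.model_copy(update={"seed": config.seed})
        report["seed"] = sim_cfg.seed
        study = _stage("simulate")(generate_study)(sim_cfg)
        _stage("simulate")(io.write_study)(study, out_dir / "study")
        datasets = {
            ds_id: (study.annotation[ds_id], data.bound, data.input, data.groups)
            for ds_id, data in study.datasets.items()
        }
        truth = study.truth
        orthologs = study.orthologs
        core = config.core_ids or sim_cfg.core_ids
        extension = (config.extension_ids if config.extension_ids is not None
                     else sim_cfg.extension_ids)
    else:
        report["seed"] = config.seed
        in_dir = Path(config.input_dir)
        design = _stage("load")(io.read_design)(in_dir / "design.tsv")
        if (in_dir / "orthologs.tsv").exists():
            orthologs = io.read_orthologs(in_dir / "orthologs.tsv")
        if (in_dir / "truth_genes.tsv").exists():
            truth = _stage("load")(io.read_truth)(in_dir)
        datasets = {}
        for ds_id, sub in design.groupby("dataset_id"):
            ann, bound, input_ = _stage("load")(io.read_dataset_dir)(in_dir / ds_id)
            groups = sub.set_index("sample_id")["group"]
            datasets[ds_id] = (ann, bound, input_, groups)
        if config.core_ids is None:
            raise PipelineError("stage 'load' failed: core_ids must be given "
                                "when running from an input directory")
        core = config.core_ids
        extension = config.extension_ids or []

    # --------------------------------------------------- call per dataset ----
    gene_call_tables: dict[str, pd.DataFrame] = {}
    report["datasets"] = {}
    for ds_id in sorted(datasets):
        ann, bound, input_, groups = datasets[ds_id]
        probe_calls = _stage("call")(call_dataset)(
            bound, input_, groups, annotation=ann.probes,
            fdr_threshold=config.fdr_threshold, test=config.test)
        io.write_probe_calls(probe_calls, out_dir / f"{ds_id}.probe_calls.tsv")

        assigned, unassigned = _stage("genes")(map_probes_to_genes)(
            probe_calls.drop(columns=["gene_id"], errors="ignore"), ann.genes)
        gene_calls = _stage("genes")(classify_genes)(assigned, dataset_id=ds_id)
        io.write_gene_calls(gene_calls, out_dir / f"{ds_id}.gene_calls.tsv")
        gene_call_tables[ds_id] = gene_calls

        summary = summarize_dataset(gene_calls, probe_calls)
        summary["probes_unassigned"] = len(unassigned)
        report["datasets"][ds_id] = summary
        if truth is not None:
            rec = _stage("recovery")(evaluate_recovery)(gene_calls, truth, ds_id)
            report["datasets"][ds_id]["recovery"] = {
                "sensitivity": rec.sensitivity,
                "empirical_fdr": rec.empirical_fdr,
                "direction_accuracy": rec.direction_accuracy,
                "n_planted": rec.n_planted,
                "n_called": rec.n_called,
            }

    # ------------------------------------------------------------ funnel ----
    if len(core) >= 2:
        funnel = _stage("intersect")(build_funnel)(
            gene_call_tables, core, extension, ortholog_map=orthologs)
        report["funnel"] = funnel_report(funnel, venn_datasets=core[:5])
        for stage_name in ("core_overlap", "direction_consistent",
                           "extension_consistent"):
            pd.DataFrame({"ortholog_group": report["funnel"][stage_name]}).to_csv(
                out_dir / f"funnel.{stage_name}.tsv", sep="\t", index=False)
    else:
        report["funnel"] = None
        logger.info("fewer than 2 core datasets; skipping the intersection")

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
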