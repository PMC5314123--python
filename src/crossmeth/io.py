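"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are TSV; all intervals are 6-column BED (0-based, half-open).
A simulated study directory looks like::

    out/
      design.tsv                    sample_id  dataset_id  group
      orthologs.tsv                 ortholog_group  dataset_id  local_gene_id
      truth_genes.tsv               dataset_id  gene_label  state
      truth_probes.tsv              dataset_id  probe_id  true_shift
      <dataset_id>/probes.bed       probe intervals (name = probe_id)
      <dataset_id>/genes.bed        gene regions  (name = gene_id)
      <dataset_id>/intensities.tsv  probe_id  sample_id  channel  intensity
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError
from .simulate import StudyData, SyntheticTruth, DatasetAnnotation

FLOAT_FMT = "%.10g"


def write_bed(df: pd.DataFrame, path: Path, name_col: str) -> None:
    bed = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df[name_col], "score": 0, "strand": ".",
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: Path, name_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", name_col, "score", "strand"])
    return df.drop(columns=["score", "strand"])


def write_study(study: StudyData, out_dir: Path) -> None:
    """Write a full simulated study to ``out_dir`` (created if needed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study.design_table.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    study.orthologs.to_csv(out_dir / "orthologs.tsv", sep="\t", index=False)

    truth_genes = pd.DataFrame(
        [(ds, g, s) for ds, states in study.truth.states.items()
         for g, s in states.items()],
        columns=["dataset_id", "gene_label", "state"])
    truth_genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    truth_probes = pd.concat(
        [shifts.rename("true_shift").reset_index().assign(dataset_id=ds)
         for ds, shifts in study.truth.probe_shifts.items()],
        ignore_index=True)[["dataset_id", "probe_id", "true_shift"]]
    truth_probes.to_csv(out_dir / "truth_probes.tsv", sep="\t", index=False,
                        float_format=FLOAT_FMT)

    for ds_id, data in study.datasets.items():
        ds_dir = out_dir / ds_id
        ds_dir.mkdir(exist_ok=True)
        ann = study.annotation[ds_id]
        write_bed(ann.probes, ds_dir / "probes.bed", "probe_id")
        write_bed(ann.genes, ds_dir / "genes.bed", "gene_id")
        long = pd.concat([
            data.bound.rename_axis("probe_id").reset_index()
                .melt(id_vars="probe_id", var_name="sample_id",
                      value_name="intensity").assign(channel="bound"),
            data.input.rename_axis("probe_id").reset_index()
                .melt(id_vars="probe_id", var_name="sample_id",
                      value_name="intensity").assign(channel="input"),
        ], ignore_index=True)[["probe_id", "sample_id", "channel", "intensity"]]
        long.to_csv(ds_dir / "intensities.tsv", sep="\t", index=False,
                    float_format=FLOAT_FMT)


def read_intensities(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long intensity TSV -> (bound, input) probe x sample tables."""
    long = pd.read_csv(path, sep="\t")
    required = {"probe_id", "sample_id", "channel", "intensity"}
    if not required <= set(long.columns):
        raise InputError(f"intensity table {path} lacks columns "
                         f"{sorted(required - set(long.columns))}")
    tables = {}
    for channel in ("bound", "input"):
        sub = long[long["channel"] == channel]
        tables[channel] = sub.pivot(index="probe_id", columns="sample_id",
                                    values="intensity")
    return tables["bound"], tables["input"]


def read_design(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "dataset_id", "group"} <= set(df.columns):
        raise InputError(f"design table {path} needs sample_id/dataset_id/group")
    return df


def read_orthologs(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_truth(out_dir: Path) -> SyntheticTruth:
    out_dir = Path(out_dir)
    # keep_default_na: the literal state "null" must survive the round trip
    genes = pd.read_csv(out_dir / "truth_genes.tsv", sep="\t",
                        keep_default_na=False)
    probes = pd.read_csv(out_dir / "truth_probes.tsv", sep="\t")
    states = {
        ds: dict(zip(sub["gene_label"], sub["state"]))
        for ds, sub in genes.groupby("dataset_id")
    }
    shifts = {
        ds: sub.set_index("probe_id")["true_shift"]
        for ds, sub in probes.groupby("dataset_id")
    }
    labels = list(dict.fromkeys(genes["gene_label"]))
    orthologs = read_orthologs(out_dir / "orthologs.tsv")
    local = {
        ds: dict(zip(sub["ortholog_group"], sub["local_gene_id"]))
        for ds, sub in orthologs.groupby("dataset_id")
    }
    return SyntheticTruth(gene_labels=labels, states=states, probe_shifts=shifts,
                          local_gene_ids=local)


def read_dataset_dir(ds_dir: Path) -> tuple[DatasetAnnotation, pd.DataFrame, pd.DataFrame]:
    """(annotation, bound, input) from one dataset directory."""
    ds_dir = Path(ds_dir)
    probes = read_bed(ds_dir / "probes.bed", "probe_id")
    genes = read_bed(ds_dir / "genes.bed", "gene_id")
    bound, input_ = read_intensities(ds_dir / "intensities.tsv")
    return DatasetAnnotation(probes=probes, genes=genes), bound, input_


def write_probe_calls(calls: pd.DataFrame, path: Path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_gene_calls(calls: pd.DataFrame, path: Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_gene_calls(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
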