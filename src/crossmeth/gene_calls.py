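"""Probe-to-gene assignment and gene-level direction classification.

A gene's dataset-level class follows its significant probes only: all
significant probes up -> hyper, all down -> hypo, both -> mixed, none
significant -> none.  A single significant probe suffices for DM status, and a
probe overlapping two gene regions contributes to both genes.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd
import pyranges as pr

from .errors import InputError

GENE_CLASSES = ("hyper", "hypo", "mixed", "none")


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise InputError(f"{what} table lacks required column {col!r}")
    if (df["end"] <= df["start"]).any():
        bad = df.loc[df["end"] <= df["start"]].iloc[0]
        raise InputError(
            f"malformed {what} interval {bad['chrom']}:{bad['start']}-{bad['end']} "
            f"(end <= start)"
        )


def map_probes_to_genes(probe_calls: pd.DataFrame, gene_regions: pd.DataFrame,
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Assign probes to every gene region they overlap by >= 1 bp.

    Coordinates are 0-based half-open in both tables, so a probe ending where
    a region starts does not overlap it.  Returns the probe-call rows joined
    with ``gene_id`` (one row per probe-gene pair) and the ids of probes that
    overlap no region.
    """
    _check_intervals(probe_calls, "probe")
    _check_intervals(gene_regions, "gene region")
    probes = pr.PyRanges(probe_calls.rename(columns={
        "chrom": "Chromosome", "start": "Start", "end": "End"}))
    genes = pr.PyRanges(gene_regions[["chrom", "start", "end", "gene_id"]].rename(
        columns={"chrom": "Chromosome", "start": "Start", "end": "End"}))
    joined = probes.join(genes, how=None).df
    if joined.empty:
        assigned = probe_calls.iloc[0:0].assign(gene_id=pd.Series(dtype=object))
    else:
        assigned = (joined.drop(columns=["Start_b", "End_b"])
                    .rename(columns={"Chromosome": "chrom", "Start": "start",
                                     "End": "end"}))
        assigned = assigned[list(probe_calls.columns) + ["gene_id"]]
        assigned = assigned.sort_values(["gene_id", "probe_id"]).reset_index(drop=True)
    unassigned = sorted(set(probe_calls["probe_id"]) - set(assigned["probe_id"]))
    return assigned, unassigned


def classify_gene_direction(directions) -> tuple[str, int, int, int]:
    """Class plus (n_hyper, n_hypo, n_ns) for one gene's probe directions."""
    directions = list(directions)
    if not directions:
        raise InputError("cannot classify a gene with zero probes")
    counts = Counter(directions)
    unknown = set(counts) - {"hyper", "hypo", "ns"}
    if unknown:
        raise InputError(f"unknown probe directions {sorted(unknown)}")
    n_hyper, n_hypo, n_ns = counts["hyper"], counts["hypo"], counts["ns"]
    if n_hyper and n_hypo:
        cls = "mixed"
    elif n_hyper:
        cls = "hyper"
    elif n_hypo:
        cls = "hypo"
    else:
        cls = "none"
    return cls, n_hyper, n_hypo, n_ns


def classify_genes(assigned_calls: pd.DataFrame,
                   dataset_id: str | None = None) -> pd.DataFrame:
    """Gene-call table from probe calls already joined with ``gene_id``."""
    for col in ("gene_id", "direction"):
        if col not in assigned_calls.columns:
            raise InputError(f"assigned probe calls lack column {col!r}")
    rows = []
    for gene, sub in assigned_calls.groupby("gene_id", sort=True):
        cls, n_hyper, n_hypo, n_ns = classify_gene_direction(sub["direction"])
        rows.append((gene, n_hyper, n_hypo, n_ns, cls))
    out = pd.DataFrame(rows, columns=["gene_id", "n_probes_hyper", "n_probes_hypo",
                                      "n_probes_ns", "direction_class"])
    if dataset_id is not None:
        out.insert(1, "dataset_id", dataset_id)
    return out


def summarize_dataset(gene_calls: pd.DataFrame,
                      probe_calls: pd.DataFrame | None = None) -> dict:
    """Counts of genes per class (and probes per direction when provided)."""
    cls = gene_calls["direction_class"].value_counts()
    summary = {f"genes_{c}": int(cls.get(c, 0)) for c in GENE_CLASSES}
    summary["genes_dm"] = (summary["genes_hyper"] + summary["genes_hypo"]
                           + summary["genes_mixed"])
    if probe_calls is not None:
        direction = probe_calls["direction"].value_counts()
        for d in ("hyper", "hypo", "ns"):
            summary[f"probes_{d}"] = int(direction.get(d, 0))
        summary["probes_dm"] = summary["probes_hyper"] + summary["probes_hypo"]
    return summary
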