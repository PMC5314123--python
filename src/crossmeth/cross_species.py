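"""Ortholog-harmonized intersection of gene calls across datasets.

The candidate funnel has three stages:

1. *core overlap* — genes differentially methylated (hyper, hypo or mixed)
   in every core dataset, regardless of direction;
2. *direction consistent* — the subset whose class is the same non-mixed
   direction (all hyper, or all hypo) in every core dataset;
3. *extension consistent* — the subset that keeps that same direction in
   every extension dataset (peripheral surrogate tissues).

Gene calls from different species are first mapped onto ortholog groups; when
no mapping table is supplied, case-insensitive symbol equality is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputError
from .gene_calls import GENE_CLASSES

logger = logging.getLogger(__name__)

DM_CLASSES = frozenset({"hyper", "hypo", "mixed"})


@dataclass
class IntersectionFunnel:
    """Staged result of the cross-dataset intersection."""

    core_ids: list[str]
    extension_ids: list[str]
    core_overlap: set[str]
    direction_consistent: set[str]
    extension_consistent: set[str]
    core_direction: dict[str, str]  # direction of each direction-consistent gene
    class_table: pd.DataFrame       # ortholog_group x dataset_id -> class

    def __post_init__(self) -> None:
        if not (self.extension_consistent <= self.direction_consistent
                <= self.core_overlap):
            raise InputError("funnel stages violate the subset chain")

    @property
    def stage_counts(self) -> tuple[int, int, int]:
        return (len(self.core_overlap), len(self.direction_consistent),
                len(self.extension_consistent))


def validate_ortholog_map(ortholog_map: pd.DataFrame) -> pd.DataFrame:
    required = {"ortholog_group", "dataset_id", "local_gene_id"}
    missing = required - set(ortholog_map.columns)
    if missing:
        raise InputError(f"ortholog map lacks columns {sorted(missing)}")
    groups_per_gene = ortholog_map.groupby(
        ["dataset_id", "local_gene_id"])["ortholog_group"].nunique()
    if (groups_per_gene > 1).any():
        ds, gene = groups_per_gene.index[groups_per_gene > 1][0]
        raise InputError(
            f"local gene {gene!r} in dataset {ds!r} maps to multiple ortholog groups"
        )
    return ortholog_map


def _merge_classes(classes: Iterable[str]) -> str:
    """One class for an ortholog group with several local genes in a dataset."""
    present = set(classes)
    hyper = "hyper" in present or "mixed" in present
    hypo = "hypo" in present or "mixed" in present
    if hyper and hypo:
        return "mixed"
    if hyper:
        return "hyper"
    if hypo:
        return "hypo"
    return "none"


def harmonize_gene_ids(calls_by_dataset: Mapping[str, pd.DataFrame],
                       ortholog_map: pd.DataFrame | None = None,
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Re-key per-dataset gene calls by ortholog group.

    Returns a long frame (ortholog_group, dataset_id, direction_class) with one
    row per group per dataset, plus per-dataset counts of calls dropped because
    their gene had no ortholog mapping.
    """
    if ortholog_map is not None:
        validate_ortholog_map(ortholog_map)
    frames, dropped = [], {}
    for ds_id, calls in calls_by_dataset.items():
        bad = set(calls["direction_class"]) - set(GENE_CLASSES)
        if bad:
            raise InputError(f"unknown gene classes {sorted(bad)} in {ds_id!r}")
        df = calls[["gene_id", "direction_class"]].copy()
        df["gene_id"] = df["gene_id"].astype(str)
        if ortholog_map is None:
            df["ortholog_group"] = df["gene_id"].str.upper()
            dropped[ds_id] = 0
        else:
            sub = ortholog_map.loc[ortholog_map["dataset_id"] == ds_id,
                                   ["local_gene_id", "ortholog_group"]]
            df = df.merge(sub, left_on="gene_id", right_on="local_gene_id",
                          how="left")
            unmapped = df["ortholog_group"].isna()
            dropped[ds_id] = int(unmapped.sum())
            if dropped[ds_id]:
                logger.info("dataset %s: dropped %d calls without ortholog mapping",
                            ds_id, dropped[ds_id])
            df = df.loc[~unmapped]
        merged = (df.groupby("ortholog_group")["direction_class"]
                  .agg(_merge_classes).reset_index())
        merged["dataset_id"] = ds_id
        frames.append(merged[["ortholog_group", "dataset_id", "direction_class"]])
    if not frames:
        harmonized = pd.DataFrame(
            columns=["ortholog_group", "dataset_id", "direction_class"])
    else:
        harmonized = pd.concat(frames, ignore_index=True)
    return harmonized, dropped


def _dm_sets(harmonized: pd.DataFrame) -> dict[str, set[str]]:
    dm = harmonized[harmonized["direction_class"].isin(DM_CLASSES)]
    return {ds: set(sub["ortholog_group"])
            for ds, sub in dm.groupby("dataset_id")}


def _require_known(harmonized: pd.DataFrame, dataset_ids: Iterable[str],
                   known: set[str] | None = None) -> None:
    # a dataset with zero calls legitimately has no harmonized rows, so the
    # caller may pass the full dataset universe explicitly
    if known is None:
        known = set(harmonized["dataset_id"])
    unknown = set(dataset_ids) - known
    if unknown:
        raise InputError(f"unknown dataset ids {sorted(unknown)}; "
                         f"harmonized calls cover {sorted(known)}")


def intersect_datasets(harmonized: pd.DataFrame, core_ids: Iterable[str],
                       known_datasets: set[str] | None = None) -> set[str]:
    """Genes differentially methylated in EVERY core dataset, any direction."""
    core_ids = list(core_ids)
    if len(core_ids) < 2:
        raise InputError("need at least 2 core datasets to intersect")
    _require_known(harmonized, core_ids, known_datasets)
    dm = _dm_sets(harmonized)
    overlap = dm.get(core_ids[0], set()).copy()
    for ds in core_ids[1:]:
        overlap &= dm.get(ds, set())
    return overlap


def filter_consistent_direction(overlap: set[str], harmonized: pd.DataFrame,
                                core_ids: Iterable[str],
                                ) -> tuple[set[str], dict[str, str]]:
    """Keep genes with the same non-mixed class in every core dataset.

    A mixed class in any core dataset disqualifies a gene.  Returns the subset
    and each kept gene's shared direction.
    """
    core_ids = list(core_ids)
    cls = harmonized.set_index(["ortholog_group", "dataset_id"])["direction_class"]
    kept, direction = set(), {}
    for gene in overlap:
        classes = {cls.get((gene, ds), "none") for ds in core_ids}
        if classes == {"hyper"} or classes == {"hypo"}:
            kept.add(gene)
            direction[gene] = classes.pop()
    return kept, direction


def apply_extension_filter(consistent: set[str], harmonized: pd.DataFrame,
                           extension_ids: Iterable[str],
                           core_direction: Mapping[str, str],
                           known_datasets: set[str] | None = None) -> set[str]:
    """Keep genes whose class equals their core direction in EVERY extension
    dataset; a gene absent from an extension call table is dropped."""
    extension_ids = list(extension_ids)
    if not extension_ids:
        return set(consistent)
    _require_known(harmonized, extension_ids, known_datasets)
    cls = harmonized.set_index(["ortholog_group", "dataset_id"])["direction_class"]
    kept = set()
    for gene in consistent:
        wanted = core_direction[gene]
        seen = [cls.get((gene, ds)) for ds in extension_ids]
        if any(c is None for c in seen):
            logger.info("gene %s absent from an extension dataset; dropped", gene)
            continue
        if all(c == wanted for c in seen):
            kept.add(gene)
    return kept


def build_funnel(calls_by_dataset: Mapping[str, pd.DataFrame],
                 core_ids: Iterable[str], extension_ids: Iterable[str] = (),
                 ortholog_map: pd.DataFrame | None = None) -> IntersectionFunnel:
    """Run all three funnel stages on per-dataset gene-call tables."""
    harmonized, _ = harmonize_gene_ids(calls_by_dataset, ortholog_map)
    core_ids, extension_ids = list(core_ids), list(extension_ids)
    known = set(calls_by_dataset)
    overlap = intersect_datasets(harmonized, core_ids, known_datasets=known)
    consistent, direction = filter_consistent_direction(overlap, harmonized, core_ids)
    final = apply_extension_filter(consistent, harmonized, extension_ids, direction,
                                   known_datasets=known)
    table = (harmonized.pivot(index="ortholog_group", columns="dataset_id",
                              values="direction_class")
             .fillna("none"))
    return IntersectionFunnel(
        core_ids=core_ids, extension_ids=extension_ids, core_overlap=overlap,
        direction_consistent=consistent, extension_consistent=final,
        core_direction=direction, class_table=table,
    )


def venn_regions(dm_sets: Mapping[str, set[str]]) -> dict[frozenset, int]:
    """Exact Venn region sizes (genes in exactly that subset of sets)."""
    if not 2 <= len(dm_sets) <= 5:
        raise InputError("Venn regions are reported for 2-5 datasets")
    names = list(dm_sets)
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(dm_sets[n] for n in combo))
            outside = set.union(set(), *(dm_sets[n] for n in names if n not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def funnel_report(funnel: IntersectionFunnel,
                  venn_datasets: Iterable[str] | None = None) -> dict:
    """JSON-ready summary: stage counts, per-stage gene lists, class table,
    and (optionally) Venn region counts for 2-5 chosen datasets."""
    report = {
        "core_datasets": funnel.core_ids,
        "extension_datasets": funnel.extension_ids,
        "stage_counts": {
            "core_overlap": len(funnel.core_overlap),
            "direction_consistent": len(funnel.direction_consistent),
            "extension_consistent": len(funnel.extension_consistent),
        },
        "core_overlap": sorted(funnel.core_overlap),
        "direction_consistent": sorted(funnel.direction_consistent),
        "extension_consistent": sorted(funnel.extension_consistent),
        "core_direction": dict(sorted(funnel.core_direction.items())),
        "classes": {g: row.to_dict()
                    for g, row in funnel.class_table.iterrows()},
    }
    if venn_datasets is not None:
        venn_datasets = list(venn_datasets)
        table = funnel.class_table
        dm_sets = {
            ds: set(table.index[table.get(ds, pd.Series(dtype=object))
                    .isin(DM_CLASSES)]) if ds in table.columns else set()
            for ds in venn_datasets
        }
        regions = venn_regions(dm_sets)
        report["venn_regions"] = {
            "&".join(sorted(k)): v for k, v in sorted(
                regions.items(), key=lambda kv: ("&".join(sorted(kv[0]))))
        }
    return report
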