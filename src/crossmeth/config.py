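"""Study configuration for the synthetic multi-cohort MeDIP-chip generator.

A study is a collection of datasets (species x tissue cohorts), each hybridised
on its own two-channel tiling array, plus a set of *planted* genes whose
methylation state in each dataset is known in advance.  The default seven-cohort
design mirrors a typical cross-species early-life-stress study: a rat
prefrontal-cortex cohort, a human umbilical-cord CD34+ cohort, and five macaque
cohorts (prefrontal cortex, CD3+ T cells at two ages, whole blood, buccal
cells), the last two serving as peripheral *extension* tissues rather than core
discovery sets.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, model_validator

GeneState = Literal["hyper", "hypo", "mixed", "null"]
DatasetRole = Literal["core", "extension"]


class DatasetDesign(BaseModel):
    """One cohort: a two-group (control vs stress) two-channel array dataset.

    ``pooled`` marks cohorts whose biological samples were pooled before
    immunoprecipitation; such cohorts are simulated as one replicate per pool.
    """

    dataset_id: str
    species: str
    tissue: str
    role: DatasetRole = "core"
    n_control: int = Field(ge=2, description="two-group tests need >=2 per group")
    n_stress: int = Field(ge=2)
    pooled: bool = False


class PlantedGene(BaseModel):
    """A gene with a known methylation state per dataset.

    Datasets absent from ``state_by_dataset`` are implicitly ``null`` (no
    planted shift).  ``effect_multiplier`` scales the study-wide effect size
    for this gene only.
    """

    gene_label: str
    state_by_dataset: dict[str, GeneState] = Field(default_factory=dict)
    effect_multiplier: float = Field(default=1.0, gt=0)


class StudyConfig(BaseModel):
    """Full specification of a synthetic multi-dataset study.

    ``baseline_logratio_sd`` is the per-sample Gaussian noise on the
    log2(bound/input) scale; ``effect_logratio`` the planted mean shift (log2)
    added to the stress group of differentially methylated probes.
    """

    datasets: list[DatasetDesign]
    n_genes: int = Field(gt=0)
    probes_per_gene: int = Field(default=3, ge=1)
    probe_length_bp: int = Field(default=60, ge=1)
    planted_genes: list[PlantedGene] = Field(default_factory=list)
    baseline_logratio_sd: float = Field(default=0.5, gt=0)
    effect_logratio: float = Field(default=1.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_cross_references(self) -> "StudyConfig":
        ids = [d.dataset_id for d in self.datasets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"datasets: duplicate dataset_id {dupes}")
        labels = [g.gene_label for g in self.planted_genes]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"planted_genes: duplicate gene_label {dupes}")
        if self.n_genes < len(labels):
            raise ValueError(
                f"n_genes: {self.n_genes} is smaller than the "
                f"{len(labels)} distinct planted gene labels"
            )
        known = set(ids)
        for gene in self.planted_genes:
            unknown = set(gene.state_by_dataset) - known
            if unknown:
                raise ValueError(
                    f"planted_genes[{gene.gene_label}].state_by_dataset: "
                    f"unknown dataset ids {sorted(unknown)}"
                )
        return self

    @property
    def core_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets if d.role == "core"]

    @property
    def extension_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets if d.role == "extension"]


def seven_cohort_design() -> list[DatasetDesign]:
    """The default seven-cohort cross-species design with its group sizes.

    The CD3+ cohorts are pooled (3 control and 3 stress pools per age), so
    they carry 3 replicates per group.
    """
    return [
        DatasetDesign(dataset_id="rat_pfc", species="rat", tissue="prefrontal_cortex",
                      role="core", n_control=4, n_stress=4),
        DatasetDesign(dataset_id="human_cd34", species="human", tissue="cord_blood_cd34",
                      role="core", n_control=8, n_stress=10),
        DatasetDesign(dataset_id="monkey_pfc", species="macaque", tissue="prefrontal_cortex",
                      role="core", n_control=4, n_stress=4),
        DatasetDesign(dataset_id="monkey_cd3_30d", species="macaque", tissue="cd3_tcells_30d",
                      role="core", n_control=3, n_stress=3, pooled=True),
        DatasetDesign(dataset_id="monkey_cd3_2y", species="macaque", tissue="cd3_tcells_2y",
                      role="core", n_control=3, n_stress=3, pooled=True),
        DatasetDesign(dataset_id="monkey_blood", species="macaque", tissue="whole_blood",
                      role="extension", n_control=5, n_stress=5),
        DatasetDesign(dataset_id="monkey_buccal", species="macaque", tissue="buccal",
                      role="extension", n_control=3, n_stress=3),
    ]


#: Gene symbols used by the demo study; chosen to exercise the funnel stages.
DEMO_SURVIVOR = "ANK3"
DEMO_CONSISTENT_ONLY = "GABRG2"
DEMO_MIXED = ("CNGA4", "DARS2", "HTR4", "LPHN2", "SLC22A2", "TIAM1")


def funnel_demo_config(
    seed: int = 0,
    n_genes: int = 100,
    effect_logratio: float = 1.5,
    baseline_logratio_sd: float = 0.3,
) -> StudyConfig:
    """Demo study reproducing the staged 8 -> 2 -> 1 candidate funnel.

    Eight genes are planted differentially methylated in all five core
    datasets; exactly two of them (ANK3, GABRG2) are hypermethylated in every
    core dataset while the other six are mixed; only ANK3 is additionally
    hypermethylated in both extension tissues.

    Beyond the eight shared genes, a few partial multi-cohort genes make the
    Venn regions non-trivial, and each peripheral cohort carries its own
    tissue-specific background DM set (~15% of the universe), so that every
    dataset's differentially methylated fraction sits near the ~20% typical
    of such studies: this keeps the per-dataset FDR step-up powered in the
    small pooled cohorts while per-dataset false-gene rates stay low enough
    that the all-cohort overlap is driven by the shared genes.
    """
    datasets = seven_cohort_design()
    core = [d.dataset_id for d in datasets if d.role == "core"]
    extension = [d.dataset_id for d in datasets if d.role == "extension"]

    planted = [
        PlantedGene(gene_label=DEMO_SURVIVOR,
                    state_by_dataset={ds: "hyper" for ds in core + extension}),
        PlantedGene(gene_label=DEMO_CONSISTENT_ONLY,
                    state_by_dataset={ds: "hyper" for ds in core}),
    ]
    planted += [
        PlantedGene(gene_label=label, state_by_dataset={ds: "mixed" for ds in core})
        for label in DEMO_MIXED
    ]
    # partial-overlap genes: differentially methylated in some cohorts only
    planted += [
        PlantedGene(gene_label="PARTIAL_RAT", state_by_dataset={"rat_pfc": "hypo"}),
        PlantedGene(gene_label="PARTIAL_HUMAN", state_by_dataset={"human_cd34": "hyper"}),
        PlantedGene(gene_label="PARTIAL_BRAIN",
                    state_by_dataset={"rat_pfc": "hyper", "monkey_pfc": "hyper"}),
        PlantedGene(gene_label="PARTIAL_BLOOD",
                    state_by_dataset={"monkey_cd3_30d": "hypo", "monkey_cd3_2y": "hypo",
                                      "monkey_blood": "hypo"}),
    ]
    # tissue-specific background DM genes in every peripheral cohort (blood
    # and buccal tissues vary in cell composition, so each such cohort has
    # its own DM set); these keep the non-null probe fraction of the low-n
    # peripheral datasets realistic so the FDR step-up retains power there,
    # while the brain cohorts' overlap stays driven by the shared genes
    states = ("hyper", "hypo", "mixed")
    for ds in datasets:
        if ds.tissue == "prefrontal_cortex":
            continue
        planted += [
            PlantedGene(gene_label=f"BG_{ds.dataset_id.upper()}_{k}",
                        state_by_dataset={ds.dataset_id: states[k % 3]})
            for k in range(max(3, round(0.15 * n_genes)))
        ]
    return StudyConfig(
        datasets=datasets,
        n_genes=n_genes,
        planted_genes=planted,
        effect_logratio=effect_logratio,
        baseline_logratio_sd=baseline_logratio_sd,
        seed=seed,
    )
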