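"""Synthetic two-channel tiling-array study generator with planted truth.

The generative model works on the log2(bound/input) scale, which is the scale
the downstream per-probe t statistics operate on:

* every probe carries a per-dataset baseline log-ratio drawn once from N(0, 1)
  (shared by both groups, so it cancels in group differences);
* every sample adds independent Gaussian noise N(0, baseline_logratio_sd);
* stress-group samples of a planted gene's probes receive an additional mean
  shift of +/- effect_logratio * effect_multiplier according to the planted
  state (hyper: all probes +, hypo: all -, mixed: first half +, second half -,
  with the extra probe shifted + when the probe count is odd);
* channel intensities are reconstructed as input = 2**U with U ~ Uniform(6, 12)
  and bound = input * 2**logratio, so both channels are strictly positive.

Dye bias, spatial artifacts, copy-number confounds and sequence-dependent
immunoprecipitation efficiency are deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .config import StudyConfig, DatasetDesign
from .errors import ConfigurationError, InputError

PROBE_SPACING_BP = 200
GENE_MARGIN_BP = 500
GENE_REGION_OFFSET = 10_000_000

#: chromosome label used for the simulated promoter tile, per species
_SPECIES_CHROM = {"rat": "chr20", "human": "chr10", "macaque": "chr14"}


@dataclass
class DatasetAnnotation:
    """Probe and gene-region intervals of one dataset (0-based, half-open)."""

    probes: pd.DataFrame  # chrom, start, end, probe_id, gene_id
    genes: pd.DataFrame   # chrom, start, end, gene_id


@dataclass
class SyntheticTruth:
    """Planted per-gene states and per-probe true mean log-ratio shifts."""

    gene_labels: list[str]
    states: dict[str, dict[str, str]]          # dataset_id -> gene_label -> state
    probe_shifts: dict[str, pd.Series]         # dataset_id -> probe_id -> shift
    local_gene_ids: dict[str, dict[str, str]]  # dataset_id -> gene_label -> local id

    def dm_genes(self, dataset_id: str) -> set[str]:
        """Labels of genes planted differentially methylated in a dataset."""
        return {g for g, s in self.states[dataset_id].items() if s != "null"}


@dataclass
class DatasetData:
    """Simulated two-channel intensities and design of one dataset."""

    design: DatasetDesign
    bound: pd.DataFrame   # probes x samples
    input: pd.DataFrame   # probes x samples
    groups: pd.Series     # sample_id -> control | stress


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    config: StudyConfig
    annotation: dict[str, DatasetAnnotation]
    datasets: dict[str, DatasetData]
    orthologs: pd.DataFrame  # ortholog_group, dataset_id, local_gene_id
    truth: SyntheticTruth

    @property
    def design_table(self) -> pd.DataFrame:
        rows = [
            (sample, ds_id, group)
            for ds_id, data in self.datasets.items()
            for sample, group in data.groups.items()
        ]
        return pd.DataFrame(rows, columns=["sample_id", "dataset_id", "group"])


@dataclass
class RecoverySummary:
    """Confusion summary of gene-level calls against the planted truth."""

    dataset_id: str
    n_planted: int
    n_called: int
    n_true_positive: int
    sensitivity: float
    empirical_fdr: float
    direction_accuracy: float
    extras: dict = field(default_factory=dict)


def validate_config(config) -> StudyConfig:
    if isinstance(config, StudyConfig):
        return config
    try:
        return StudyConfig.model_validate(config)
    except ValidationError as exc:  # re-raise naming the offending field
        raise ConfigurationError(str(exc)) from exc


def gene_labels(config: StudyConfig) -> list[str]:
    """Planted labels first, then synthetic filler labels up to n_genes."""
    labels = [g.gene_label for g in config.planted_genes]
    labels += [f"G{i:04d}" for i in range(len(labels), config.n_genes)]
    return labels


def _local_gene_id(label: str, species: str) -> str:
    # rat symbols are conventionally capitalised, primate symbols upper-case
    return label.capitalize() if species == "rat" else label.upper()


def generate_annotation(config: StudyConfig | dict) -> dict[str, DatasetAnnotation]:
    """Lay out non-overlapping gene regions, each tiled by equally spaced probes.

    Each gene region spans its probes plus a margin on both sides; probes are
    ``probe_length_bp`` long and every probe lies inside exactly one gene
    region.  All coordinates are 0-based half-open.
    """
    config = validate_config(config)
    labels = gene_labels(config)
    spacing = max(PROBE_SPACING_BP, config.probe_length_bp + 10)
    probe_span = (config.probes_per_gene - 1) * spacing + config.probe_length_bp
    gene_span = probe_span + 2 * GENE_MARGIN_BP

    annotation: dict[str, DatasetAnnotation] = {}
    for ds in config.datasets:
        chrom = _SPECIES_CHROM.get(ds.species, "chr1")
        gene_rows, probe_rows = [], []
        for i, label in enumerate(labels):
            local = _local_gene_id(label, ds.species)
            gstart = GENE_REGION_OFFSET + i * (gene_span + GENE_MARGIN_BP)
            gene_rows.append((chrom, gstart, gstart + gene_span, local))
            for k in range(config.probes_per_gene):
                pstart = gstart + GENE_MARGIN_BP + k * spacing
                probe_rows.append(
                    (chrom, pstart, pstart + config.probe_length_bp,
                     f"{ds.dataset_id}_g{i:04d}_p{k}", local)
                )
        annotation[ds.dataset_id] = DatasetAnnotation(
            probes=pd.DataFrame(probe_rows,
                                columns=["chrom", "start", "end", "probe_id", "gene_id"]),
            genes=pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"]),
        )
    return annotation


def _probe_shifts(config: StudyConfig, ds_id: str, probes: pd.DataFrame,
                  labels: list[str]) -> np.ndarray:
    """True stress-group mean shift per probe, following the planted states."""
    ppg = config.probes_per_gene
    state_of = {
        g.gene_label: (g.state_by_dataset.get(ds_id, "null"), g.effect_multiplier)
        for g in config.planted_genes
    }
    shifts = np.zeros(len(probes))
    for i, label in enumerate(labels):
        state, mult = state_of.get(label, ("null", 1.0))
        if state == "null":
            continue
        effect = config.effect_logratio * mult
        sl = slice(i * ppg, (i + 1) * ppg)
        if state == "hyper":
            shifts[sl] = effect
        elif state == "hypo":
            shifts[sl] = -effect
        else:  # mixed: first half up (extra probe up when odd), rest down
            n_up = math.ceil(ppg / 2)
            shifts[i * ppg: i * ppg + n_up] = effect
            shifts[i * ppg + n_up: (i + 1) * ppg] = -effect
    return shifts


def generate_study(config: StudyConfig | dict) -> StudyData:
    """Simulate intensities, designs, ortholog table and truth for all datasets.

    Determinism contract: identical config (including its seed) yields
    byte-identical outputs.  Each dataset draws from its own child stream of
    the study seed, so adding a dataset does not perturb the others.
    """
    config = validate_config(config)
    annotation = generate_annotation(config)
    labels = gene_labels(config)
    children = np.random.SeedSequence(config.seed).spawn(len(config.datasets))

    datasets: dict[str, DatasetData] = {}
    states: dict[str, dict[str, str]] = {}
    probe_shifts: dict[str, pd.Series] = {}
    local_ids: dict[str, dict[str, str]] = {}
    ortho_rows = []

    for ds, seed_seq in zip(config.datasets, children):
        rng = np.random.default_rng(seed_seq)
        probes = annotation[ds.dataset_id].probes
        m = len(probes)
        shifts = _probe_shifts(config, ds.dataset_id, probes, labels)

        samples = [f"{ds.dataset_id}_ctrl{i + 1}" for i in range(ds.n_control)]
        samples += [f"{ds.dataset_id}_strs{i + 1}" for i in range(ds.n_stress)]
        groups = pd.Series(
            ["control"] * ds.n_control + ["stress"] * ds.n_stress,
            index=pd.Index(samples, name="sample_id"), name="group",
        )
        is_stress = (groups == "stress").to_numpy()

        baseline = rng.normal(0.0, 1.0, m)
        noise = rng.normal(0.0, config.baseline_logratio_sd, (m, len(samples)))
        logratio = baseline[:, None] + shifts[:, None] * is_stress[None, :] + noise
        log_input = rng.uniform(6.0, 12.0, (m, len(samples)))

        input_df = pd.DataFrame(np.exp2(log_input), index=probes["probe_id"],
                                columns=samples)
        bound_df = input_df * np.exp2(logratio)
        datasets[ds.dataset_id] = DatasetData(design=ds, bound=bound_df,
                                              input=input_df, groups=groups)

        planted_state = {
            g.gene_label: g.state_by_dataset.get(ds.dataset_id, "null")
            for g in config.planted_genes
        }
        states[ds.dataset_id] = {lb: planted_state.get(lb, "null") for lb in labels}
        probe_shifts[ds.dataset_id] = pd.Series(shifts, index=probes["probe_id"],
                                                name="true_shift")
        local_ids[ds.dataset_id] = {lb: _local_gene_id(lb, ds.species) for lb in labels}
        ortho_rows += [
            (lb, ds.dataset_id, _local_gene_id(lb, ds.species)) for lb in labels
        ]

    truth = SyntheticTruth(gene_labels=labels, states=states,
                           probe_shifts=probe_shifts, local_gene_ids=local_ids)
    orthologs = pd.DataFrame(
        ortho_rows, columns=["ortholog_group", "dataset_id", "local_gene_id"]
    )
    return StudyData(config=config, annotation=annotation, datasets=datasets,
                     orthologs=orthologs, truth=truth)


def simulate_qpcr_ct(n_control: int = 4, n_stress: int = 4,
                     planted_log2_effect: float = 0.0, sd_ct: float = 0.2,
                     seed: int = 0, reference_ct: float = 20.0,
                     base_delta_ct: float = 4.0,
                     target_col: str = "ct_target",
                     reference_col: str = "ct_reference") -> pd.DataFrame:
    """Two-group qPCR Ct table with a planted log2 abundance difference.

    A +1 log2 abundance in the stress group lowers its target Ct by one cycle
    (fold change 2 under the 2^-ddCt arithmetic).  Gaussian cycle noise of
    ``sd_ct`` is added to the target channel.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("control", n_control), ("stress", n_stress)):
        delta = base_delta_ct - (planted_log2_effect if group == "stress" else 0.0)
        for i in range(n):
            rows.append((f"{group}_{i + 1}", group,
                         reference_ct + delta + rng.normal(0.0, sd_ct),
                         reference_ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", target_col,
                                       reference_col])


def simulate_trajectory(ages: tuple[str, ...] = ("PND7", "PND21", "PND62"),
                        control_means: tuple[float, ...] = (1.0, 1.1, 2.0),
                        stress_effects: tuple[float, ...] = (0.0, 0.0, -1.0),
                        n_control: int = 7, n_stress: int = 9,
                        sd: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Tidy developmental-trajectory table (group x age) with planted effects.

    The defaults mirror a developmental expression design: stable values
    before weaning, a rise into adulthood, and a stress-group deficit planted
    at the last age only.
    """
    if not len(ages) == len(control_means) == len(stress_effects):
        raise InputError("ages, control_means and stress_effects must align")
    rng = np.random.default_rng(seed)
    rows = []
    for age, mu, eff in zip(ages, control_means, stress_effects):
        for group, n, shift in (("control", n_control, 0.0),
                                ("stress", n_stress, eff)):
            for i in range(n):
                rows.append((f"{group}_{age}_{i + 1}", group, age,
                             rng.normal(mu + shift, sd)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "age", "value"])


DM_CLASSES = frozenset({"hyper", "hypo", "mixed"})


def evaluate_recovery(gene_calls: pd.DataFrame, truth: SyntheticTruth,
                      dataset_id: str) -> RecoverySummary:
    """Score gene-level calls of one dataset against the planted truth.

    ``gene_calls`` needs columns ``gene_id`` and ``direction_class``; gene ids
    may be either canonical truth labels or the dataset's local (species-cased)
    symbols.  A gene counts as called when its class is hyper, hypo or mixed;
    genes absent from the table or classed ``none`` are not called.  Direction
    accuracy is the fraction of true positives whose class equals the planted
    state.
    """
    if dataset_id not in truth.states:
        raise InputError(f"unknown dataset_id {dataset_id!r}")
    by_fold = {lb.casefold(): lb for lb in truth.gene_labels}
    calls = gene_calls.reset_index() if "gene_id" not in gene_calls.columns else gene_calls
    unknown = [g for g in calls["gene_id"] if str(g).casefold() not in by_fold]
    if unknown:
        raise InputError(
            f"gene universe mismatch: calls contain genes not in the truth "
            f"universe, e.g. {sorted(set(map(str, unknown)))[:5]}"
        )
    state = truth.states[dataset_id]
    called = {
        by_fold[str(g).casefold()]: cls
        for g, cls in zip(calls["gene_id"], calls["direction_class"])
        if cls in DM_CLASSES
    }
    planted = truth.dm_genes(dataset_id)
    tp = set(called) & planted
    sensitivity = len(tp) / len(planted) if planted else 1.0
    fdr = (len(called) - len(tp)) / len(called) if called else 0.0
    dir_ok = sum(1 for g in tp if called[g] == state[g])
    return RecoverySummary(
        dataset_id=dataset_id,
        n_planted=len(planted),
        n_called=len(called),
        n_true_positive=len(tp),
        sensitivity=sensitivity,
        empirical_fdr=fdr,
        direction_accuracy=dir_ok / len(tp) if tp else 1.0,
    )
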