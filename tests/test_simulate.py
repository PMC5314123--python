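"""Synthetic-study generator: geometry, determinism, generative faithfulness."""

import numpy as np
import pandas as pd
import pytest

import crossmeth as cm
from crossmeth.simulate import gene_labels

from conftest import gene_calls_for


# ------------------------------------------------------------ annotation ----

def test_minimal_annotation_places_each_probe_in_its_gene(tiny_design):
    cfg = cm.StudyConfig(datasets=[tiny_design], n_genes=2, probes_per_gene=1)
    ann = cm.generate_annotation(cfg)["rat_pfc"]
    assert len(ann.probes) == 2 and len(ann.genes) == 2
    for _, p in ann.probes.iterrows():
        inside = ann.genes[(ann.genes.start <= p.start) & (p.end <= ann.genes.end)
                           & (ann.genes.chrom == p.chrom)]
        assert list(inside.gene_id) == [p.gene_id]


def test_probe_length_is_sixty_bases(tiny_config):
    ann = cm.generate_annotation(tiny_config)["rat_pfc"]
    assert ((ann.probes.end - ann.probes.start) == 60).all()


def test_gene_regions_do_not_overlap(tiny_config):
    genes = cm.generate_annotation(tiny_config)["rat_pfc"].genes.sort_values("start")
    assert (genes.start.values[1:] >= genes.end.values[:-1]).all()


def test_annotation_is_deterministic(tiny_config):
    a = cm.generate_annotation(tiny_config)["rat_pfc"]
    b = cm.generate_annotation(tiny_config)["rat_pfc"]
    pd.testing.assert_frame_equal(a.probes, b.probes)
    pd.testing.assert_frame_equal(a.genes, b.genes)


def test_invalid_config_names_offending_field(tiny_design):
    with pytest.raises(Exception, match="n_genes"):
        cm.StudyConfig(datasets=[tiny_design], n_genes=1, planted_genes=[
            cm.PlantedGene(gene_label="A", state_by_dataset={}),
            cm.PlantedGene(gene_label="B", state_by_dataset={}),
        ])
    with pytest.raises(Exception, match="state_by_dataset"):
        cm.StudyConfig(datasets=[tiny_design], n_genes=2, planted_genes=[
            cm.PlantedGene(gene_label="A", state_by_dataset={"nope": "hyper"}),
        ])
    with pytest.raises(Exception, match="dataset_id"):
        cm.StudyConfig(datasets=[tiny_design, tiny_design], n_genes=2)


# ----------------------------------------------------------------- study ----

def test_study_is_seed_deterministic(tiny_config):
    a = cm.generate_study(tiny_config)
    b = cm.generate_study(tiny_config)
    for ds in a.datasets:
        pd.testing.assert_frame_equal(a.datasets[ds].bound, b.datasets[ds].bound)
        pd.testing.assert_frame_equal(a.datasets[ds].input, b.datasets[ds].input)
    assert a.truth.states == b.truth.states


def test_different_seeds_differ(tiny_config):
    other = tiny_config.model_copy(update={"seed": tiny_config.seed + 1})
    a = cm.generate_study(tiny_config)
    b = cm.generate_study(other)
    assert not a.datasets["rat_pfc"].bound.equals(b.datasets["rat_pfc"].bound)


def test_intensities_strictly_positive(tiny_config):
    study = cm.generate_study(tiny_config)
    for data in study.datasets.values():
        assert (data.bound.to_numpy() > 0).all()
        assert (data.input.to_numpy() > 0).all()


def test_seven_cohort_design_group_sizes():
    """The default design carries the seven cohorts with their group sizes."""
    study = cm.generate_study(cm.StudyConfig(datasets=cm.seven_cohort_design(),
                                             n_genes=2, probes_per_gene=1))
    design = study.design_table
    sizes = {
        ds: (sub[sub.group == "control"].shape[0], sub[sub.group == "stress"].shape[0])
        for ds, sub in design.groupby("dataset_id")
    }
    assert sizes == {
        "rat_pfc": (4, 4), "human_cd34": (8, 10), "monkey_pfc": (4, 4),
        "monkey_cd3_30d": (3, 3), "monkey_cd3_2y": (3, 3),
        "monkey_blood": (5, 5), "monkey_buccal": (3, 3),
    }


def test_noiseless_limit_recovers_planted_shift(tiny_design):
    cfg = cm.StudyConfig(datasets=[tiny_design], n_genes=2,
                         baseline_logratio_sd=1e-9, planted_genes=[
                             cm.PlantedGene(gene_label="HYP",
                                            state_by_dataset={"rat_pfc": "hyper"})])
    study = cm.generate_study(cfg)
    data = study.datasets["rat_pfc"]
    m = cm.compute_log_ratios(data.bound, data.input, data.groups)
    ctrl, strs = m.split()
    diff = strs.mean(axis=1) - ctrl.mean(axis=1)
    shifts = study.truth.probe_shifts["rat_pfc"].to_numpy()
    assert np.allclose(diff, shifts, atol=1e-6)
    assert np.allclose(shifts[:3], cfg.effect_logratio)


def test_mixed_gene_has_probes_shifted_both_ways(tiny_config):
    study = cm.generate_study(tiny_config)
    shifts = study.truth.probe_shifts["rat_pfc"]
    mix = shifts[shifts.index.str.startswith("rat_pfc_g0002")]
    assert (mix > 0).any() and (mix < 0).any()
    # odd probe count: the extra probe is shifted up
    assert (mix > 0).sum() == 2 and (mix < 0).sum() == 1


def test_null_gene_mean_difference_is_unbiased(tiny_design):
    """Monte Carlo over 1000 seeds: the null-gene group difference averages 0."""
    cfg_base = dict(datasets=[tiny_design.model_copy(update={
        "n_control": 2, "n_stress": 2})], n_genes=1, probes_per_gene=1,
        baseline_logratio_sd=0.5)
    diffs = []
    for seed in range(1000):
        study = cm.generate_study(cm.StudyConfig(**cfg_base, seed=seed))
        data = study.datasets["rat_pfc"]
        m = cm.compute_log_ratios(data.bound, data.input, data.groups)
        ctrl, strs = m.split()
        diffs.append(strs.mean() - ctrl.mean())
    se = 0.5 / np.sqrt(1000 * 2)  # sd of a single-sample mean difference / sqrt(reps)
    assert abs(np.mean(diffs)) < 3 * se * np.sqrt(2)


def test_large_sample_mean_shifts_converge_to_truth(tiny_design):
    """Empirical per-probe shifts approach the planted values as n grows."""
    big = tiny_design.model_copy(update={"n_control": 500, "n_stress": 500})
    cfg = cm.StudyConfig(datasets=[big], n_genes=4, planted_genes=[
        cm.PlantedGene(gene_label="HYP", state_by_dataset={"rat_pfc": "hyper"}),
        cm.PlantedGene(gene_label="LOW", state_by_dataset={"rat_pfc": "hypo"}),
        cm.PlantedGene(gene_label="MIX", state_by_dataset={"rat_pfc": "mixed"}),
    ], seed=5)
    study = cm.generate_study(cfg)
    data = study.datasets["rat_pfc"]
    m = cm.compute_log_ratios(data.bound, data.input, data.groups)
    ctrl, strs = m.split()
    diff = strs.mean(axis=1) - ctrl.mean(axis=1)
    shifts = study.truth.probe_shifts["rat_pfc"].to_numpy()
    tol = 4 * cfg.baseline_logratio_sd * np.sqrt(2 / 500)
    assert np.abs(diff - shifts).max() < tol


def test_gene_label_universe(tiny_config):
    labels = gene_labels(tiny_config)
    assert labels[:3] == ["HYP", "LOW", "MIX"]
    assert len(labels) == tiny_config.n_genes == len(set(labels))


# -------------------------------------------------------------- recovery ----

def _calls(pairs):
    return pd.DataFrame(pairs, columns=["gene_id", "direction_class"])


def _truth(states):
    return cm.SyntheticTruth(gene_labels=list(states), states={"d": states},
                             probe_shifts={"d": pd.Series(dtype=float)},
                             local_gene_ids={"d": {g: g for g in states}})


def test_recovery_identity_is_perfect():
    truth = _truth({"A": "hyper", "B": "hypo", "C": "null"})
    rec = cm.evaluate_recovery(_calls([("A", "hyper"), ("B", "hypo"),
                                       ("C", "none")]), truth, "d")
    assert (rec.sensitivity, rec.empirical_fdr, rec.direction_accuracy) == (1, 0, 1)


def test_recovery_empty_call_convention():
    truth = _truth({f"G{i}": "hyper" for i in range(10)})
    rec = cm.evaluate_recovery(_calls([]), truth, "d")
    assert rec.sensitivity == 0.0 and rec.empirical_fdr == 0.0


def test_recovery_counting():
    """8 called, 6 of them planted, 10 planted -> sensitivity 0.6, FDR 0.25."""
    states = {f"T{i}": "hyper" for i in range(10)}
    states |= {f"N{i}": "null" for i in range(5)}
    calls = [(f"T{i}", "hyper") for i in range(6)] + \
            [(f"N{i}", "hyper") for i in range(2)]
    rec = cm.evaluate_recovery(_calls(calls), _truth(states), "d")
    assert rec.sensitivity == pytest.approx(0.6)
    assert rec.empirical_fdr == pytest.approx(0.25)


def test_recovery_rejects_foreign_gene_universe():
    truth = _truth({"A": "hyper"})
    with pytest.raises(cm.InputError, match="universe"):
        cm.evaluate_recovery(_calls([("ZZZ", "hyper")]), truth, "d")


def test_noiseless_classes_equal_planted_states_for_dm_genes(tiny_design):
    """Module invariant: with vanishing noise every DM gene is classed as planted."""
    cfg = cm.StudyConfig(
        datasets=[tiny_design], n_genes=8, baseline_logratio_sd=1e-9,
        planted_genes=[
            cm.PlantedGene(gene_label="H1", state_by_dataset={"rat_pfc": "hyper"}),
            cm.PlantedGene(gene_label="H2", state_by_dataset={"rat_pfc": "hypo"}),
            cm.PlantedGene(gene_label="M1", state_by_dataset={"rat_pfc": "mixed"}),
        ], seed=2)
    study = cm.generate_study(cfg)
    gene_calls, _ = gene_calls_for(study, "rat_pfc")
    classes = dict(zip(gene_calls.gene_id.str.upper(), gene_calls.direction_class))
    for gene, state in study.truth.states["rat_pfc"].items():
        if state != "null":
            assert classes[gene.upper()] == state
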